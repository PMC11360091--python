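"""Energy windowing, background subtraction, and q-space histogramming."""

import numpy as np
import pytest

from ssaxs import (
    DetectorFrame,
    EnergyAxis,
    EnergyWindowSpec,
    GeometryConfig,
    PhysicalConstants,
    default_q_edges,
    detector_image,
    momentum_transfer,
    partition_windows,
    pixel_scattering_angle,
    rebin_energy,
    reduce_to_pattern,
    select_energy_range,
    subtract_background,
)
from conftest import random_raw_frame


def brute_force_pattern(frame, geom, q_edges, window, const=PhysicalConstants()):
    """Naive per-cell accumulation — the reference the vectorized path must equal."""
    counts = np.zeros(len(q_edges) - 1)
    centers = frame.energy_axis.centers_keV
    lo, hi = window
    for k in range(frame.energy_axis.n_bins):
        if not (lo <= centers[k] < hi):
            continue
        for i in range(frame.n_rows):
            for j in range(frame.n_cols):
                if geom.mask is not None and geom.mask[i, j]:
                    continue
                c = frame.counts[k, i, j]
                if c == 0:
                    continue
                q = momentum_transfer(
                    centers[k], pixel_scattering_angle(geom, i, j), const
                )
                m = np.searchsorted(q_edges, q, side="right") - 1
                if 0 <= m < len(counts) and q < q_edges[-1]:
                    counts[m] += c
    return counts


class TestPartitionWindows:
    def test_single_window_30_50(self):
        spec = EnergyWindowSpec(30, 50, 4, 20)
        assert partition_windows(spec) == [(30.0, 50.0)]

    def test_three_windows_30_45(self):
        spec = EnergyWindowSpec(30, 45, 5, 5)
        assert partition_windows(spec) == [(30.0, 35.0), (35.0, 40.0), (40.0, 45.0)]

    def test_window_equal_to_range(self):
        spec = EnergyWindowSpec(10, 15, 1, 5)
        assert len(partition_windows(spec)) == 1

    def test_windows_tile_without_gap_or_overlap(self):
        windows = partition_windows(EnergyWindowSpec(20, 60, 2, 8))
        assert windows[0][0] == 20 and windows[-1][1] == 60
        for (_, hi), (lo, _) in zip(windows[:-1], windows[1:]):
            assert hi == lo

    def test_non_divisible_range_reports_remainder(self):
        with pytest.raises(ValueError, match="remainder"):
            partition_windows(EnergyWindowSpec(30, 45, 4, 7))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EnergyWindowSpec(50, 30, 4, 20)
        with pytest.raises(ValueError):
            EnergyWindowSpec(30, 50, 25, 20)  # bin width > window
        with pytest.raises(ValueError):
            EnergyWindowSpec(30, 50, 4, 30)  # window > range


class TestSelectEnergyRange:
    def test_full_range_is_identity(self, small_axis):
        rng = np.random.default_rng(0)
        frame = random_raw_frame(small_axis, 4, 4, rng)
        out = select_energy_range(frame, 0, 1000)
        np.testing.assert_array_equal(out.counts, frame.counts)

    def test_empty_range_zeroes_everything(self, small_axis):
        rng = np.random.default_rng(0)
        frame = random_raw_frame(small_axis, 4, 4, rng)
        assert select_energy_range(frame, 500, 600).total_counts == 0

    def test_half_open_selection_30_45(self):
        # 1 keV bins from 0: centers 30.5 .. 44.5 lie in [30, 45) -> bins 30..44
        axis = EnergyAxis(n_bins=200, bin_width_keV=1.0, offset_keV=0.0)
        frame = DetectorFrame(np.ones((200, 2, 2), dtype=np.int64), axis)
        out = select_energy_range(frame, 30, 45)
        kept = np.flatnonzero(out.counts.sum(axis=(1, 2)))
        np.testing.assert_array_equal(kept, np.arange(30, 45))
        assert out.total_counts == 15 * 4

    def test_inverted_range_rejected(self, small_axis):
        frame = DetectorFrame(np.zeros((10, 2, 2), dtype=np.int64), small_axis)
        with pytest.raises(ValueError, match="inverted"):
            select_energy_range(frame, 45, 30)


class TestRebinEnergy:
    def test_preserves_totals_and_coarsens_axis(self):
        axis = EnergyAxis(n_bins=20, bin_width_keV=1.0, offset_keV=30.0)
        rng = np.random.default_rng(2)
        frame = random_raw_frame(axis, 3, 3, rng)
        out = rebin_energy(frame, 4.0)
        assert out.energy_axis.n_bins == 5
        assert out.energy_axis.bin_width_keV == 4.0
        assert out.total_counts == frame.total_counts
        np.testing.assert_array_equal(
            out.counts[0], frame.counts[:4].sum(axis=0)
        )

    def test_non_integer_factor_rejected(self, small_axis):
        frame = DetectorFrame(np.zeros((10, 2, 2), dtype=np.int64), small_axis)
        with pytest.raises(ValueError, match="integer multiple"):
            rebin_energy(frame, 2.5)


class TestSubtractBackground:
    def test_self_subtraction_is_zero(self, small_axis):
        rng = np.random.default_rng(4)
        frame = random_raw_frame(small_axis, 4, 4, rng)
        diff = subtract_background(frame, frame)
        assert diff.total_counts == 0
        assert not diff.is_raw

    def test_elementwise_difference_keeps_negatives(self, small_axis):
        sample = DetectorFrame(np.full((10, 2, 2), 5, dtype=np.int64), small_axis)
        bg = DetectorFrame(np.full((10, 2, 2), 2, dtype=np.int64), small_axis)
        assert np.all(subtract_background(sample, bg).counts == 3)
        assert np.all(subtract_background(bg, sample).counts == -3)

    def test_axis_mismatch_rejected(self):
        a = DetectorFrame(np.zeros((10, 2, 2), dtype=np.int64),
                          EnergyAxis(10, 1.0, 0.0))
        b = DetectorFrame(np.zeros((10, 2, 2), dtype=np.int64),
                          EnergyAxis(10, 1.0, 5.0))
        with pytest.raises(ValueError, match="energy-axis mismatch"):
            subtract_background(a, b)

    def test_reduction_is_linear_in_subtraction(self, small_geometry, small_axis):
        rng = np.random.default_rng(9)
        sample = random_raw_frame(small_axis, 8, 8, rng)
        bg = random_raw_frame(small_axis, 8, 8, rng)
        q_edges = np.arange(0, 6, 0.1)
        window = (30.0, 40.0)
        direct = reduce_to_pattern(
            subtract_background(sample, bg), small_geometry, q_edges, window
        )
        separate = (
            reduce_to_pattern(sample, small_geometry, q_edges, window).counts
            - reduce_to_pattern(bg, small_geometry, q_edges, window).counts
        )
        np.testing.assert_allclose(direct.counts, separate, atol=1e-9)


class TestReduceToPattern:
    def test_zero_frame_gives_zero_pattern(self, small_geometry, small_axis):
        frame = DetectorFrame(np.zeros((10, 8, 8), dtype=np.int64), small_axis)
        pattern = reduce_to_pattern(frame, small_geometry, np.arange(0, 5, 0.1), (30, 40))
        assert pattern.total_counts == 0

    def test_single_photon_lands_in_its_q_bin(self, small_geometry, small_axis):
        counts = np.zeros((10, 8, 8), dtype=np.int64)
        counts[5, 7, 7] = 1
        frame = DetectorFrame(counts, small_axis)
        q_edges = np.arange(0, 6, 0.1)
        pattern = reduce_to_pattern(frame, small_geometry, q_edges, (30, 40))
        q = momentum_transfer(
            small_axis.centers_keV[5], pixel_scattering_angle(small_geometry, 7, 7)
        )
        expected_bin = np.searchsorted(q_edges, q, side="right") - 1
        assert pattern.counts[expected_bin] == 1
        assert pattern.total_counts == 1

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, small_geometry, small_axis, trial):
        rng = np.random.default_rng(100 + trial)
        frame = random_raw_frame(small_axis, 8, 8, rng)
        q_edges = np.arange(0.0, 4.5, 0.15)
        window = (32.0, 38.0)
        pattern = reduce_to_pattern(frame, small_geometry, q_edges, window)
        expected = brute_force_pattern(frame, small_geometry, q_edges, window)
        np.testing.assert_array_equal(pattern.counts, expected)

    def test_oracle_agreement_with_mask(self, small_axis):
        mask = np.zeros((8, 8), dtype=bool)
        mask[::3, 1::2] = True
        geom = GeometryConfig(sdd_mm=250, beam_center=(-1, -1), n_rows=8, n_cols=8,
                              mask=mask)
        rng = np.random.default_rng(42)
        frame = random_raw_frame(small_axis, 8, 8, rng)
        q_edges = np.arange(0.0, 4.5, 0.1)
        pattern = reduce_to_pattern(frame, geom, q_edges, (30, 40))
        expected = brute_force_pattern(frame, geom, q_edges, (30, 40))
        np.testing.assert_array_equal(pattern.counts, expected)

    def test_count_conservation_full_range(self, bench_geometry, hexitec_axis):
        rng = np.random.default_rng(8)
        frame = random_raw_frame(hexitec_axis, 80, 80, rng, high=3)
        q_edges = default_q_edges(bench_geometry, 200.0)
        window = (0.0, 200.0)
        pattern = reduce_to_pattern(frame, bench_geometry, q_edges, window)
        assert pattern.total_counts == frame.total_counts

    def test_window_additivity(self, small_geometry, small_axis):
        rng = np.random.default_rng(13)
        frame = random_raw_frame(small_axis, 8, 8, rng)
        q_edges = np.arange(0, 6, 0.1)
        whole = reduce_to_pattern(frame, small_geometry, q_edges, (30, 40))
        parts = sum(
            reduce_to_pattern(frame, small_geometry, q_edges, w).counts
            for w in [(30.0, 35.0), (35.0, 40.0)]
        )
        np.testing.assert_allclose(parts, whole.counts, atol=1e-9)

    def test_shape_mismatch_rejected(self, bench_geometry, small_axis):
        frame = DetectorFrame(np.zeros((10, 8, 8), dtype=np.int64), small_axis)
        with pytest.raises(ValueError, match="do not match"):
            reduce_to_pattern(frame, bench_geometry, np.arange(0, 5, 0.1), (30, 40))


class TestDetectorImage:
    def test_zero_frame(self, small_axis):
        frame = DetectorFrame(np.zeros((10, 4, 4), dtype=np.int64), small_axis)
        assert detector_image(frame, (0, 100)).sum() == 0

    def test_single_count_window_membership(self, small_axis):
        counts = np.zeros((10, 4, 4), dtype=np.int64)
        counts[5, 1, 2] = 1  # center 35.5 keV
        frame = DetectorFrame(counts, small_axis)
        img = detector_image(frame, (30.0, 40.0))
        assert img[1, 2] == 1 and img.sum() == 1
        assert detector_image(frame, (36.0, 40.0)).sum() == 0

    def test_partition_additivity(self, small_axis):
        rng = np.random.default_rng(21)
        frame = random_raw_frame(small_axis, 4, 4, rng)
        total = detector_image(frame, (30.0, 40.0))
        tiled = sum(detector_image(frame, w)
                    for w in [(30.0, 32.0), (32.0, 36.0), (36.0, 40.0)])
        np.testing.assert_array_equal(tiled, total)
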