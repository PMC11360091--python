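import numpy as np
import pytest

from ssaxs import DetectorFrame, EnergyAxis, GeometryConfig, SourceSpectrum


@pytest.fixture
def bench_geometry():
    """Default validation geometry: SDD 250 mm, 80x80 x 0.25 mm sensor,
    transmitted beam just off one corner (beam-stop arrangement)."""
    return GeometryConfig(
        sdd_mm=250.0, beam_center=(-2.0, -2.0), pixel_pitch_mm=0.25,
        n_rows=80, n_cols=80,
    )


@pytest.fixture
def hexitec_axis():
    """HEXITEC-like axis: 200 bins x 1 keV from 0."""
    return EnergyAxis(n_bins=200, bin_width_keV=1.0, offset_keV=0.0)


@pytest.fixture
def small_geometry():
    return GeometryConfig(
        sdd_mm=250.0, beam_center=(-1.0, -1.0), pixel_pitch_mm=0.25,
        n_rows=8, n_cols=8,
    )


@pytest.fixture
def small_axis():
    return EnergyAxis(n_bins=10, bin_width_keV=1.0, offset_keV=30.0)


@pytest.fixture
def flat_30_45():
    return SourceSpectrum.flat(30.0, 45.0)


def random_raw_frame(axis, n_rows, n_cols, rng, high=5):
    counts = rng.integers(0, high, size=(axis.n_bins, n_rows, n_cols))
    return DetectorFrame(counts=counts, energy_axis=axis, is_raw=True)
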