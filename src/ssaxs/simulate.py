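"""Forward simulation of spectroscopic detector frames.

Generates synthetic measurements containing Debye–Scherrer rings — the
circular traces a powder sample's Bragg reflections leave on a flat
detector — under a polychromatic source spectrum with Poisson counting
noise.  The ring profile is Gaussian in q (the coordinate the reduction
measures), so the injected ground truth is directly recoverable: a ring
at q₀ must reappear as a 1D pattern peak at q₀.

Expected per-ring totals are normalized over the *on-detector* cells, so
a ring's ``intensity`` is the expected number of counts it contributes
to the frame, making intensity ratios across simulated scan positions
exact in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import DetectorFrame, EnergyAxis
from .geometry import GeometryConfig, PhysicalConstants, precompute_q_map

__all__ = ["RingSpec", "SourceSpectrum", "SimulationReport", "simulate_frame", "simulate_scan"]


@dataclass(frozen=True)
class RingSpec:
    """One powder reflection: a Gaussian ring in q.

    ``intensity`` is the expected total number of counts the ring
    contributes over the whole spectrum and detector.
    """

    q_peak: float
    sigma_q: float = 0.15
    intensity: float = 10_000.0

    def __post_init__(self) -> None:
        if self.q_peak <= 0:
            raise ValueError(f"q_peak must be positive, got {self.q_peak}")
        if self.sigma_q <= 0:
            raise ValueError(f"sigma_q must be positive, got {self.sigma_q}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class SourceSpectrum:
    """Relative source weight as a function of photon energy (keV).

    Tabulated (energy, weight) pairs, linearly interpolated onto the
    detector's energy-bin centers and normalized to unit sum; zero
    outside the tabulated range.  Stands in for a polychromatic tube
    output — shape matters only through the per-bin weights.
    """

    energies_keV: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or len(e) < 1:
            raise ValueError("spectrum table must be matching 1D energy/weight arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("spectrum energies must be strictly ascending")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("spectrum weights must be non-negative with at least one positive")
        object.__setattr__(self, "energies_keV", tuple(float(x) for x in e))
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @classmethod
    def flat(cls, lo_keV: float, hi_keV: float) -> "SourceSpectrum":
        """Uniform spectrum over [lo, hi] keV."""
        if lo_keV >= hi_keV:
            raise ValueError(f"inverted spectrum range [{lo_keV}, {hi_keV}]")
        return cls(energies_keV=(lo_keV, hi_keV), weights=(1.0, 1.0))

    def bin_weights(self, axis: EnergyAxis) -> np.ndarray:
        """Normalized weight of each energy bin (by bin center), sum 1."""
        w = np.interp(
            axis.centers_keV, self.energies_keV, self.weights, left=0.0, right=0.0
        )
        total = w.sum()
        if total <= 0:
            raise ValueError(
                "spectrum has zero weight over the detector energy axis "
                f"({axis.offset_keV}..{axis.offset_keV + axis.n_bins * axis.bin_width_keV} keV)"
            )
        return w / total


@dataclass(frozen=True)
class SimulationReport:
    """Ground truth emitted alongside a simulated frame."""

    expected_per_ring: tuple[float, ...]
    expected_background: float
    total_counts: int

    @property
    def expected_total(self) -> float:
        return sum(self.expected_per_ring) + self.expected_background


def expected_rate_map(
    geom: GeometryConfig,
    axis: EnergyAxis,
    spectrum: SourceSpectrum,
    rings: list[RingSpec],
    background_rate: float = 0.0,
    const: PhysicalConstants = PhysicalConstants(),
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Poisson rate λ(k,i,j) of the forward model, plus per-ring expected totals.

    λ = background_rate + Σ_r intensity_r · w(E_k) · N(q(k,i,j); q_r, σ_r),
    each ring renormalized over on-detector cells so its expected total
    equals ``intensity_r`` (0 if the ring never intersects the sensor).
    """
    if background_rate < 0:
        raise ValueError("background_rate must be non-negative")
    w = spectrum.bin_weights(axis)
    qmap = precompute_q_map(geom, axis, const)
    on_detector = np.isfinite(qmap)
    lam = np.full(qmap.shape, float(background_rate))
    lam[~on_detector] = 0.0
    expected = []
    for ring in rings:
        g = np.exp(-0.5 * ((qmap - ring.q_peak) / ring.sigma_q) ** 2)
        g = np.where(on_detector, g, 0.0)
        u = w[:, None, None] * g
        s = u.sum()
        if s > 0 and ring.intensity > 0:
            lam += ring.intensity * u / s
            expected.append(float(ring.intensity))
        else:
            expected.append(0.0)
    return lam, tuple(expected)


def simulate_frame(
    geom: GeometryConfig,
    axis: EnergyAxis,
    spectrum: SourceSpectrum,
    rings: list[RingSpec],
    background_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    const: PhysicalConstants = PhysicalConstants(),
) -> tuple[DetectorFrame, SimulationReport]:
    """Draw one Poisson frame from the ring + flat-background forward model.

    ``background_rate`` is the expected count per (energy bin, pixel)
    cell.  The same seed always reproduces the same frame.
    """
    lam, expected = expected_rate_map(geom, axis, spectrum, rings, background_rate, const)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.int64)
    n_cells = int(np.isfinite(precompute_q_map(geom, axis, const)).sum())
    report = SimulationReport(
        expected_per_ring=expected,
        expected_background=float(background_rate) * n_cells,
        total_counts=int(counts.sum()),
    )
    seed_tag = seed if isinstance(seed, int) else "generator"
    frame = DetectorFrame(
        counts=counts,
        energy_axis=axis,
        is_raw=True,
        provenance=f"simulate_frame(seed={seed_tag})",
    )
    return frame, report


def simulate_scan(
    geom: GeometryConfig,
    axis: EnergyAxis,
    spectrum: SourceSpectrum,
    rings: list[RingSpec],
    intensity_multipliers: np.ndarray,
    background_rate: float = 0.0,
    seed: int = 0,
    const: PhysicalConstants = PhysicalConstants(),
) -> tuple[list[DetectorFrame], list[SimulationReport]]:
    """Simulate a raster scan, one frame per grid cell in row-major order.

    Each cell scales every ring's intensity by its multiplier (e.g. mass
    fractions 0.25/0.5/0.75/1.0 across a well plate).  Deterministic
    under ``seed``; per-position streams are independent.
    """
    mult = np.asarray(intensity_multipliers, dtype=float)
    if mult.ndim != 2 or mult.size == 0:
        raise ValueError(f"multiplier grid must be non-empty 2D, got shape {mult.shape}")
    if np.any(mult < 0):
        raise ValueError("intensity multipliers must be non-negative")
    children = np.random.SeedSequence(seed).spawn(mult.size)
    frames, reports = [], []
    for pos, (m, child) in enumerate(zip(mult.ravel(), children)):
        scaled = [
            RingSpec(q_peak=r.q_peak, sigma_q=r.sigma_q, intensity=r.intensity * m)
            for r in rings
        ]
        frame, report = simulate_frame(
            geom, axis, spectrum, scaled, background_rate,
            seed=np.random.default_rng(child), const=const,
        )
        frame.provenance = f"simulate_scan(seed={seed}, position={pos})"
        frames.append(frame)
        reports.append(report)
    return frames, reports
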