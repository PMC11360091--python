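"""Spatially resolved scattering maps from raster-scan measurements.

A pencil-beam raster scan produces one detector frame per sample
position.  Each frame is reduced to a 1D pattern and scored by the area
under the peak (AUP) — the sum of pattern counts over a user q-range,
e.g. 7–9 nm⁻¹ for the first caffeine reflection — and the scores are
arranged into the user-declared scan grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import DetectorFrame
from .geometry import GeometryConfig, PhysicalConstants
from .reduction import ScatteringPattern, reduce_to_pattern, subtract_background

__all__ = ["ScanMap", "area_under_peak", "build_scan_map"]

ORDERINGS = ("row-major", "serpentine")


@dataclass
class ScanMap:
    """2D grid of AUP values assembled from a raster scan."""

    values: np.ndarray
    q_range: tuple[float, float]
    ordering: str = "row-major"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"map values must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if self.ordering not in ORDERINGS:
            raise ValueError(f"ordering must be one of {ORDERINGS}, got {self.ordering!r}")


def area_under_peak(pattern: ScatteringPattern, q_min: float, q_max: float) -> float:
    """Sum of pattern counts over q bins whose center lies in [q_min, q_max).

    No baseline is subtracted; for histogrammed counts the plain sum is
    the natural "area".
    """
    if q_min >= q_max:
        raise ValueError(f"inverted q-range [{q_min}, {q_max})")
    centers = pattern.q_centers
    in_range = (centers >= q_min) & (centers < q_max)
    if not np.any(in_range):
        raise ValueError(
            f"q-range [{q_min}, {q_max}) contains no bin center of the pattern "
            f"(grid spans [{pattern.q_edges[0]}, {pattern.q_edges[-1]}))"
        )
    return float(pattern.counts[in_range].sum())


def build_scan_map(
    frames: Sequence[DetectorFrame],
    scan_rows: int,
    scan_cols: int,
    geom: GeometryConfig,
    window_keV: tuple[float, float],
    q_edges: np.ndarray,
    q_range: tuple[float, float],
    background: DetectorFrame | None = None,
    const: PhysicalConstants = PhysicalConstants(),
    ordering: str = "row-major",
) -> ScanMap:
    """Reduce every scan position and place its AUP into the scan grid.

    Frames are consumed in their given order; in row-major mode frame f
    lands at (f // scan_cols, f % scan_cols), in serpentine mode
    odd-numbered scan rows run right-to-left.  One shared background
    frame, if given, is subtracted from every position.
    """
    if ordering not in ORDERINGS:
        raise ValueError(f"ordering must be one of {ORDERINGS}, got {ordering!r}")
    n = len(frames)
    if n != scan_rows * scan_cols:
        raise ValueError(
            f"{n} measurements cannot fill a {scan_rows}x{scan_cols} grid "
            f"({scan_rows * scan_cols} cells)"
        )
    values = np.empty((scan_rows, scan_cols), dtype=float)
    for f, frame in enumerate(frames):
        if background is not None:
            frame = subtract_background(frame, background)
        pattern = reduce_to_pattern(frame, geom, q_edges, window_keV, const)
        r, c = divmod(f, scan_cols)
        if ordering == "serpentine" and r % 2 == 1:
            c = scan_cols - 1 - c
        values[r, c] = area_under_peak(pattern, *q_range)
    return ScanMap(values=values, q_range=(float(q_range[0]), float(q_range[1])), ordering=ordering)
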