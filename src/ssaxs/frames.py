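"""Core in-memory containers for spectroscopic detector data.

A spectroscopic photon-counting detector (HEXITEC-class CdTe sensor)
records, for every pixel, a histogram of photon energies.  A single
measurement is therefore a 3D count array indexed (energy bin, pixel row,
pixel column), carried here by :class:`DetectorFrame` together with the
energy-axis metadata that turns bin indices into keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnergyAxis", "DetectorFrame"]


@dataclass(frozen=True)
class EnergyAxis:
    """Uniform energy binning of the detector's spectral axis.

    Bin ``k`` spans the half-open interval
    ``[offset + k*w, offset + (k+1)*w)`` where ``w`` is ``bin_width_keV``;
    its representative energy is the bin center ``offset + (k + 0.5)*w``.

    Parameters
    ----------
    n_bins
        Number of energy bins (e.g. 200 for a HEXITEC acquisition).
    bin_width_keV
        Width of each bin in keV (e.g. 1.0).
    offset_keV
        Energy of the lower edge of bin 0.
    """

    n_bins: int
    bin_width_keV: float = 1.0
    offset_keV: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins <= 0:
            raise ValueError(f"n_bins must be positive, got {self.n_bins}")
        if self.bin_width_keV <= 0:
            raise ValueError(
                f"bin_width_keV must be positive, got {self.bin_width_keV}"
            )

    @property
    def centers_keV(self) -> np.ndarray:
        """Bin-center energies, shape ``(n_bins,)``."""
        return self.offset_keV + (np.arange(self.n_bins) + 0.5) * self.bin_width_keV

    @property
    def edges_keV(self) -> np.ndarray:
        """Bin edges, shape ``(n_bins + 1,)``."""
        return self.offset_keV + np.arange(self.n_bins + 1) * self.bin_width_keV


@dataclass
class DetectorFrame:
    """One detector measurement: counts indexed (energy bin, row, column).

    ``is_raw`` marks unmodified detector output, whose counts must be
    non-negative integers; derived frames (e.g. after background
    subtraction) are real-valued and may go negative.
    """

    counts: np.ndarray
    energy_axis: EnergyAxis
    is_raw: bool = True
    provenance: str = ""
    exposure_s: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError(f"counts must be 3D (energy, row, col), got shape {counts.shape}")
        if counts.shape[0] != self.energy_axis.n_bins:
            raise ValueError(
                f"counts has {counts.shape[0]} energy planes but the energy axis "
                f"declares {self.energy_axis.n_bins} bins"
            )
        if not np.all(np.isfinite(counts)):
            raise ValueError("counts contain non-finite values")
        if self.is_raw:
            if np.any(counts < 0):
                raise ValueError("raw frame contains negative counts")
            if not np.issubdtype(counts.dtype, np.integer):
                if not np.array_equal(counts, np.round(counts)):
                    raise ValueError("raw frame contains non-integer counts")
                counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.float64, copy=False)
        self.counts = counts
        if self.exposure_s is not None and self.exposure_s <= 0:
            raise ValueError(f"exposure_s must be positive, got {self.exposure_s}")

    @property
    def n_rows(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[2]

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "DetectorFrame":
        return DetectorFrame(
            counts=self.counts.copy(),
            energy_axis=self.energy_axis,
            is_raw=self.is_raw,
            provenance=self.provenance,
            exposure_s=self.exposure_s,
        )
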