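"""Detector geometry: pixels → scattering angles → momentum transfer.

The flat 2D detector sits at a sample-to-detector distance SDD behind the
sample; the transmitted primary beam (blocked by a beam stop) defines the
origin of the scattering angle on the detector plane.  A pixel at radial
distance r from the beam center sees the scattering angle
``2θ = arctan(r / SDD)``, and an elastically scattered photon of energy E
landing there carries momentum transfer

    q = 4π E sin(θ) / hc,    θ = 2θ / 2,

with hc = 1.24 keV·nm.  The Bragg condition links q to a lattice d-spacing
by q = 2π/d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import EnergyAxis

__all__ = [
    "PhysicalConstants",
    "GeometryConfig",
    "pixel_scattering_angle",
    "momentum_transfer",
    "q_from_dspacing",
    "precompute_q_map",
    "ring_radius",
    "max_attainable_q",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering the q conversion.

    ``hc_keV_nm`` defaults to the rounded 1.24 keV·nm conventionally used
    in scattering work; :meth:`codata` supplies the full-precision value.
    """

    hc_keV_nm: float = 1.24

    def __post_init__(self) -> None:
        if self.hc_keV_nm <= 0:
            raise ValueError(f"hc_keV_nm must be positive, got {self.hc_keV_nm}")

    @classmethod
    def codata(cls) -> "PhysicalConstants":
        from scipy import constants

        # h*c in keV*nm: J*m / (1000 eV/keV * e) * 1e9 nm/m
        hc = constants.h * constants.c / (constants.e * 1e3) * 1e9
        return cls(hc_keV_nm=hc)


@dataclass
class GeometryConfig:
    """System geometry of the sSAXS bench.

    Parameters
    ----------
    sdd_mm
        Sample-to-detector distance in mm (typically 220–300).
    beam_center
        (row, col) of the transmitted primary beam in fractional pixel
        coordinates; pixel (i, j) occupies [i, i+1) × [j, j+1) in pitch
        units, so its center is (i + 0.5, j + 0.5).  The beam center may
        lie outside the sensor (beam-stop arrangements often put it just
        off a corner).
    pixel_pitch_mm
        Pixel pitch in mm (0.25 for an 80×80 HEXITEC-class sensor).
    n_rows, n_cols
        Sensor extent in pixels.
    mask
        Optional boolean array (n_rows, n_cols); True excludes a pixel
        from reduction.
    """

    sdd_mm: float
    beam_center: tuple[float, float]
    pixel_pitch_mm: float = 0.25
    n_rows: int = 80
    n_cols: int = 80
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sdd_mm <= 0:
            raise ValueError(f"sdd_mm must be positive, got {self.sdd_mm}")
        if self.pixel_pitch_mm <= 0:
            raise ValueError(f"pixel_pitch_mm must be positive, got {self.pixel_pitch_mm}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("detector extents must be positive")
        self.beam_center = (float(self.beam_center[0]), float(self.beam_center[1]))
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"mask shape {mask.shape} does not match detector "
                    f"({self.n_rows}, {self.n_cols})"
                )
            self.mask = mask

    def pixel_radii_mm(self) -> np.ndarray:
        """Distance of every pixel center from the beam center, in mm."""
        rows = np.arange(self.n_rows) + 0.5 - self.beam_center[0]
        cols = np.arange(self.n_cols) + 0.5 - self.beam_center[1]
        return self.pixel_pitch_mm * np.hypot(rows[:, None], cols[None, :])


def pixel_scattering_angle(geom: GeometryConfig, row: int, col: int) -> float:
    """Scattering angle 2θ (radians) subtended by pixel center (row, col).

    2θ = arctan(r / SDD) with r the in-plane distance of the pixel center
    from the transmitted-beam location; always in [0, π/2).
    """
    if not (0 <= row < geom.n_rows and 0 <= col < geom.n_cols):
        raise ValueError(
            f"pixel ({row}, {col}) outside detector ({geom.n_rows}, {geom.n_cols})"
        )
    r = geom.pixel_pitch_mm * np.hypot(
        row + 0.5 - geom.beam_center[0], col + 0.5 - geom.beam_center[1]
    )
    return float(np.arctan(r / geom.sdd_mm))


def momentum_transfer(
    E_keV, two_theta, const: PhysicalConstants = PhysicalConstants()
):
    """Momentum transfer q (nm⁻¹) for photons of energy E at angle 2θ.

    q = 4π E sin(2θ/2) / hc.  θ in the Bragg formula is half the
    scattering angle 2θ measured from the beam axis.  Accepts scalars or
    broadcastable arrays.
    """
    E = np.asarray(E_keV, dtype=float)
    if np.any(E <= 0):
        raise ValueError("photon energy must be positive")
    q = 4.0 * np.pi * E * np.sin(np.asarray(two_theta) / 2.0) / const.hc_keV_nm
    if np.isscalar(E_keV) and np.isscalar(two_theta):
        return float(q)
    return q


def q_from_dspacing(d_nm: float) -> float:
    """Peak position q = 2π/d for a lattice spacing d (nm)."""
    if d_nm <= 0:
        raise ValueError(f"d-spacing must be positive, got {d_nm}")
    return 2.0 * np.pi / d_nm


def ring_radius(
    geom: GeometryConfig,
    q: float,
    E_keV: float,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Radius (mm) on the detector plane of the ring at momentum transfer q.

    Inverts the q formula: r = SDD·tan(2·arcsin(q·hc / 4πE)).  Raises if
    the requested q is kinematically unreachable at this energy.
    """
    if E_keV <= 0:
        raise ValueError("photon energy must be positive")
    if q < 0:
        raise ValueError("q must be non-negative")
    s = q * const.hc_keV_nm / (4.0 * np.pi * E_keV)
    if s > 1:
        raise ValueError(
            f"q = {q} nm^-1 is unreachable at E = {E_keV} keV "
            "(energy too low for the requested momentum transfer)"
        )
    return float(geom.sdd_mm * np.tan(2.0 * np.arcsin(s)))


def precompute_q_map(
    geom: GeometryConfig,
    axis: EnergyAxis,
    const: PhysicalConstants = PhysicalConstants(),
) -> np.ndarray:
    """q value of every (energy bin, row, col) cell, shape (n_bins, n_rows, n_cols).

    The representative energy of bin k is its center.  Masked pixels are
    marked NaN so downstream binning drops them.
    """
    two_theta = np.arctan(geom.pixel_radii_mm() / geom.sdd_mm)  # (rows, cols)
    E = axis.centers_keV[:, None, None]
    qmap = 4.0 * np.pi * E * np.sin(two_theta / 2.0)[None, :, :] / const.hc_keV_nm
    if geom.mask is not None:
        qmap[:, geom.mask] = np.nan
    return qmap


def max_attainable_q(
    geom: GeometryConfig,
    E_keV: float,
    const: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Largest q any unmasked pixel reaches at energy ``E_keV``."""
    radii = geom.pixel_radii_mm()
    if geom.mask is not None:
        radii = radii[~geom.mask]
    r_max = float(np.max(radii))
    return momentum_transfer(E_keV, np.arctan(r_max / geom.sdd_mm), const)
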