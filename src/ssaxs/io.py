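"""Reading and writing detector frames and derived products.

Two interchangeable frame dialects are supported:

* an HDF5 container (``.h5``/``.hdf5``) with a 3D ``/counts`` dataset
  (axis order energy → row → col, C-order; int64 raw, float64 corrected)
  and the energy-axis fields as attributes — the preferred form;
* a raw binary dump (``.bin``) with a JSON text sidecar
  (``<name>.json``) holding the same metadata.

Patterns and maps are exported as plain CSV.  Scan folders are read in
natural-sort order of filename, so ``pos_2`` precedes ``pos_10``
regardless of filesystem enumeration order.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np

from .frames import DetectorFrame, EnergyAxis
from .mapping import ScanMap
from .reduction import ScatteringPattern

__all__ = [
    "FrameFormatError",
    "load_frame",
    "save_frame",
    "load_scan_folder",
    "export_pattern",
    "read_pattern",
    "export_map",
    "natural_key",
]

FRAME_SUFFIXES = (".h5", ".hdf5", ".bin")


class FrameFormatError(ValueError):
    """A frame file exists but does not conform to a supported layout."""


def natural_key(name: str) -> tuple:
    """Sort key comparing digit runs numerically: a_2 < a_10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p.lower() for p in parts)


def save_frame(frame: DetectorFrame, path: str | Path) -> Path:
    """Write a frame to ``path``; the dialect follows the file suffix.

    Writing is deterministic: identical frames produce identical bytes.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    dtype = np.int64 if frame.is_raw else np.float64
    counts = np.ascontiguousarray(frame.counts, dtype=dtype)
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w", libver="earliest") as f:
            ds = f.create_dataset("counts", data=counts, track_times=False)
            ds.attrs["bin_width_keV"] = frame.energy_axis.bin_width_keV
            ds.attrs["offset_keV"] = frame.energy_axis.offset_keV
            ds.attrs["is_raw"] = frame.is_raw
            ds.attrs["provenance"] = frame.provenance
            if frame.exposure_s is not None:
                ds.attrs["exposure_s"] = frame.exposure_s
    elif suffix == ".bin":
        counts.tofile(path)
        meta = {
            "n_bins": frame.energy_axis.n_bins,
            "bin_width_keV": frame.energy_axis.bin_width_keV,
            "offset_keV": frame.energy_axis.offset_keV,
            "n_rows": frame.n_rows,
            "n_cols": frame.n_cols,
            "is_raw": frame.is_raw,
            "dtype": counts.dtype.name,
            "provenance": frame.provenance,
            "exposure_s": frame.exposure_s,
        }
        path.with_suffix(".json").write_text(
            json.dumps(meta, sort_keys=True, indent=1) + "\n"
        )
    else:
        raise FrameFormatError(
            f"unsupported frame suffix {suffix!r} for {path} "
            f"(expected one of {FRAME_SUFFIXES})"
        )
    return path


def load_frame(path: str | Path) -> DetectorFrame:
    """Read a frame written by :func:`save_frame` (either dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return _load_hdf5(path)
    if suffix == ".bin":
        return _load_binary(path)
    raise FrameFormatError(
        f"unsupported frame suffix {suffix!r} for {path} "
        f"(expected one of {FRAME_SUFFIXES})"
    )


def _load_hdf5(path: Path) -> DetectorFrame:
    try:
        with h5py.File(path, "r") as f:
            if "counts" not in f:
                raise FrameFormatError(f"{path}: missing /counts dataset")
            ds = f["counts"]
            counts = ds[()]
            if counts.ndim != 3:
                raise FrameFormatError(
                    f"{path}: /counts must be 3D, got shape {counts.shape}"
                )
            axis = EnergyAxis(
                n_bins=counts.shape[0],
                bin_width_keV=float(ds.attrs["bin_width_keV"]),
                offset_keV=float(ds.attrs["offset_keV"]),
            )
            exposure = ds.attrs.get("exposure_s")
            return DetectorFrame(
                counts=counts,
                energy_axis=axis,
                is_raw=bool(ds.attrs["is_raw"]),
                provenance=str(ds.attrs.get("provenance", "")),
                exposure_s=float(exposure) if exposure is not None else None,
            )
    except (OSError, KeyError) as exc:
        raise FrameFormatError(f"cannot read HDF5 frame {path}: {exc}") from exc


def _load_binary(path: Path) -> DetectorFrame:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FrameFormatError(f"{path}: missing JSON sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        shape = (int(meta["n_bins"]), int(meta["n_rows"]), int(meta["n_cols"]))
        dtype = np.dtype(meta.get("dtype", "int64" if meta["is_raw"] else "float64"))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FrameFormatError(f"corrupt sidecar {sidecar}: {exc}") from exc
    flat = np.fromfile(path, dtype=dtype)
    if flat.size != int(np.prod(shape)):
        raise FrameFormatError(
            f"{path}: file holds {flat.size} values but sidecar declares "
            f"shape {shape} ({int(np.prod(shape))} values)"
        )
    axis = EnergyAxis(
        n_bins=shape[0],
        bin_width_keV=float(meta["bin_width_keV"]),
        offset_keV=float(meta["offset_keV"]),
    )
    exposure = meta.get("exposure_s")
    return DetectorFrame(
        counts=flat.reshape(shape),
        energy_axis=axis,
        is_raw=bool(meta["is_raw"]),
        provenance=str(meta.get("provenance", "")),
        exposure_s=float(exposure) if exposure is not None else None,
    )


def load_scan_folder(folder: str | Path) -> list[DetectorFrame]:
    """Load every frame file in a folder, in natural-sort filename order.

    Any unreadable member raises, naming the offending file — raster
    positions are never silently skipped.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"scan folder not found: {folder}")
    files = sorted(
        (p for p in folder.iterdir() if p.suffix.lower() in FRAME_SUFFIXES),
        key=lambda p: natural_key(p.name),
    )
    if not files:
        raise FileNotFoundError(f"no frame files ({FRAME_SUFFIXES}) in {folder}")
    frames = []
    for p in files:
        try:
            frames.append(load_frame(p))
        except Exception as exc:
            raise FrameFormatError(f"failed to load scan member {p}: {exc}") from exc
    return frames


def export_pattern(pattern: ScatteringPattern, path: str | Path) -> Path:
    """Write a pattern as CSV: header ``q_nm_inv,counts``, one row per bin.

    Bin-center q values; ≥ 10 significant digits so a re-parse
    reproduces the counts.
    """
    path = Path(path)
    rows = "".join(
        f"{q:.10g},{c:.10g}\n" for q, c in zip(pattern.q_centers, pattern.counts)
    )
    path.write_text("q_nm_inv,counts\n" + rows)
    return path


def read_pattern(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse an exported pattern CSV back into (q_centers, counts)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return data[:, 0], data[:, 1]


def export_map(scan_map: ScanMap, path: str | Path) -> Path:
    """Write a scan map as a CSV matrix, one row per scan row."""
    path = Path(path)
    rows = "".join(",".join(f"{v:.10g}" for v in row) + "\n" for row in scan_map.values)
    path.write_text(rows)
    return path
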