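"""Slice-series CSV I/O.

A volume on disk is a directory of one uncompressed CSV file per slice
plus a ``metadata.csv`` holding the spatial metadata — the same shape of
layout DICOM uses (a stack of 2D arrays plus header), but in plain text.

Dialect (normative):

* ``metadata.csv``: header line ``key,value``; required keys ``n_x``,
  ``n_y``, ``n_z``, ``pixel_size_x_mm``, ``pixel_size_y_mm``,
  ``slice_thickness_mm``; unknown keys are preserved on round trip.
* slices named ``slice_NNNN.csv`` (4 digits, 0-based, ascending z), each
  with ``n_y`` lines of ``n_x`` comma-separated values (row = y ascending,
  column = x ascending), no header.
* '.' decimal separator, no quoting or thousands separators; full ``repr``
  precision by default, fixed decimals when a precision is configured.
* UTF-8, "\\n" line terminator.  Same volume + same precision produce
  byte-identical files across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from ctcompat.volume import HUVolume, VoxelSpacing

METADATA_FILENAME = "metadata.csv"
REQUIRED_KEYS = (
    "n_x",
    "n_y",
    "n_z",
    "pixel_size_x_mm",
    "pixel_size_y_mm",
    "slice_thickness_mm",
)
MAX_SLICES = 10000  # 4-digit naming scheme


class SeriesFormatError(ValueError):
    """A slice series on disk does not conform to the dialect."""


@dataclass
class SeriesManifest:
    """Inventory of one on-disk slice series."""

    directory: Path
    slice_filenames: List[str]
    metadata: Dict[str, str] = field(default_factory=dict)


def _slice_name(z: int) -> str:
    return f"slice_{z:04d}.csv"


def _format_value(v: float, precision: Optional[int]) -> str:
    if precision is None:
        return repr(float(v))
    return f"{v:.{precision}f}"


def write_series(
    volume: HUVolume,
    directory: Union[str, os.PathLike],
    precision: Optional[int] = None,
    extra_metadata: Optional[Dict[str, str]] = None,
) -> SeriesManifest:
    """Write a volume as a slice series; returns the manifest.

    *precision* fixes the number of decimals per value; the default writes
    full ``repr`` precision so that reading the series back is bit-exact.
    *extra_metadata* entries are appended to ``metadata.csv`` verbatim.
    """
    directory = Path(directory)
    n_x, n_y, n_z = volume.dims
    if n_z > MAX_SLICES:
        raise SeriesFormatError(
            f"{n_z} slices exceed the 4-digit naming scheme limit of {MAX_SLICES}"
        )
    directory.mkdir(parents=True, exist_ok=True)

    metadata: Dict[str, str] = {
        "n_x": str(n_x),
        "n_y": str(n_y),
        "n_z": str(n_z),
        "pixel_size_x_mm": repr(float(volume.spacing.dx)),
        "pixel_size_y_mm": repr(float(volume.spacing.dy)),
        "slice_thickness_mm": repr(float(volume.spacing.dz)),
    }
    if extra_metadata:
        for k, v in extra_metadata.items():
            if k not in metadata:
                metadata[k] = str(v)

    lines = ["key,value"]
    lines += [f"{k},{v}" for k, v in metadata.items()]
    (directory / METADATA_FILENAME).write_text("\n".join(lines) + "\n", encoding="utf-8")

    slice_filenames = []
    for z in range(n_z):
        name = _slice_name(z)
        rows = [
            ",".join(_format_value(v, precision) for v in row)
            for row in volume.values[z]
        ]
        (directory / name).write_text("\n".join(rows) + "\n", encoding="utf-8")
        slice_filenames.append(name)

    return SeriesManifest(directory, slice_filenames, metadata)


def _parse_metadata(path: Path) -> Dict[str, str]:
    if not path.is_file():
        raise SeriesFormatError(f"missing metadata file {path}")
    metadata: Dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != "key,value":
        raise SeriesFormatError(f"{path}: first line must be the header 'key,value'")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if "," not in line:
            raise SeriesFormatError(f"{path}:{lineno}: expected 'key,value', got {line!r}")
        key, value = line.split(",", 1)
        metadata[key.strip()] = value.strip()
    missing = [k for k in REQUIRED_KEYS if k not in metadata]
    if missing:
        raise SeriesFormatError(f"{path}: missing required metadata keys {missing}")
    return metadata


def _parse_slice(path: Path, n_x: int, n_y: int) -> np.ndarray:
    rows: List[List[float]] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) != n_y:
        raise SeriesFormatError(
            f"{path}: expected {n_y} rows, found {len(lines)}"
        )
    for lineno, line in enumerate(lines, start=1):
        cells = line.split(",")
        if len(cells) != n_x:
            raise SeriesFormatError(
                f"{path}:{lineno}: ragged row — expected {n_x} values, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            bad = next(c for c in cells if not _is_number(c))
            raise SeriesFormatError(
                f"{path}:{lineno}: non-numeric cell {bad!r}"
            ) from None
    return np.asarray(rows, dtype=np.float64)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_manifest(directory: Union[str, os.PathLike]) -> SeriesManifest:
    """Read and validate a series' metadata and slice inventory."""
    directory = Path(directory)
    metadata = _parse_metadata(directory / METADATA_FILENAME)
    try:
        n_z = int(metadata["n_z"])
    except ValueError:
        raise SeriesFormatError(
            f"{directory / METADATA_FILENAME}: n_z must be an integer, got {metadata['n_z']!r}"
        ) from None
    names = [_slice_name(z) for z in range(n_z)]
    missing = [n for n in names if not (directory / n).is_file()]
    if missing:
        raise SeriesFormatError(
            f"{directory}: metadata declares {n_z} slices but "
            f"{len(missing)} are missing (first: {missing[0]})"
        )
    return SeriesManifest(directory, names, metadata)


def read_series(directory: Union[str, os.PathLike]) -> HUVolume:
    """Read a slice series back into an :class:`HUVolume`.

    Errors (missing metadata, slice-count mismatch, ragged rows,
    non-numeric cells) name the offending file and location.
    """
    manifest = read_manifest(directory)
    md = manifest.metadata
    try:
        n_x, n_y, n_z = (int(md[k]) for k in ("n_x", "n_y", "n_z"))
        spacing = VoxelSpacing(
            dx=float(md["pixel_size_x_mm"]),
            dy=float(md["pixel_size_y_mm"]),
            dz=float(md["slice_thickness_mm"]),
        )
    except ValueError as exc:
        raise SeriesFormatError(
            f"{manifest.directory / METADATA_FILENAME}: bad numeric metadata ({exc})"
        ) from None

    slices = [
        _parse_slice(manifest.directory / name, n_x, n_y)
        for name in manifest.slice_filenames
    ]
    values = np.stack(slices, axis=0)
    return HUVolume(values, spacing, declared_dims=(n_x, n_y, n_z))
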