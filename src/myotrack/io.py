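"""Readers and writers for the delimited-text and raster formats.

Track tables are CSV in the dialect of imaging "spots" exports: a header
row, comma separators, decimal points; columns ``track_id, time_min, x_um,
y_um[, z_um]``.  Units are fixed (µm, minutes) — any conversion happens
before the data reaches this boundary.  Output files carry a provenance
header of ``#``-prefixed comment lines (tool version, seed, configuration)
which the readers skip, so every result file is self-describing.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Point3D, Track3D
from .metrics import SheetMask

__all__ = [
    "ParseError",
    "provenance_header",
    "read_tracks",
    "write_table",
    "tracks_from_frame",
    "read_mask",
    "write_mask",
]

TRACK_COLUMNS_3D = ["track_id", "time_min", "x_um", "y_um", "z_um"]
TRACK_COLUMNS_2D = ["track_id", "time_min", "x_um", "y_um"]


class ParseError(ValueError):
    """Malformed input file; the message carries the file line number."""


def provenance_header(seed: int | None = None, config: dict | None = None) -> list[str]:
    """Comment lines identifying tool version, seed and configuration."""
    lines = [f"# myotrack {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config:
        blob = json.dumps(config, sort_keys=True, default=str)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
        lines.append(f"# config={blob}")
        lines.append(f"# config_sha256={digest}")
    return lines


def read_tracks(path: str | Path, dim: int | None = None) -> pd.DataFrame:
    """Read and validate a tracks CSV.

    ``dim`` forces 2 or 3 spatial columns; by default the file decides
    (``z_um`` present or not).  Comment lines (``#``) are skipped.
    Missing columns, unparsable numbers, duplicated ``(track_id, time)``
    pairs and non-increasing times raise :class:`ParseError` naming the
    offending file line.
    """
    path = Path(path)
    rows: list[dict] = []
    line_numbers: list[int] = []
    header: list[str] | None = None
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh), start=1):
            if not raw or (raw[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                continue
            if len(raw) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(raw)}")
            rows.append(dict(zip(header, raw)))
            line_numbers.append(lineno)
    if header is None:
        raise ParseError(f"{path}: empty file")
    want = TRACK_COLUMNS_3D if (dim == 3 or (dim is None and "z_um" in header)) else TRACK_COLUMNS_2D
    missing = [c for c in want if c not in header]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = pd.DataFrame(rows, columns=header)
    for col in want[1:]:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(f"{path}:{line_numbers[bad]}: bad value in {col!r}") from exc
    dup = df.duplicated(subset=["track_id", "time_min"])
    if dup.any():
        bad = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(
            f"{path}:{line_numbers[bad]}: duplicate (track_id, time) pair"
        )
    for _, grp in df.groupby("track_id", sort=False):
        t = grp["time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            bad_pos = int(grp.index[int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1])
            raise ParseError(
                f"{path}:{line_numbers[bad_pos]}: time not strictly increasing"
            )
    return df[want].reset_index(drop=True)


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a tidy table as CSV with a provenance comment header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in provenance_header(seed=seed, config=config):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def tracks_from_frame(df: pd.DataFrame) -> list[Track3D]:
    """Convert a validated tracks table into :class:`Track3D` objects
    (z = 0 for 2D tables)."""
    out = []
    has_z = "z_um" in df.columns
    for tid, grp in df.groupby("track_id", sort=False):
        samples = [
            (
                float(r.time_min),
                Point3D(float(r.x_um), float(r.y_um), float(r.z_um) if has_z else 0.0),
            )
            for r in grp.itertuples()
        ]
        out.append(Track3D(track_id=str(tid), samples=samples))
    return out


def read_mask(
    path: str | Path,
    pixel_size_um: float,
    threshold_window: tuple[float, float] | None = None,
    cell_count: int | None = None,
) -> SheetMask:
    """Read a single-channel raster (TIFF/PNG) as a binary sheet mask.

    Already-binary rasters (values 0/1, or 0/255 for 8-bit PNG
    convenience) pass through; grayscale data needs an explicit
    ``threshold_window`` ``(min, max)`` — pixels inside the window become
    foreground, as in the original 16-bit workflow with window (299, 300).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel raster, got shape {img.shape}")
    values = np.unique(img)
    if threshold_window is not None:
        lo, hi = threshold_window
        binary = (img >= lo) & (img <= hi)
    elif set(values.tolist()) <= {0, 1}:
        binary = img.astype(bool)
    elif set(values.tolist()) <= {0, 255}:
        binary = img > 0
    else:
        raise ValueError(
            f"{path}: raster is not binary; pass threshold_window=(min, max)"
        )
    return SheetMask(mask=binary, pixel_size_um=pixel_size_um, cell_count=cell_count)


def write_mask(mask: SheetMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit (0/255) PNG or TIFF by extension."""
    path = Path(path)
    img = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)
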