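"""Readers and writers for the text and TIFF dialects IMC software exports.

Supported formats:

* **Pixel table** — one row per pixel with ``X``/``Y`` (and optionally ``Z``)
  coordinate columns plus one column per mass channel, tab- or
  comma-separated.  This is the instrument vendor's TXT export.
* **Multi-page TIFF** — one 32-bit float page per channel, the channel label
  stored in the page description.
* **Per-channel CSV grids** — one headerless CSV of the pixel grid per
  channel, the filename carrying the channel label.

The proprietary MCD binary container is deliberately unsupported; the TXT and
TIFF exports are universal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .images import ChannelImage, ImageStack

__all__ = [
    "ChannelHeaderSpec", "parse_channel_header",
    "read_pixel_table", "write_pixel_table",
    "read_tiff_stack", "write_tiff_stack",
    "read_csv_grids", "write_csv_grids",
    "FormatError",
]

logger = logging.getLogger("tellimc.io")


class FormatError(ValueError):
    """A file does not conform to the expected IMC export layout."""


# All IUPAC element symbols; used to reject column names like "Start_push"
# that merely resemble a symbol-digit pattern.
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu".split())

_MASS_FIRST = re.compile(r"^(\d{2,3})([A-Z][a-z]?)")
_ELEMENT_FIRST = re.compile(r"^([A-Z][a-z]?)(\d{2,3})")


@dataclass(frozen=True)
class ChannelHeaderSpec:
    """A parsed channel column header: raw text plus element and mass."""

    raw_header: str
    element: str
    mass: int


def parse_channel_header(header: str) -> ChannelHeaderSpec | None:
    """Parse a channel header in which an element symbol and a 2-3 digit
    mass number co-occur in either order: ``"128Te"``, ``"Te128"``,
    ``"128Te(Te128Di)"``.  Element symbols are case-sensitive.  Returns None
    for headers that are not channel labels (coordinates, push counts, ...).
    """
    header = header.strip()
    m = _MASS_FIRST.match(header)
    if m and m.group(2) in _ELEMENTS:
        return ChannelHeaderSpec(header, m.group(2), int(m.group(1)))
    m = _ELEMENT_FIRST.match(header)
    if m and m.group(1) in _ELEMENTS:
        return ChannelHeaderSpec(header, m.group(1), int(m.group(2)))
    return None


_SEPARATORS = {"tab": "\t", "comma": ","}


def read_pixel_table(path, dialect: str = "tab",
                     pixel_size_um: float = 1.0) -> ImageStack:
    """Read a pixel-table export into an :class:`ImageStack`.

    The table must have a header row with ``X`` and ``Y`` columns and at
    least one parseable channel column; the (X, Y) pairs must tile a complete
    rectangle (row-major raster).  1-based coordinates (min X = min Y = 1)
    are shifted to 0-based with a logged notice.  Unparseable columns are
    skipped with a warning and recorded in stack provenance.
    """
    if dialect not in _SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tab' or 'comma'")
    df = pd.read_csv(path, sep=_SEPARATORS[dialect],
                     float_precision="round_trip")
    for coord in ("X", "Y"):
        if coord not in df.columns:
            raise FormatError(f"pixel table {path} lacks required column {coord}")

    xs = df["X"].to_numpy()
    ys = df["Y"].to_numpy()
    xi = np.rint(xs).astype(np.int64)
    yi = np.rint(ys).astype(np.int64)
    if np.any(np.abs(xs - xi) > 1e-6) or np.any(np.abs(ys - yi) > 1e-6):
        raise FormatError("X/Y coordinates are not integers")
    if xi.size and xi.min() == 1 and yi.min() == 1:
        logger.info("pixel table %s uses 1-based coordinates; shifting to 0-based",
                    path)
        xi -= 1
        yi -= 1
    if xi.size == 0:
        raise FormatError(f"pixel table {path} has no rows")
    if xi.min() < 0 or yi.min() < 0:
        raise FormatError("negative raster coordinates")

    width = int(xi.max()) + 1
    height = int(yi.max()) + 1
    flat = yi * width + xi
    present = np.zeros(height * width, dtype=bool)
    if np.unique(flat).size != flat.size:
        raise FormatError("duplicate (X, Y) pixel coordinates in table")
    present[flat] = True
    if not present.all():
        missing = int(np.flatnonzero(~present)[0])
        raise FormatError(
            f"ragged raster: pixel (X={missing % width}, Y={missing // width}) "
            "is absent")

    channels: list[ChannelImage] = []
    skipped: list[str] = []
    seen: set[tuple[str, int]] = set()
    for col in df.columns:
        if col in ("X", "Y", "Z"):
            if col == "Z":
                skipped.append(col)
            continue
        spec = parse_channel_header(str(col))
        if spec is None or (spec.element, spec.mass) in seen:
            if spec is not None:
                logger.warning("duplicate channel column %r skipped", col)
            else:
                logger.warning("column %r is not a channel header; skipped", col)
            skipped.append(str(col))
            continue
        seen.add((spec.element, spec.mass))
        grid = np.full(height * width, np.nan)
        grid[flat] = df[col].to_numpy(dtype=np.float64)
        channels.append(ChannelImage(grid.reshape(height, width),
                                     spec.element, spec.mass, pixel_size_um))
    if not channels:
        raise FormatError(f"pixel table {path} has no parseable channel columns")
    provenance = {"source": str(path), "format": "pixel_table",
                  "skipped_columns": skipped}
    return ImageStack(channels, provenance)


def write_pixel_table(stack: ImageStack, path, dialect: str = "tab") -> None:
    """Write a stack as a pixel table (inverse of :func:`read_pixel_table`).

    Values are written with full precision so the write/read round trip is
    bit-exact.
    """
    if dialect not in _SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tab' or 'comma'")
    height, width = stack.shape
    yy, xx = np.mgrid[0:height, 0:width]
    data = {"X": xx.ravel(), "Y": yy.ravel()}
    for ch in stack:
        data[ch.label] = ch.pixels.ravel()
    pd.DataFrame(data).to_csv(path, sep=_SEPARATORS[dialect], index=False,
                              float_format="%.17g")


def read_tiff_stack(path, channel_labels: Sequence[str] | None = None,
                    pixel_size_um: float = 1.0) -> ImageStack:
    """Read a multi-page TIFF, one channel per page.

    Labels come from each page's ImageDescription tag, or positionally from
    ``channel_labels`` (which must then match the page count).
    """
    channels: list[ChannelImage] = []
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        n = len(pages)
        if channel_labels is not None and len(channel_labels) != n:
            raise FormatError(
                f"{n} TIFF pages but {len(channel_labels)} labels supplied")
        for i, page in enumerate(pages):
            if channel_labels is not None:
                raw = channel_labels[i]
            else:
                raw = page.description or ""
                if not raw:
                    raise FormatError(
                        f"TIFF page {i} has no label and no override given")
            spec = parse_channel_header(str(raw))
            if spec is None:
                raise FormatError(
                    f"TIFF page {i} label {raw!r} is not a channel header")
            channels.append(ChannelImage(page.asarray().astype(np.float64),
                                         spec.element, spec.mass, pixel_size_um))
    return ImageStack(channels, {"source": str(path), "format": "tiff"})


def write_tiff_stack(stack: ImageStack, path) -> None:
    """Write a stack as a 32-bit float multi-page TIFF.

    One page per channel in stack order, page description ``"NNNEl"`` (mass
    then element).  Round trips bit-exactly through
    :func:`read_tiff_stack` for values representable in float32.
    """
    with tifffile.TiffWriter(path) as writer:
        for ch in stack:
            writer.write(ch.pixels.astype(np.float32),
                         description=ch.label, contiguous=False)


def write_csv_grids(stack: ImageStack, directory) -> list[Path]:
    """Write one headerless CSV grid per channel; filename carries the label."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in stack:
        p = directory / f"{ch.label}.csv"
        np.savetxt(p, ch.pixels, delimiter=",", fmt="%.17g")
        paths.append(p)
    return paths


def read_csv_grids(paths: Sequence, pixel_size_um: float = 1.0) -> ImageStack:
    """Read per-channel CSV grids; each filename stem must be a channel label."""
    channels = []
    for p in paths:
        p = Path(p)
        spec = parse_channel_header(p.stem)
        if spec is None:
            raise FormatError(f"filename {p.name!r} is not a channel label")
        grid = np.loadtxt(p, delimiter=",", ndmin=2)
        channels.append(ChannelImage(grid, spec.element, spec.mass, pixel_size_um))
    if not channels:
        raise FormatError("no CSV grids supplied")
    return ImageStack(channels, {"format": "csv_grids"})
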