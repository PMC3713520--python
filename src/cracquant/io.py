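"""Reading and writing the pipeline's on-disk formats.

Images are single-plane grayscale TIFF (8- or 16-bit); anything else
(multi-plane, RGB, other formats) is rejected rather than guessed. Tables
are comma-delimited UTF-8 with a header row; lines starting with ``#`` are
treated as comments (the pipeline writes provenance there). Manifests are
flat YAML listing per-field file paths, cell_id and condition. Loading
never rescales intensities.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    ChannelAlignmentError,
    MissingChannelError,
    TraceParseError,
    UnsupportedImageError,
)
from .types import CFP, KNOWN_CHANNELS, YFP, FieldOfView, FuraTrace, Image2D

__all__ = [
    "read_image",
    "write_image",
    "load_fov",
    "read_manifest",
    "write_manifest",
    "read_trace_table",
    "write_trace_table",
]


def read_image(path: str | Path, channel: str = "OTHER") -> Image2D:
    """Read a single-plane grayscale TIFF into an :class:`Image2D`.

    Raises :class:`UnsupportedImageError` for non-TIFF files, RGB images or
    multi-plane stacks, naming the offence.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise UnsupportedImageError(
                    f"{path}: multi-plane TIFF ({len(tif.pages)} pages); expected a single plane"
                )
            arr = tif.pages[0].asarray()
    except UnsupportedImageError:
        raise
    except Exception as exc:  # tifffile raises several types for non-TIFF input
        raise UnsupportedImageError(f"{path}: not a readable TIFF file ({exc})") from exc
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path}: expected a 2-D grayscale image, got shape {arr.shape} (RGB/multichannel?)"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedImageError(f"{path}: unsupported sample dtype {arr.dtype}; expected uint8/uint16")
    return Image2D(pixels=arr.astype(float), bit_depth=depth, channel=channel)


def write_image(image: Image2D | np.ndarray, path: str | Path, bit_depth: Optional[int] = None) -> None:
    """Write an image as single-plane grayscale TIFF.

    Values are rounded and clipped to the target bit depth's range
    ([0, 255] or [0, 65535]); writing then reading an integer-valued image
    is the identity on pixel values and bit depth.
    """
    if isinstance(image, Image2D):
        px = image.pixels
        depth = bit_depth if bit_depth is not None else image.bit_depth
    else:
        px = np.asarray(image, dtype=float)
        depth = bit_depth if bit_depth is not None else 16
    if depth == 8:
        out = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    elif depth == 16:
        out = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {depth}")
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def load_fov(entry: Mapping, base_dir: str | Path | None = None) -> FieldOfView:
    """Assemble a :class:`FieldOfView` from one manifest entry.

    The entry must provide ``cell_id``, ``condition`` and per-channel paths
    as keys ``<channel>_path`` (lowercase channel name), at minimum
    ``cfp_path`` and ``yfp_path``. Channel images are dimension-checked.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    cell_id = str(entry.get("cell_id", ""))
    condition = str(entry.get("condition", ""))
    images: dict[str, Image2D] = {}
    for channel in KNOWN_CHANNELS:
        key = f"{channel.lower()}_path"
        if key in entry and entry[key]:
            images[channel] = read_image(base / entry[key], channel=channel)
    for required in (CFP, YFP):
        if required not in images:
            raise MissingChannelError(
                f"manifest entry for cell {cell_id!r} lacks a {required} image path"
            )
    shapes = {ch: im.shape for ch, im in images.items()}
    if len(set(shapes.values())) > 1:
        raise ChannelAlignmentError(
            f"cell {cell_id!r}: channel dimensions disagree: {shapes}"
        )
    return FieldOfView(cell_id=cell_id, condition=condition, images=images)


def read_manifest(path: str | Path) -> list[dict]:
    """Read a YAML manifest: a list of flat key-value field entries."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "fields" in data:
        data = data["fields"]
    if not isinstance(data, list):
        raise TraceParseError(f"{path}: manifest must be a list of entries")
    return data


def write_manifest(entries: Iterable[Mapping], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"fields": [dict(e) for e in entries]}, fh, sort_keys=True)


def read_trace_table(
    path: str | Path,
    t_tg: float,
    t_ca: float,
    bg340: float = 0.0,
    bg380: float = 0.0,
) -> list[FuraTrace]:
    """Read a per-cell Fura-2 table into one :class:`FuraTrace` per cell.

    Expected columns: ``cell_id, time_s`` plus either ``f340, f380`` or a
    precomputed ``ratio`` (optionally ``condition``). Time must be strictly
    increasing within each cell; violations raise :class:`TraceParseError`
    identifying the cell and row.
    """
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "time_s"}
    if not required.issubset(df.columns):
        raise TraceParseError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    has_raw = {"f340", "f380"}.issubset(df.columns)
    if not has_raw and "ratio" not in df.columns:
        raise TraceParseError(f"{path}: need either f340/f380 columns or a ratio column")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        t = sub["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(sub.index[bad[0] + 1])
            raise TraceParseError(
                f"{path}: non-monotone time for cell {cell_id!r} at row {row} "
                f"(t={t[bad[0] + 1]} after t={t[bad[0]]})"
            )
        condition = str(sub["condition"].iloc[0]) if "condition" in sub.columns else ""
        traces.append(
            FuraTrace(
                cell_id=str(cell_id),
                condition=condition,
                time_s=t,
                f340=sub["f340"].to_numpy(dtype=float) if has_raw else None,
                f380=sub["f380"].to_numpy(dtype=float) if has_raw else None,
                ratio=sub["ratio"].to_numpy(dtype=float) if "ratio" in sub.columns else None,
                t_tg=t_tg,
                t_ca=t_ca,
                bg340=bg340,
                bg380=bg380,
            )
        )
    return traces


def write_trace_table(traces: Iterable[FuraTrace], path: str | Path, header_comment: str = "") -> None:
    """Write traces as one long-format CSV (inverse of :func:`read_trace_table`)."""
    frames = []
    for tr in traces:
        cols = {"cell_id": tr.cell_id, "time_s": tr.time_s}
        if tr.f340 is not None and tr.f380 is not None:
            cols["f340"] = tr.f340
            cols["f380"] = tr.f380
        if tr.ratio is not None:
            cols["ratio"] = tr.ratio
        if tr.condition:
            cols["condition"] = tr.condition
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
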