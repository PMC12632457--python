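"""Readers and writers for the external formats the pipeline touches.

Conventions used throughout the package:

* Image stacks are stored ``(channel, z, y, x)``; physical coordinates are
  micrometres with the origin at the corner of voxel ``(0, 0, 0)`` and voxel
  *centers* at ``(i + 0.5) * d`` along each axis.
* Genomic coordinates are 0-based half-open everywhere inside the package;
  conversion from GFF3's 1-based closed convention happens only here, at the
  I/O boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "GenomicInterval",
    "read_stack",
    "write_stack",
    "read_intervals",
    "write_intervals_bed",
    "write_intervals_gff3",
    "read_count_table",
    "write_count_table",
    "write_results",
    "COUNT_TABLE_COLUMNS",
]


@dataclass
class ImageStack:
    """A multi-channel 3D voxel grid with physical voxel dimensions.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)`` holding photon counts.
    voxel_size
        ``(dx, dy, dz)`` in micrometres.
    channel_names
        One label per channel, e.g. ``("membrane", "locus")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("stack data must be (channel, z, y, x)")
        if min(self.data.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            # negative values can arise from read noise on ingest; clip to the
            # physical photon-count domain
            self.data = np.clip(self.data, 0.0, None)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (z, y, x) array."""
        if isinstance(name_or_index, str):
            if name_or_index not in self.channel_names:
                raise KeyError(f"no channel named {name_or_index!r}")
            name_or_index = self.channel_names.index(name_or_index)
        return self.data[name_or_index]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )


# ---------------------------------------------------------------------------
# image stacks (TIFF + JSON sidecar metadata)
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF with a JSON metadata description.

    Voxel size and channel names go into the TIFF ImageDescription tag so the
    file is self-describing on round trip.
    """
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "voxel_size_um": list(stack.voxel_size),
        "channel_names": list(stack.channel_names),
    }
    tifffile.imwrite(
        path, stack.data, description=json.dumps(meta), photometric="minisblack"
    )
    return path


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a z-stack TIFF written by :func:`write_stack` (or compatible).

    Axis order is normalized to ``(channel, z, y, x)``. Voxel size comes from
    the embedded JSON metadata unless ``voxel_size_override`` is given; a file
    with neither is rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 2:
        raise ValueError(f"{path} is not a z-stack (single 2D page)")
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: cannot interpret {data.ndim}-dimensional TIFF")
    voxel_size = voxel_size_override or meta.get("voxel_size_um")
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel size in metadata and no override supplied"
        )
    channel_names = tuple(meta.get("channel_names", ()))
    return ImageStack(data=data, voxel_size=tuple(voxel_size), channel_names=channel_names)


# ---------------------------------------------------------------------------
# genomic intervals (BED / GFF3)
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_GFF3_COLS = [
    "chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff3_name(attributes: str) -> str:
    for key in ("Name", "ID", "gene_id"):
        for part in str(attributes).split(";"):
            if part.strip().startswith(key + "="):
                return part.strip()[len(key) + 1 :]
    return ""


def read_intervals(path: str | Path, format: str = "BED") -> list[GenomicInterval]:
    """Read genomic intervals from BED or GFF3 into the internal convention.

    BED is already 0-based half-open and passes through; GFF3 records
    (1-based, closed) are converted to ``(start - 1, end)``. Records that are
    degenerate after conversion (start >= end) are dropped with a logged
    warning; an empty file yields an empty list.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return out
    if fmt == "BED":
        df.columns = _BED_COLS[: df.shape[1]]
        starts = df["start"].astype(int)
        ends = df["end"].astype(int)
        names = df["name"] if "name" in df else pd.Series([""] * len(df))
        scores = df["score"] if "score" in df else pd.Series([None] * len(df))
        strands = df["strand"] if "strand" in df else pd.Series([None] * len(df))
    else:
        if df.shape[1] != 9:
            raise ValueError(f"{path}: GFF3 requires 9 tab-separated columns")
        df.columns = _GFF3_COLS
        starts = df["start"].astype(int) - 1  # 1-based closed -> 0-based half-open
        ends = df["end"].astype(int)
        names = df["attributes"].map(_gff3_name)
        scores = df["score"]
        strands = df["strand"]
    for i in range(len(df)):
        start, end = int(starts.iloc[i]), int(ends.iloc[i])
        if start >= end or start < 0:
            logger.warning(
                "rejecting degenerate interval %s:%s-%s in %s",
                df["chrom"].iloc[i], start, end, path.name,
            )
            continue
        raw_score = scores.iloc[i]
        score = None
        if raw_score is not None and str(raw_score) not in {".", "nan", "None"}:
            try:
                score = float(raw_score)
            except ValueError:
                score = None
        strand = strands.iloc[i]
        strand = strand if strand in {"+", "-"} else None
        out.append(
            GenomicInterval(
                chrom=str(df["chrom"].iloc[i]), start=start, end=end,
                name=str(names.iloc[i]) if names.iloc[i] is not None else "",
                score=score, strand=strand,
            )
        )
    return out


def write_intervals_gff3(
    intervals: Iterable[GenomicInterval], path: str | Path, feature_type: str = "region"
) -> Path:
    """Write intervals as GFF3 (converting back to 1-based closed coordinates)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            strand = iv.strand or "."
            attrs = f"Name={iv.name}" if iv.name else "."
            fh.write(
                f"{iv.chrom}\t.\t{feature_type}\t{iv.start + 1}\t{iv.end}\t"
                f"{score}\t{strand}\t.\t{attrs}\n"
            )
    return path


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> Path:
    """Write intervals as BED6 (0-based half-open, '.' for missing fields)."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            strand = iv.strand or "."
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")
    return path


# ---------------------------------------------------------------------------
# plating count tables
# ---------------------------------------------------------------------------

COUNT_TABLE_COLUMNS = [
    "sample_id",
    "genotype",
    "colonies_selective",
    "colonies_permissive",
    "dilution_selective",
    "dilution_permissive",
]


def _validate_count_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    for col in ("colonies_selective", "colonies_permissive"):
        vals = df[col].to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{col} must hold non-negative integers")
    for col in ("dilution_selective", "dilution_permissive"):
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError(f"{col} must lie in (0, 1]")
    return df


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plating-count CSV (fluctuation-assay input)."""
    return _validate_count_table(pd.read_csv(path))


def write_count_table(df: pd.DataFrame, path: str | Path) -> Path:
    _validate_count_table(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# result tables + run manifest
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Serialize result tables as CSV plus a JSON run manifest.

    ``tables`` maps a short name (becomes ``<name>.csv``) to a DataFrame.
    The manifest records whatever provenance the caller passes (config, seed,
    exclusion counts) plus package versions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        written[name] = p
    import perinuc

    manifest_out = dict(manifest or {})
    manifest_out.setdefault("versions", {})
    manifest_out["versions"].update(
        {"perinuc": perinuc.__version__, "numpy": np.__version__, "pandas": pd.__version__}
    )
    mp = outdir / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest_out, fh, indent=2, sort_keys=True, default=str)
    written["manifest"] = mp
    return written
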