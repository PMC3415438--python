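"""Tile-based somatic copy-number analysis.

Depth is averaged in non-overlapping 5 kb tiles; tiles with under 80%
uniquely mappable bases (or no normal coverage) are uncallable.  The
tumor/normal depth ratio is normalized by its genome-wide median before
the log2 transform to remove library-size differences.  Runs of two or
more adjacent same-direction tiles beyond the call thresholds are merged
into segments; copy number is purity-adjusted as

    CN = (2 * 2**log2r - 2 * (1 - p)) / p,  clipped at 0.

A segment in one sample is *sample-specific* only when every overlapped
tile in the other sample sits strictly inside (-0.1, 0.1); a single tile
at or beyond +-0.1 makes it shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeIntervals

DEFAULT_TILE_SIZE = 5_000
DEFAULT_MAPPABLE_FRACTION = 0.8
DEFAULT_AMP_THRESHOLD = 0.25
DEFAULT_DEL_THRESHOLD = -0.25
SPECIFICITY_GATE = 0.1


@dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    direction: str            # "amplification" | "deletion"
    mean_log2_ratio: float
    n_tiles: int
    purity_adjusted_cn: float
    specificity: str = "unclassified"


def tile_depths(
    normal_depth: Mapping[str, np.ndarray],
    tumor_depth: Mapping[str, np.ndarray],
    mappability: GenomeIntervals,
    tile_size: int = DEFAULT_TILE_SIZE,
    min_mappable: float = DEFAULT_MAPPABLE_FRACTION,
) -> pd.DataFrame:
    """Per-tile mean depths and normalized log2 tumor/normal ratio.

    ``*_depth`` map chromosome to a per-base retained-depth array.
    ``log2_ratio`` is NaN for uncallable tiles (mappability below
    threshold or zero normal depth).
    """
    rows = []
    for chrom in sorted(normal_depth):
        nd, td = normal_depth[chrom], tumor_depth[chrom]
        L = len(nd)
        n_tiles = L // tile_size
        for t in range(n_tiles):
            s, e = t * tile_size, (t + 1) * tile_size
            mfrac = mappability.overlap_length(chrom, s, e) / tile_size
            rows.append((chrom, s, e, nd[s:e].mean(), td[s:e].mean(), mfrac))
    tiles = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                        "normal_depth", "tumor_depth",
                                        "mappable_fraction"])
    callable_ = (tiles["mappable_fraction"] >= min_mappable) \
        & (tiles["normal_depth"] > 0)
    ratio = np.where(callable_, tiles["tumor_depth"] /
                     tiles["normal_depth"].where(tiles["normal_depth"] > 0, 1.0),
                     np.nan)
    med = np.nanmedian(ratio) if np.isfinite(ratio).any() else 1.0
    if med <= 0 or not np.isfinite(med):
        med = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tiles["log2_ratio"] = np.log2(ratio / med)
    tiles.loc[~callable_, "log2_ratio"] = np.nan
    return tiles


def purity_adjusted_cn(log2_ratio: float, purity: float) -> float:
    """Tumor-cell copy number implied by a bulk log2 ratio at given purity."""
    if purity <= 0:
        return 2.0
    return max((2.0 * 2.0 ** log2_ratio - 2.0 * (1.0 - purity)) / purity, 0.0)


def call_cnv_segments(
    tiles: pd.DataFrame,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    purity: float = 1.0,
    min_tiles: int = 2,
) -> List[CnvSegment]:
    """Merge maximal runs of adjacent same-direction called tiles.

    Runs shorter than ``min_tiles`` are dropped.  Adjacency requires
    tiles to abut (same chromosome, end == next start).
    """
    segments: List[CnvSegment] = []
    for chrom, sub in tiles.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        r = sub["log2_ratio"].to_numpy()
        direction = np.zeros(len(sub), dtype=int)
        with np.errstate(invalid="ignore"):
            direction[r >= amp_threshold] = 1
            direction[r <= del_threshold] = -1
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_start = 0
        for i in range(1, len(sub) + 1):
            boundary = (
                i == len(sub)
                or direction[i] != direction[run_start]
                or starts[i] != ends[i - 1]
            )
            if not boundary:
                continue
            d = direction[run_start]
            n = i - run_start
            if d != 0 and n >= min_tiles:
                mean_r = float(r[run_start:i].mean())
                segments.append(CnvSegment(
                    str(chrom), int(starts[run_start]), int(ends[i - 1]),
                    "amplification" if d > 0 else "deletion",
                    mean_r, n, purity_adjusted_cn(mean_r, purity)))
            run_start = i
    return segments


def sample_specific_filter(
    segments: Iterable[CnvSegment],
    other_tiles: pd.DataFrame,
    gate: float = SPECIFICITY_GATE,
) -> List[CnvSegment]:
    """Label segments sample-specific or shared from the other sample's tiles."""
    out = []
    for seg in segments:
        sub = other_tiles[(other_tiles["chrom"] == seg.chrom)
                          & (other_tiles["start"] < seg.end)
                          & (other_tiles["end"] > seg.start)]
        r = sub["log2_ratio"].to_numpy()
        r = r[np.isfinite(r)]
        shared = bool(len(r)) and bool((np.abs(r) >= gate).any())
        out.append(CnvSegment(seg.chrom, seg.start, seg.end, seg.direction,
                              seg.mean_log2_ratio, seg.n_tiles,
                              seg.purity_adjusted_cn,
                              "shared" if shared else "sample_specific"))
    return out


def non_cnv_mask(
    tiles_a: pd.DataFrame,
    tiles_b: Optional[pd.DataFrame] = None,
    gate: float = SPECIFICITY_GATE,
) -> GenomeIntervals:
    """Tiled territory where both samples sit strictly inside (-gate, gate).

    Uncallable tiles (NaN ratio) are excluded as unknown.
    """
    frames = [tiles_a] if tiles_b is None else [tiles_a, tiles_b]
    bad = GenomeIntervals()
    tiled = GenomeIntervals.from_frame(tiles_a)
    for tiles in frames:
        r = tiles["log2_ratio"].to_numpy()
        outside = ~(np.isfinite(r) & (r > -gate) & (r < gate))
        bad = bad.union(GenomeIntervals.from_frame(tiles[outside]))
    return tiled.subtract(bad)


def segments_to_frame(segments: Iterable[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.direction, s.mean_log2_ratio, s.n_tiles,
          s.purity_adjusted_cn, s.specificity) for s in segments],
        columns=["chrom", "start", "end", "direction", "mean_log2_ratio",
                 "n_tiles", "purity_adjusted_cn", "specificity"])
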