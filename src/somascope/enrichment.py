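"""Block-sampling enrichment of variant positions in genomic features.

The observed statistic is the number of variant positions falling in a
feature set, both restricted to callable territory.  The null preserves
the clustering of the variant set: per chromosome, all positions are
mapped into the compressed coordinate system of the callable territory
and rotated circularly by one uniform random offset per sampling, so
inter-variant spacing is retained exactly.  Enrichment is reported as

    log2( observed / mean(null) )

with the null standard deviation alongside; results with fewer than
``min_overlap`` (default 10) observed overlaps are suppressed as
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeIntervals

DEFAULT_N_SAMPLINGS = 10_000
DEFAULT_MIN_OVERLAP = 10


class EmptyTerritoryError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    label: str
    observed: int
    null_mean: float
    null_sd: float
    n_samplings: int
    n_variants: int
    suppressed: bool

    @property
    def log2_enrichment(self) -> float:
        if self.null_mean <= 0 or self.observed <= 0:
            return float("nan")
        return float(np.log2(self.observed / self.null_mean))

    def to_row(self) -> dict:
        return {
            "label": self.label, "observed": self.observed,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
            "log2_enrichment": self.log2_enrichment,
            "n_samplings": self.n_samplings, "n_variants": self.n_variants,
            "suppressed": self.suppressed,
        }


class Territory:
    """Callable territory with a compressed (gap-free) coordinate system."""

    def __init__(self, intervals: GenomeIntervals):
        if intervals.total_length == 0:
            raise EmptyTerritoryError("territory is empty")
        self.intervals = intervals
        self._starts: Dict[str, np.ndarray] = {}
        self._offsets: Dict[str, np.ndarray] = {}
        self.lengths: Dict[str, int] = {}
        for chrom in intervals.chroms:
            arr = intervals.intervals(chrom)
            lens = arr[:, 1] - arr[:, 0]
            cum = np.concatenate([[0], np.cumsum(lens)])
            self._starts[chrom] = arr[:, 0]
            self._offsets[chrom] = cum
            self.lengths[chrom] = int(cum[-1])

    def compress(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Genome coordinates -> territory coordinates (positions must lie
        inside the territory)."""
        arr = self.intervals.intervals(chrom)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        if (idx < 0).any() or (positions >= arr[idx, 1]).any():
            raise ValueError(f"positions outside territory on {chrom}")
        return self._offsets[chrom][idx] + (positions - self._starts[chrom][idx])

    def compress_edges(self, features: GenomeIntervals, chrom: str) -> np.ndarray:
        """Feature set -> sorted edge array in territory coordinates."""
        clipped = features.intersect(self.intervals)
        arr = clipped.intervals(chrom)
        if len(arr) == 0:
            return np.empty(0, dtype=np.int64)
        ivs = self.intervals.intervals(chrom)
        s_idx = np.searchsorted(ivs[:, 0], arr[:, 0], side="right") - 1
        e_idx = np.searchsorted(ivs[:, 0], arr[:, 1] - 1, side="right") - 1
        starts = self._offsets[chrom][s_idx] + (arr[:, 0] - ivs[s_idx, 0])
        ends = self._offsets[chrom][e_idx] + (arr[:, 1] - ivs[e_idx, 0])
        return np.column_stack([starts, ends]).ravel()


def _count_inside(edges: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Count positions inside [edges] pairs; works on any trailing shape."""
    if len(edges) == 0:
        return np.zeros(positions.shape[:-1], dtype=np.int64) \
            if positions.ndim > 1 else np.int64(0)
    idx = np.searchsorted(edges, positions, side="right")
    return (idx % 2 == 1).sum(axis=-1)


def sample_null(
    positions: Mapping[str, np.ndarray],
    territory: Territory,
    seed: int | np.random.Generator = 0,
    n_samplings: int = 1,
) -> Dict[str, np.ndarray]:
    """Circularly rotated variant positions in territory coordinates.

    Returns chrom -> array of shape (n_samplings, n_variants_on_chrom).
    Offset 0 would reproduce the observed configuration; offsets are
    drawn uniformly from the territory length of each chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = {}
    for chrom in sorted(positions):
        pos = np.asarray(positions[chrom], dtype=np.int64)
        if chrom not in territory.lengths or len(pos) == 0:
            out[chrom] = np.empty((n_samplings, 0), dtype=np.int64)
            continue
        L = territory.lengths[chrom]
        comp = territory.compress(chrom, pos)
        offsets = rng.integers(0, L, size=n_samplings)
        out[chrom] = (comp[None, :] + offsets[:, None]) % L
    return out


def enrichment(
    positions: Mapping[str, np.ndarray],
    features: GenomeIntervals,
    territory: Territory | GenomeIntervals,
    n_samplings: int = DEFAULT_N_SAMPLINGS,
    seed: int | np.random.Generator = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    label: str = "",
) -> EnrichmentResult:
    """Observed vs rotation-null overlap of variants with a feature set."""
    if isinstance(territory, GenomeIntervals):
        territory = Territory(territory)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    observed = 0
    null = np.zeros(n_samplings, dtype=np.int64)
    n_variants = 0
    for chrom in sorted(positions):
        pos = np.asarray(positions[chrom], dtype=np.int64)
        if chrom not in territory.lengths or len(pos) == 0:
            continue
        n_variants += len(pos)
        edges = territory.compress_edges(features, chrom)
        comp = territory.compress(chrom, pos)
        observed += int(_count_inside(edges, comp))
        L = territory.lengths[chrom]
        offsets = rng.integers(0, L, size=n_samplings)
        rotated = (comp[None, :] + offsets[:, None]) % L
        null += _count_inside(edges, rotated)
    return EnrichmentResult(
        label=label, observed=observed,
        null_mean=float(null.mean()), null_sd=float(null.std()),
        n_samplings=n_samplings, n_variants=n_variants,
        suppressed=observed < min_overlap)


def enrichment_profile(
    variant_sets: Mapping[str, Mapping[str, np.ndarray]],
    feature_families: Mapping[str, GenomeIntervals],
    territory: Territory | GenomeIntervals,
    n_samplings: int = DEFAULT_N_SAMPLINGS,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """One EnrichmentResult per (variant set, feature family) pair.

    ``variant_sets`` typically holds the somatic set and a common-SNP
    control; all pairs share the territory.  The rotation stream is
    seeded per feature family (not per variant set), so identical
    variant sets produce identical profiles and different sets are
    compared against paired null rotations.
    """
    if isinstance(territory, GenomeIntervals):
        territory = Territory(territory)
    rows = []
    for set_label, positions in sorted(variant_sets.items()):
        for fi, (feat_label, features) in enumerate(
                sorted(feature_families.items())):
            res = enrichment(
                positions, features, territory, n_samplings=n_samplings,
                seed=np.random.default_rng([seed & 0x7FFFFFFF, fi]),
                min_overlap=min_overlap, label=f"{set_label}:{feat_label}")
            row = res.to_row()
            row["variant_set"] = set_label
            row["feature"] = feat_label
            rows.append(row)
    return pd.DataFrame(rows)


def filter_common_snps(vcf_path, min_maf: float = 0.05) -> Dict[str, np.ndarray]:
    """Positions (0-based, per chromosome) of VCF records with AF-derived
    minor allele frequency >= ``min_maf`` — the common-variant control."""
    import pysam

    by_chrom: Dict[str, list] = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            af = rec.info.get("AF")
            if af is None:
                continue
            af = af[0] if isinstance(af, tuple) else float(af)
            maf = min(af, 1.0 - af)
            if maf >= min_maf:
                by_chrom.setdefault(rec.chrom, []).append(rec.pos - 1)
    return {c: np.asarray(sorted(v), dtype=np.int64)
            for c, v in by_chrom.items()}
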