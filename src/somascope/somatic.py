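"""Somatic SSNV and indel detection from tumor/normal call tables.

A somatic single-nucleotide variant is a site where the tumor's
MPV-called genotype contains an allele absent from the normal's
MPG-called genotype.  Sites whose tumor alleles are a subset of the
normal alleles (loss of heterozygosity) carry no novel somatic allele
and are dropped, as are known-variant positions and positions within
ten bases (inclusive) of a tumor indel call.

Three post-hoc validation filters flag residual artifacts:

* ``normal_lookup`` — the somatic allele is seen in >= 1 normal read at
  any mapping quality >= 1;
* ``indel_proximity`` — an indel called from mapQ >= 1 reads with score
  >= 10 lies within 10 bp;
* ``strand_bias`` — all reads carrying the somatic allele map to one
  strand (requires >= 2 such reads to trigger).

Flagged calls leave the pass set but are retained with their flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genotyper import SiteEvidence
from .intervals import GenomeIntervals

FILTER_NAMES = ("normal_lookup", "indel_proximity", "strand_bias")
DEFAULT_INDEL_WINDOW = 10


def _near_any(chrom: str, pos: np.ndarray, indel_pos: Mapping[str, np.ndarray],
              window: int) -> np.ndarray:
    """True where a position lies within ``window`` (inclusive) of an indel."""
    ip = indel_pos.get(chrom)
    if ip is None or len(ip) == 0:
        return np.zeros(len(pos), dtype=bool)
    ip = np.sort(np.asarray(ip, dtype=np.int64))
    idx = np.searchsorted(ip, pos)
    near = np.zeros(len(pos), dtype=bool)
    left = idx > 0
    near[left] = pos[left] - ip[idx[left] - 1] <= window
    right = idx < len(ip)
    near[right] |= ip[idx[right]] - pos[right] <= window
    return near


def _positions_by_chrom(df: pd.DataFrame) -> Dict[str, np.ndarray]:
    return {str(c): np.sort(sub["pos"].to_numpy(np.int64))
            for c, sub in df.groupby("chrom")} if len(df) else {}


def detect_ssnv(
    tumor_calls: pd.DataFrame,
    normal_calls: pd.DataFrame,
    known_variants: Optional[Iterable[Tuple[str, int]]] = None,
    tumor_indels: Optional[pd.DataFrame] = None,
    indel_window: int = DEFAULT_INDEL_WINDOW,
) -> pd.DataFrame:
    """Tumor-vs-normal subtraction yielding candidate somatic SSNVs.

    ``tumor_calls`` needs columns chrom, pos, ref, genotype (2-letter
    string), mpv_score, callable; ``normal_calls`` needs chrom, pos,
    genotype, callable.  Both must be position-sorted per chromosome.
    """
    for name, df in (("tumor", tumor_calls), ("normal", normal_calls)):
        for chrom, sub in df.groupby("chrom"):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"{name} calls unsorted on {chrom}")
    merged = tumor_calls.merge(
        normal_calls[["chrom", "pos", "genotype", "callable"]],
        on=["chrom", "pos"], suffixes=("", "_normal"))
    merged = merged[merged["callable"] & merged["callable_normal"]]

    def novel_allele(row):
        novel = set(row.genotype) - set(row.genotype_normal)
        return "".join(sorted(novel)) if novel else None

    merged = merged.copy()
    merged["somatic_allele"] = [
        novel_allele(r) for r in merged.itertuples(index=False)]
    merged = merged[merged["somatic_allele"].notna()]
    if len(merged):
        # a multi-allelic novelty keeps its first (alphabetical) allele
        merged["somatic_allele"] = merged["somatic_allele"].str[0]

    if known_variants:
        known = set(known_variants)
        keep = [(c, p) not in known
                for c, p in zip(merged["chrom"], merged["pos"])]
        merged = merged[np.asarray(keep, dtype=bool)]
    if tumor_indels is not None and len(tumor_indels):
        ipos = _positions_by_chrom(tumor_indels)
        drop = np.zeros(len(merged), dtype=bool)
        for chrom, sub in merged.groupby("chrom"):
            mask = _near_any(str(chrom), sub["pos"].to_numpy(np.int64),
                             ipos, indel_window)
            drop[merged["chrom"] == chrom] = mask
        merged = merged[~drop]
    out = merged.rename(columns={"genotype_normal": "normal_genotype"})
    cols = ["chrom", "pos", "ref", "normal_genotype", "genotype",
            "somatic_allele"]
    if "mpv_score" in out.columns:
        cols.append("mpv_score")
    return out[cols].sort_values(["chrom", "pos"]).reset_index(drop=True)


def _site_flags(
    chrom: str,
    pos: int,
    allele: str,
    normal: SiteEvidence,
    tumor: SiteEvidence,
    indel_pos: Mapping[str, np.ndarray],
    indel_window: int,
    min_strand_reads: int,
) -> List[str]:
    flags = []
    if any(r.base == allele and r.mapping_quality >= 1 for r in normal.reads):
        flags.append("normal_lookup")
    near = _near_any(chrom, np.array([pos]), indel_pos, indel_window)[0]
    if near:
        flags.append("indel_proximity")
    alt_strands = [r.strand for r in tumor.reads
                   if r.base == allele and r.mapping_quality >= 1]
    if len(alt_strands) >= min_strand_reads and len(set(alt_strands)) == 1:
        flags.append("strand_bias")
    return flags


def apply_validation_filters(
    variants: pd.DataFrame,
    normal_evidence: Mapping[Tuple[str, int], SiteEvidence],
    tumor_evidence: Mapping[Tuple[str, int], SiteEvidence],
    low_mapq_indels: Iterable[Tuple[str, int]] = (),
    indel_window: int = DEFAULT_INDEL_WINDOW,
    min_strand_reads: int = 2,
) -> pd.DataFrame:
    """Annotate calls with filter flags; ``pass_filters`` marks the clean set."""
    indel_pos: Dict[str, list] = {}
    for chrom, pos in low_mapq_indels:
        indel_pos.setdefault(chrom, []).append(pos)
    indel_arr = {c: np.sort(np.asarray(v, np.int64))
                 for c, v in indel_pos.items()}
    flags_col, pass_col = [], []
    for row in variants.itertuples(index=False):
        key = (row.chrom, row.pos)
        if key not in normal_evidence or key not in tumor_evidence:
            raise KeyError(f"missing evidence at {row.chrom}:{row.pos}")
        flags = _site_flags(row.chrom, row.pos, row.somatic_allele,
                            normal_evidence[key], tumor_evidence[key],
                            indel_arr, indel_window, min_strand_reads)
        flags_col.append(";".join(flags) if flags else "PASS")
        pass_col.append(not flags)
    out = variants.copy()
    out["filter_flags"] = flags_col
    out["pass_filters"] = pass_col
    return out


def common_callable_territory(mask_a: GenomeIntervals,
                              mask_b: GenomeIntervals) -> GenomeIntervals:
    """Territory reliably callable in both samples."""
    return mask_a.intersect(mask_b)


@dataclass
class CallsetComparison:
    n_shared: int
    n_a_only: int
    n_b_only: int

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_a_only + self.n_b_only

    @property
    def fraction_shared(self) -> float:
        return self.n_shared / self.n_union if self.n_union else 0.0

    @property
    def fraction_a_only(self) -> float:
        return self.n_a_only / self.n_union if self.n_union else 0.0

    @property
    def fraction_b_only(self) -> float:
        return self.n_b_only / self.n_union if self.n_union else 0.0


def compare_callsets(
    set_a: Iterable[Tuple[str, int]],
    set_b: Iterable[Tuple[str, int]],
    common_mask: GenomeIntervals,
    cnv_mask: Optional[GenomeIntervals] = None,
) -> CallsetComparison:
    """Concordance of two callsets restricted to shared callable territory.

    When ``cnv_mask`` is given, sites inside it are excluded as well.
    """
    def restrict(calls) -> Set[Tuple[str, int]]:
        kept = set()
        by_chrom: Dict[str, list] = {}
        for chrom, pos in calls:
            by_chrom.setdefault(chrom, []).append(pos)
        for chrom, positions in by_chrom.items():
            arr = np.asarray(positions, dtype=np.int64)
            keep = common_mask.contains(chrom, arr)
            if cnv_mask is not None:
                keep &= ~cnv_mask.contains(chrom, arr)
            for p in arr[keep]:
                kept.add((chrom, int(p)))
        return kept

    a, b = restrict(set_a), restrict(set_b)
    return CallsetComparison(len(a & b), len(a - b), len(b - a))


def detect_somatic_indels(
    tumor_indels: pd.DataFrame,
    normal_indels: pd.DataFrame,
    non_cnv_mask: Optional[GenomeIntervals] = None,
    min_score: float = 10.0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Somatic indels: confident tumor calls not matching the normal call.

    Input tables carry chrom, pos, allele (``+SEQ`` insertion or ``-N``
    deletion), score.  The normal call at a position is its scored
    allele when score >= ``min_score``, else reference.  Restricted to
    the non-CNV mask when given; returns (calls, per-size histogram).
    """
    tum = tumor_indels[tumor_indels["score"] >= min_score]
    normal_call: Dict[Tuple[str, int], str] = {
        (r.chrom, int(r.pos)): r.allele
        for r in normal_indels.itertuples(index=False)
        if r.score >= min_score
    }
    keep = [normal_call.get((r.chrom, int(r.pos))) != r.allele
            for r in tum.itertuples(index=False)]
    out = tum[np.asarray(keep, dtype=bool)].copy() if len(tum) else tum.copy()
    if non_cnv_mask is not None and len(out):
        inside = np.concatenate([
            non_cnv_mask.contains(str(chrom), sub["pos"].to_numpy(np.int64))
            for chrom, sub in out.groupby("chrom", sort=True)
        ])
        out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        out = out[inside]
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)

    def indel_size(allele: str) -> int:
        return len(allele) - 1 if allele.startswith("+") else -int(allele[1:])

    sizes = out["allele"].map(indel_size) if len(out) else pd.Series(dtype=int)
    hist = sizes.value_counts().sort_index()
    out["size"] = sizes
    return out, hist
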