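"""Annotation landscapes: gene models, hierarchical genic partitioning,
chromatin states, non-genic constraint tiles, and mutation-rate summaries.

The genic partition assigns every base (or every query interval) to
exactly one category along the priority chain

    coding > 5' UTR > 3' UTR > intron > TSS-proximal > TSS-distal

where TSS-proximal means within ``tss_window`` (default 5,000 bp) of any
transcription start site and the two TSS categories apply only to
intergenic territory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeIntervals

LANDMARK_ORDER = ("coding", "utr5", "utr3", "intron", "tss_proximal", "tss_distal")
# per-base codes, higher wins
_CODES = {name: code for code, name in enumerate(reversed(LANDMARK_ORDER), start=1)}
_GFF_FEATURE = {
    "coding": "CDS",
    "utr5": "five_prime_UTR",
    "utr3": "three_prime_UTR",
}
DEFAULT_TSS_WINDOW = 5_000
DEFAULT_GENE_MASK_PAD = 10_000
DEFAULT_NONGENIC_TILE = 50_000


class GeneModels:
    """Gene annotation as two frames: gene spans and sub-features.

    ``genes``: gene_id, chrom, start, end, strand.
    ``parts``: gene_id, feature in {exon, CDS, five_prime_UTR,
    three_prime_UTR}, chrom, start, end.  Coordinates 0-based half-open.
    """

    def __init__(self, genes: pd.DataFrame, parts: pd.DataFrame):
        self.genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.parts = parts.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def tss(self) -> pd.DataFrame:
        """One row per gene: chrom, pos (0-based base of transcription start)."""
        pos = np.where(self.genes["strand"] == "+",
                       self.genes["start"], self.genes["end"] - 1)
        return pd.DataFrame({"chrom": self.genes["chrom"], "pos": pos,
                             "strand": self.genes["strand"],
                             "gene_id": self.genes["gene_id"]})

    def spans(self) -> GenomeIntervals:
        return GenomeIntervals.from_frame(self.genes)

    def feature_intervals(self, feature: str) -> GenomeIntervals:
        sub = self.parts[self.parts["feature"] == feature]
        return GenomeIntervals.from_frame(sub)

    def introns(self) -> GenomeIntervals:
        return self.spans().subtract(self.feature_intervals("exon"))

    # -- GFF3 round trip ------------------------------------------------
    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.iterrows():
                fh.write(
                    f"{g.chrom}\tsomascope\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                sub = self.parts[self.parts["gene_id"] == g.gene_id]
                for i, (_, p) in enumerate(sub.iterrows()):
                    fh.write(
                        f"{g.chrom}\tsomascope\t{p.feature}\t{p.start + 1}\t"
                        f"{p.end}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.{p.feature}.{i};Parent={g.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path) -> "GeneModels":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
        genes, parts = [], []
        for g in db.features_of_type("gene"):
            genes.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
            for child in db.children(g.id):
                parts.append((g.id, child.featuretype, child.seqid,
                              child.start - 1, child.end))
        genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start",
                                                "end", "strand"])
        parts_df = pd.DataFrame(parts, columns=["gene_id", "feature", "chrom",
                                                "start", "end"])
        return cls(genes_df, parts_df)


@dataclass
class LandmarkPartition:
    """Mutually exclusive genic categories tiling the genome."""

    categories: Dict[str, GenomeIntervals]
    chrom_lengths: Dict[str, int]

    def territory(self, name: str) -> int:
        return self.categories[name].total_length

    def check_partition(self) -> None:
        """Assert disjointness and exact coverage of the genome."""
        total = sum(self.territory(n) for n in self.categories)
        genome = sum(self.chrom_lengths.values())
        if total != genome:
            raise AssertionError(
                f"partition covers {total} bp of a {genome} bp genome")
        merged = GenomeIntervals()
        for iv in self.categories.values():
            merged = merged.union(iv)
        if merged.total_length != genome:
            raise AssertionError("landmark categories overlap")


def _label_arrays(genes: GeneModels, chrom_lengths: Mapping[str, int],
                  tss_window: int) -> Dict[str, np.ndarray]:
    labels = {c: np.full(n, _CODES["tss_distal"], dtype=np.uint8)
              for c, n in chrom_lengths.items()}

    def paint(chrom, start, end, code):
        if chrom not in labels:
            return
        arr = labels[chrom]
        s, e = max(0, int(start)), min(len(arr), int(end))
        if e > s:
            np.maximum(arr[s:e], code, out=arr[s:e])

    for _, t in genes.tss().iterrows():
        paint(t.chrom, t.pos - tss_window, t.pos + tss_window + 1,
              _CODES["tss_proximal"])
    for _, g in genes.genes.iterrows():
        paint(g.chrom, g.start, g.end, _CODES["intron"])
    for feature, code in (("three_prime_UTR", _CODES["utr3"]),
                          ("five_prime_UTR", _CODES["utr5"]),
                          ("CDS", _CODES["coding"])):
        sub = genes.parts[genes.parts["feature"] == feature]
        for _, p in sub.iterrows():
            paint(p.chrom, p.start, p.end, code)
    return labels


def _runs(codes: np.ndarray) -> Iterable[Tuple[int, int, int]]:
    """(start, end, value) runs of a 1-D code array."""
    if len(codes) == 0:
        return
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(codes)]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), int(codes[s])


def partition_by_landmark(
    genes: GeneModels,
    chrom_lengths: Mapping[str, int],
    target: Optional[GenomeIntervals] = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
):
    """Partition the genome — or classify ``target`` intervals — by landmark.

    Without ``target``, returns a :class:`LandmarkPartition` whose
    categories tile the genome exactly.  With ``target``, returns a
    DataFrame with one row per target interval and its single assigned
    category: the highest-priority category it overlaps by >= 1 bp.
    """
    labels = _label_arrays(genes, chrom_lengths, tss_window)
    code_to_name = {v: k for k, v in _CODES.items()}

    if target is not None:
        rows = []
        for chrom, start, end in target.records():
            if chrom in labels:
                code = int(labels[chrom][start:end].max()) if end > start else 0
            else:
                code = _CODES["tss_distal"]
            rows.append((chrom, start, end, code_to_name.get(code, "tss_distal")))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])

    cats: Dict[str, list] = {name: [] for name in LANDMARK_ORDER}
    for chrom, arr in labels.items():
        for s, e, code in _runs(arr):
            cats[code_to_name[code]].append((chrom, s, e))
    return LandmarkPartition(
        {name: GenomeIntervals.from_records(recs) for name, recs in cats.items()},
        dict(chrom_lengths),
    )


def chromatin_state_mask(
    segmentation: pd.DataFrame,
    drop_states: Sequence[int] = (14, 15),
) -> Dict[int, GenomeIntervals]:
    """Per-state interval sets, with repeat-dominated states removed."""
    out: Dict[int, GenomeIntervals] = {}
    for state, sub in segmentation.groupby("state"):
        if int(state) in drop_states:
            continue
        out[int(state)] = GenomeIntervals.from_frame(sub)
    return out


def nongenic_constraint_bins(
    genes: GeneModels,
    constrained: GenomeIntervals,
    chrom_lengths: Mapping[str, int],
    mask_pad: int = DEFAULT_GENE_MASK_PAD,
    tile_size: int = DEFAULT_NONGENIC_TILE,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Constraint-sorted non-genic tiles split into ``n_bins`` bins.

    Masks everything within ``mask_pad`` of any part of a gene, tiles the
    remainder with non-overlapping ``tile_size`` windows, scores each by
    its constrained-base fraction, drops zero-overlap tiles, sorts
    ascending and bins into equal groups with the remainder going to the
    last bin.
    """
    allowed = GenomeIntervals.whole_genome(dict(chrom_lengths)).subtract(
        genes.spans().expand(mask_pad, dict(chrom_lengths)))
    rows = []
    for chrom, start, end in allowed.records():
        for s in range(start, end - tile_size + 1, tile_size):
            frac = constrained.overlap_length(chrom, s, s + tile_size) / tile_size
            rows.append((chrom, s, s + tile_size, frac))
    tiles = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                        "constrained_fraction"])
    tiles = tiles[tiles["constrained_fraction"] > 0].reset_index(drop=True)
    tiles = tiles.sort_values(
        ["constrained_fraction", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)
    n = len(tiles)
    size = n // n_bins
    if size == 0:
        tiles["bin"] = 0
    else:
        tiles["bin"] = np.minimum(np.arange(n) // size, n_bins - 1)
    return tiles


def regress_mutation_rate(
    table: pd.DataFrame,
    response: str = "rate",
    covariates: Sequence[str] = ("constraint", "gc", "transcribed"),
) -> dict:
    """OLS of per-bin mutation accumulation on annotation covariates.

    Returns the fitted coefficient table, R^2, and the Spearman rank
    correlation of the response against the transcribed-fraction
    covariate (the transcription-coupled-repair signal).
    """
    import statsmodels.api as sm

    X = sm.add_constant(table[list(covariates)].astype(float))
    model = sm.OLS(table[response].astype(float), X).fit()
    coef = pd.DataFrame({
        "coef": model.params,
        "stderr": model.bse,
        "t": model.tvalues,
        "p": model.pvalues,
    })
    rho = p = np.nan
    if "transcribed" in covariates and len(table) > 2:
        rho, p = stats.spearmanr(table[response], table["transcribed"])
    return {"coefficients": coef, "r_squared": float(model.rsquared),
            "spearman_transcribed": (float(rho), float(p)), "model": model}


def transcript_distance_profile(
    positions: Mapping[str, np.ndarray],
    genes: GeneModels,
    bin_size: int = 5_000,
) -> pd.DataFrame:
    """Mutation rate versus distance from the TSS along each transcript.

    Distance runs in the direction of transcription, so minus-strand
    genes are measured right-to-left.  Rates are per-Mb of transcript
    territory falling in each bin; bases in several genes count toward
    each.
    """
    counts: Dict[int, int] = {}
    territory: Dict[int, int] = {}
    for _, g in genes.genes.iterrows():
        length = g.end - g.start
        # transcript territory per distance bin
        for b in range(0, length, bin_size):
            nb = min(bin_size, length - b)
            territory[b // bin_size] = territory.get(b // bin_size, 0) + nb
        pos = np.asarray(positions.get(g.chrom, ()), dtype=np.int64)
        inside = pos[(pos >= g.start) & (pos < g.end)]
        dist = inside - g.start if g.strand == "+" else g.end - 1 - inside
        for d in dist:
            counts[int(d) // bin_size] = counts.get(int(d) // bin_size, 0) + 1
    rows = [
        (b * bin_size, counts.get(b, 0), territory[b],
         1e6 * counts.get(b, 0) / territory[b])
        for b in sorted(territory)
    ]
    return pd.DataFrame(rows, columns=["distance_bin_start", "n_variants",
                                       "territory_bp", "rate_per_mb"])


def per_state_rate(
    positions: Mapping[str, np.ndarray],
    state_sets: Mapping[int, GenomeIntervals],
) -> pd.DataFrame:
    """SSNVs per megabase of territory for each annotation state."""
    rows = []
    for state in sorted(state_sets):
        iv = state_sets[state]
        n = sum(int(iv.contains(c, p).sum()) for c, p in positions.items())
        terr = iv.total_length
        rate = 1e6 * n / terr if terr else 0.0
        rows.append((state, n, terr, rate))
    return pd.DataFrame(rows, columns=["state", "n_variants", "territory_bp",
                                       "rate_per_mb"])


def positions_by_chrom(df: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Variant table -> dict of sorted position arrays per chromosome."""
    return {str(c): np.sort(sub["pos"].to_numpy(dtype=np.int64))
            for c, sub in df.groupby("chrom")}
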