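"""Synthetic tumor/normal genomes with known truth.

The generator emulates the statistical structure the pipeline assumes:
diploid germline genotypes, clonal somatic substitutions with a
UV-biased C>T / G>A spectrum at a chosen rate per megabase, copy-number
segments, normal-cell admixture at a chosen purity, Phred-driven
sequencing error, and a random annotation landscape (gene models,
chromatin states, per-cell-type DHS sets, constrained regions,
mappability, RNA read intervals).

Evidence is generated per site as count tensors indexed by
``(base, base-quality class, mapping-quality class, strand)`` rather
than as individual reads; :meth:`PileupTable.site_evidence` expands a
column back into per-read observations.  Defaults follow the study
conditions the pipeline was built for: ~42 somatic SSNVs per Mb, a
tissue purity of 0.58 (42% normal cells), and ~30x retained coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotyper import BASES, ReadObs, SiteEvidence
from .features import GeneModels
from .intervals import GenomeIntervals

# 29 cell lines of the DHS atlas the analysis was designed around.
DEFAULT_CELL_TYPES: Tuple[str, ...] = (
    "AosmcSerumfree", "Chorion", "Fibrobl", "Fibrop", "Gm12878", "Gm12891",
    "Gm12892", "Gm18507", "Gm19238", "Gm19239", "Gm19240", "H1hesc", "H9es",
    "Helas3Ifna4h", "Helas3", "Hepg2", "Hsmm", "Hsmmt", "Huvec", "K562",
    "Lhsr", "LhsrAndro", "Mcf7", "Medullo", "Melano", "Myometr", "Nhek",
    "Panislets", "Progfib",
)

_OTHER = np.array([[b for b in range(4) if b != r] for r in range(4)])


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs for the synthetic tumor/normal study."""

    genome_length: int = 1_000_000      # bases per synthetic chromosome
    n_chroms: int = 1
    germline_het_rate: float = 6.7e-4   # per-base heterozygosity
    somatic_rate: float = 42.0          # SSNVs per Mb (background passenger rate)
    uv_fraction: float = 0.7            # fraction of somatic SSNVs that are C>T/G>A
    purity: float = 0.58                # tumor-cell fraction (tissue: 42% normal)
    mean_depth: float = 30.0
    normal_mean_depth: Optional[float] = None  # defaults to mean_depth
    base_q_model: Tuple[Tuple[int, float], ...] = (
        (10, 0.05), (20, 0.15), (30, 0.30), (40, 0.50))
    low_mapq_fraction: float = 0.05     # two-point mapQ mixture: low (10) vs high (37)
    mapq_values: Tuple[int, int] = (10, 37)
    base_composition: Tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    cnv_spec: Tuple[Tuple[Tuple[str, int, int], int], ...] = ()
    strand_artifact_rate: float = 0.0   # artifact SSNVs per Mb, alt reads one strand
    germline_indel_rate: float = 10.0   # per Mb
    somatic_indel_rate: float = 2.0     # per Mb
    # annotation landscape
    genes_per_mb: float = 8.0
    dhs_cell_types: Tuple[str, ...] = DEFAULT_CELL_TYPES
    dhs_clusters_per_mb: float = 30.0
    dhs_ubiquitous_fraction: float = 0.2
    dhs_clade_fraction: float = 0.3
    dhs_width: int = 200
    dhs_jitter: int = 20
    dhs_focal_cell_type: str = "Melano"
    dhs_transcribed_prob_focal: float = 0.6
    dhs_transcribed_prob_other: float = 0.2
    constrained_fraction: float = 0.05
    unmappable_fraction: float = 0.05
    transcribed_gene_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_chroms <= 0:
            raise ConfigurationError("genome_length and n_chroms must be positive")
        if not 0.0 <= self.purity <= 1.0:
            raise ConfigurationError("purity must lie in [0, 1]")
        if self.somatic_rate < 0:
            raise ConfigurationError("somatic_rate must be non-negative")
        if abs(sum(p for _, p in self.base_q_model) - 1.0) > 1e-9:
            raise ConfigurationError("base_q_model probabilities must sum to 1")
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for (chrom, start, end), cn in self.cnv_spec:
            if cn < 0 or end <= start:
                raise ConfigurationError(f"bad cnv_spec entry {(chrom, start, end, cn)}")
            spans.setdefault(chrom, []).append((start, end))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ConfigurationError(f"cnv_spec intervals overlap on {chrom}")

    @property
    def chrom_names(self) -> Tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}

    @property
    def normal_depth(self) -> float:
        return self.normal_mean_depth if self.normal_mean_depth is not None \
            else self.mean_depth


@dataclass
class TruthSet:
    """Planted ground truth for one simulated tumor/normal pair."""

    germline: pd.DataFrame       # chrom, pos, ref, genotype (e.g. "AC")
    somatic: pd.DataFrame        # chrom, pos, ref, alt, cell_fraction, artifact
    cnv_segments: Tuple[Tuple[Tuple[str, int, int], int], ...]
    purity: float
    germline_indels: pd.DataFrame  # chrom, pos, allele
    somatic_indels: pd.DataFrame


@dataclass
class PileupTable:
    """Per-site read-count tensors for one sample.

    ``counts[chrom]`` has shape ``(L, 4, n_qual, 2, 2)`` indexed by
    (position, base, quality class, mapQ class low/high, strand +/-).
    """

    sample: str
    ref: Dict[str, np.ndarray]
    counts: Dict[str, np.ndarray]
    qual_values: Tuple[int, ...]
    mapq_values: Tuple[int, int]

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self.counts))

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.ref.items()}

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=(1, 2, 3, 4))

    def retained_counts(self, chrom: str, min_mapq: int = 30) -> np.ndarray:
        """(L, 4, n_qual) counts from reads passing the mapQ threshold."""
        keep = [i for i, m in enumerate(self.mapq_values) if m >= min_mapq]
        return self.counts[chrom][:, :, :, keep, :].sum(axis=(3, 4))

    def retained_counts_at(self, chrom: str, positions: np.ndarray,
                           min_mapq: int = 30) -> np.ndarray:
        """(n, 4, n_qual) counts at selected positions, mapQ-filtered."""
        keep = [i for i, m in enumerate(self.mapq_values) if m >= min_mapq]
        sub = self.counts[chrom][np.asarray(positions, dtype=np.int64)]
        return sub[:, :, :, keep, :].sum(axis=(3, 4))

    def retained_depth(self, chrom: str, min_mapq: int = 30,
                       min_baseq: int = 20) -> np.ndarray:
        c = self.retained_counts(chrom, min_mapq)
        keep_q = np.asarray(self.qual_values) >= min_baseq
        return c[:, :, keep_q].sum(axis=(1, 2))

    def site_evidence(self, chrom: str, pos: int) -> SiteEvidence:
        """Expand one pileup column into per-read observations."""
        col = self.counts[chrom][pos]
        reads = []
        for b, q, m, s in zip(*np.nonzero(col)):
            for _ in range(int(col[b, q, m, s])):
                reads.append(ReadObs(BASES[b], int(self.qual_values[q]),
                                     int(self.mapq_values[m]), "+-"[s]))
        return SiteEvidence(chrom, int(pos),
                            BASES[int(self.ref[chrom][pos])], reads)

    def allele_strand_counts(self, chrom: str, pos: int, base: str,
                             min_mapq: int = 1) -> Tuple[int, int]:
        """(plus, minus) read counts carrying ``base`` at mapQ >= threshold."""
        from .genotyper import BASE_INDEX
        keep = [i for i, m in enumerate(self.mapq_values) if m >= min_mapq]
        col = self.counts[chrom][pos, BASE_INDEX[base]][:, keep, :]
        per_strand = col.sum(axis=(0, 1))
        return int(per_strand[0]), int(per_strand[1])


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def simulate_reference(config: SimulationConfig) -> Dict[str, np.ndarray]:
    """One uint8-coded sequence (A=0..T=3) per chromosome."""
    rng = _rng(config, 0)
    comp = np.asarray(config.base_composition, dtype=float)
    comp = comp / comp.sum()
    return {c: rng.choice(4, size=config.genome_length, p=comp).astype(np.uint8)
            for c in config.chrom_names}


def decode_reference(ref: Mapping[str, np.ndarray]) -> Dict[str, str]:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {c: lut[a].tobytes().decode() for c, a in ref.items()}


def _cn_array(config: SimulationConfig, chrom: str, length: int) -> np.ndarray:
    cn = np.full(length, 2, dtype=np.int16)
    for (c, start, end), copies in config.cnv_spec:
        if c == chrom:
            cn[start:end] = copies
    return cn


def simulate_truth(ref: Mapping[str, np.ndarray],
                   config: SimulationConfig) -> TruthSet:
    rng = _rng(config, 1)
    germ_rows, som_rows, gind_rows, sind_rows = [], [], [], []
    mb = config.genome_length / 1e6
    for chrom in config.chrom_names:
        codes = ref[chrom]
        L = len(codes)
        n_het = rng.binomial(L, config.germline_het_rate)
        het_pos = np.sort(rng.choice(L, size=n_het, replace=False))
        taken = set(int(p) for p in het_pos)
        for p in het_pos:
            r = BASES[codes[p]]
            alt = rng.choice([b for b in BASES if b != r])
            if rng.random() < 2 / 3:
                gt = "".join(sorted((r, alt)))
            else:
                gt = alt + alt
            germ_rows.append((chrom, int(p), r, gt))

        def free_position(candidates: np.ndarray) -> int:
            while True:
                p = int(rng.choice(candidates))
                if p not in taken:
                    taken.add(p)
                    return p

        cg_sites = np.flatnonzero((codes == 1) | (codes == 2))
        all_sites = np.arange(L)
        n_som = rng.poisson(config.somatic_rate * mb)
        for _ in range(n_som):
            if rng.random() < config.uv_fraction and len(cg_sites):
                p = free_position(cg_sites)
                r = BASES[codes[p]]
                alt = "T" if r == "C" else "A"
            else:
                p = free_position(all_sites)
                r = BASES[codes[p]]
                alt = rng.choice([b for b in BASES if b != r])
            som_rows.append((chrom, p, r, alt, 1.0, False))
        n_art = rng.poisson(config.strand_artifact_rate * mb)
        for _ in range(n_art):
            p = free_position(all_sites)
            r = BASES[codes[p]]
            alt = rng.choice([b for b in BASES if b != r])
            som_rows.append((chrom, p, r, alt, 1.0, True))

        for rows, rate in ((gind_rows, config.germline_indel_rate),
                           (sind_rows, config.somatic_indel_rate)):
            for _ in range(rng.poisson(rate * mb)):
                p = free_position(all_sites)
                if rng.random() < 0.5:
                    size = int(rng.integers(1, 4))
                    allele = "+" + "".join(rng.choice(list(BASES), size))
                else:
                    allele = f"-{int(rng.integers(1, 4))}"
                rows.append((chrom, p, allele))

    germline = pd.DataFrame(germ_rows, columns=["chrom", "pos", "ref", "genotype"])
    somatic = pd.DataFrame(som_rows, columns=["chrom", "pos", "ref", "alt",
                                              "cell_fraction", "artifact"])
    somatic = somatic.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return TruthSet(
        germline=germline.sort_values(["chrom", "pos"]).reset_index(drop=True),
        somatic=somatic,
        cnv_segments=tuple(config.cnv_spec),
        purity=config.purity,
        germline_indels=pd.DataFrame(gind_rows, columns=["chrom", "pos", "allele"]),
        somatic_indels=pd.DataFrame(sind_rows, columns=["chrom", "pos", "allele"]),
    )


def _background_counts(rng, depth, ref_codes, qual_values, pq, low_frac):
    """Vectorized hom-ref pileup columns for a whole chromosome."""
    L = len(ref_codes)
    nq = len(qual_values)
    counts = np.zeros((L, 4, nq, 2, 2), dtype=np.int16)
    cell_p = []
    for qi in range(nq):
        for mi, pm in enumerate((low_frac, 1.0 - low_frac)):
            for si in range(2):
                cell_p.append((qi, mi, si, pq[qi] * pm * 0.5))
    remaining = depth.astype(np.int64).copy()
    rem_p = 1.0
    ar = np.arange(L)
    errs = 10.0 ** (-np.asarray(qual_values, dtype=float) / 10.0)
    b1, b2, b3 = (_OTHER[ref_codes, k] for k in range(3))
    for qi, mi, si, pc in cell_p[:-1]:
        n_cell = rng.binomial(remaining, min(pc / rem_p, 1.0))
        remaining -= n_cell
        rem_p -= pc
        _fill_cell(rng, counts, ar, ref_codes, b1, b2, b3, n_cell,
                   errs[qi], qi, mi, si)
    qi, mi, si, _ = cell_p[-1]
    _fill_cell(rng, counts, ar, ref_codes, b1, b2, b3, remaining,
               errs[qi], qi, mi, si)
    return counts


def _fill_cell(rng, counts, ar, ref_codes, b1, b2, b3, n_cell, e, qi, mi, si):
    err = rng.binomial(n_cell, e)
    e1 = rng.binomial(err, 1.0 / 3.0)
    e2 = rng.binomial(err - e1, 0.5)
    e3 = err - e1 - e2
    counts[ar, ref_codes, qi, mi, si] += (n_cell - err).astype(np.int16)
    counts[ar, b1, qi, mi, si] += e1.astype(np.int16)
    counts[ar, b2, qi, mi, si] += e2.astype(np.int16)
    counts[ar, b3, qi, mi, si] += e3.astype(np.int16)


def _tumor_allele_weights(rng, gt_codes, som_alt, cn, cell_fraction, purity):
    """Expected per-base read weights at one tumor variant site."""
    copies_n = np.zeros(4)
    for a in gt_codes:
        copies_n[a] += 1.0
    copies_t = np.zeros(4)
    if som_alt is not None:
        # somatic site on a hom-ref germline background: alt on one copy
        ref_code = gt_codes[0]
        f = cell_fraction
        alt_copies = min(1, cn)
        copies_t[som_alt] += f * alt_copies
        copies_t[ref_code] += f * (cn - alt_copies) + (1 - f) * cn
    elif gt_codes[0] == gt_codes[1]:
        copies_t[gt_codes[0]] = cn
    else:
        base, extra = divmod(cn, 2)
        copies_t[gt_codes[0]] += base
        copies_t[gt_codes[1]] += base
        if extra:
            copies_t[gt_codes[int(rng.integers(2))]] += extra
    w = purity * copies_t + (1 - purity) * copies_n
    total = w.sum()
    if total <= 0:
        w = copies_n.copy()
        total = w.sum() or 1.0
    return w / total


def _variant_column(rng, d, weights, qual_values, pq, errs, low_frac,
                    nq, artifact_alt=None):
    col = np.zeros((4, nq, 2, 2), dtype=np.int16)
    if d == 0:
        return col
    template = rng.choice(4, size=d, p=weights)
    qi = rng.choice(nq, size=d, p=pq)
    mi = (rng.random(d) >= low_frac).astype(np.int8)
    si = rng.integers(0, 2, size=d).astype(np.int8)
    flip = rng.random(d) < errs[qi]
    base = template.copy()
    if flip.any():
        base[flip] = (template[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
    if artifact_alt is not None:
        si[base == artifact_alt] = 0
    np.add.at(col, (base, qi, mi, si), 1)
    return col


def simulate_pileups(ref: Mapping[str, np.ndarray], truth: TruthSet,
                     config: SimulationConfig) -> Tuple[PileupTable, PileupTable]:
    """Generate (normal, tumor) evidence tables consistent with the truth."""
    from .genotyper import BASE_INDEX

    qual_values = tuple(q for q, _ in config.base_q_model)
    pq = np.asarray([p for _, p in config.base_q_model], dtype=float)
    pq = pq / pq.sum()
    errs = 10.0 ** (-np.asarray(qual_values, dtype=float) / 10.0)
    nq = len(qual_values)
    p = config.purity

    germ_by_chrom = {c: sub for c, sub in truth.germline.groupby("chrom")}
    som_by_chrom = {c: sub for c, sub in truth.somatic.groupby("chrom")}

    tables = []
    for sample_idx, sample in enumerate(("normal", "tumor")):
        counts = {}
        for chrom_idx, chrom in enumerate(config.chrom_names):
            codes = np.asarray(ref[chrom])
            if codes.max(initial=0) > 3:
                raise ValueError("reference codes out of range")
            L = len(codes)
            rng = _rng(config, 2 + sample_idx, chrom_idx)
            if sample == "tumor":
                cn = _cn_array(config, chrom, L)
                lam = config.mean_depth * (p * cn / 2.0 + (1 - p))
            else:
                cn = None
                lam = np.full(L, config.normal_depth)
            depth = rng.poisson(lam)
            cc = _background_counts(rng, depth, codes, qual_values, pq,
                                    config.low_mapq_fraction)
            # overwrite variant-site columns (order fixed for determinism)
            sites = []
            germ = germ_by_chrom.get(chrom)
            if germ is not None:
                for _, row in germ.iterrows():
                    gt_codes = tuple(BASE_INDEX[a] for a in row.genotype)
                    sites.append((int(row.pos), gt_codes, None, 1.0, False))
            if sample == "tumor":
                som = som_by_chrom.get(chrom)
                if som is not None:
                    for _, row in som.iterrows():
                        rc = BASE_INDEX[row.ref]
                        sites.append((int(row.pos), (rc, rc),
                                      BASE_INDEX[row.alt],
                                      float(row.cell_fraction), bool(row.artifact)))
            sites.sort(key=lambda t: t[0])
            for pos, gt_codes, som_alt, cf, artifact in sites:
                if pos < 0 or pos >= L:
                    raise IndexError(f"variant position {pos} outside {chrom}")
                site_cn = int(cn[pos]) if cn is not None else 2
                if sample == "tumor":
                    w = _tumor_allele_weights(rng, gt_codes, som_alt,
                                              site_cn, cf, p)
                else:
                    w = np.zeros(4)
                    for a in gt_codes:
                        w[a] += 0.5
                cc[pos] = _variant_column(
                    rng, int(depth[pos]), w, qual_values, pq, errs,
                    config.low_mapq_fraction, nq,
                    artifact_alt=som_alt if artifact else None)
            counts[chrom] = cc
        tables.append(PileupTable(sample, {c: np.asarray(ref[c]) for c in
                                           config.chrom_names},
                                  counts, qual_values, config.mapq_values))
    return tables[0], tables[1]


# ----------------------------------------------------------------------
# Annotation landscape
# ----------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    genes: GeneModels
    chromatin: pd.DataFrame             # chrom, start, end, state (1..15)
    dhs: Dict[str, GenomeIntervals]     # cell type -> peak set
    dhs_truth: pd.DataFrame             # chrom, start, end, members, transcribed
    constrained: GenomeIntervals
    mappability: GenomeIntervals
    rna: pd.DataFrame                   # chrom, start, end, mapq


def default_clades(cell_types: Sequence[str]) -> List[List[str]]:
    """Group cell types into clades; GM lymphoblastoids form one clade."""
    gm = [c for c in cell_types if c.startswith("Gm")]
    rest = [c for c in cell_types if not c.startswith("Gm")]
    clades = [gm] if gm else []
    step = max(1, len(rest) // 4)
    clades.extend(rest[i:i + step] for i in range(0, len(rest), step))
    return [c for c in clades if c]


def simulate_annotations(ref: Mapping[str, np.ndarray],
                         config: SimulationConfig) -> AnnotationBundle:
    rng = _rng(config, 4)
    chrom_lengths = {c: len(ref[c]) for c in config.chrom_names}
    genes = _simulate_genes(rng, chrom_lengths, config)
    chromatin = _simulate_chromatin(rng, chrom_lengths)
    dhs, dhs_truth = _simulate_dhs(rng, chrom_lengths, config)
    constrained = _random_intervals(rng, chrom_lengths,
                                    config.constrained_fraction, 100, 500)
    holes = _random_intervals(rng, chrom_lengths,
                              config.unmappable_fraction, 2_000, 20_000)
    mappability = GenomeIntervals.whole_genome(chrom_lengths).subtract(holes)
    rna = _simulate_rna(rng, genes, dhs_truth, config)
    return AnnotationBundle(genes, chromatin, dhs, dhs_truth,
                            constrained, mappability, rna)


def _simulate_genes(rng, chrom_lengths, config) -> GeneModels:
    gene_rows, part_rows = [], []
    gid = 0
    for chrom, L in chrom_lengths.items():
        n = int(round(L / 1e6 * config.genes_per_mb))
        cursor = int(rng.integers(0, 20_000)) if L > 40_000 else 0
        for _ in range(n):
            length = int(rng.integers(5_000, 30_000))
            gap = int(rng.integers(10_000, 60_000))
            start = cursor + gap
            end = start + length
            if end >= L:
                break
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            gene_id = f"gene{gid}"
            gene_rows.append((gene_id, chrom, start, end, strand))
            part_rows.extend(_gene_parts(rng, gene_id, chrom, start, end, strand))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                             "end", "strand"])
    parts = pd.DataFrame(part_rows, columns=["gene_id", "feature", "chrom",
                                             "start", "end"])
    return GeneModels(genes, parts)


def _gene_parts(rng, gene_id, chrom, start, end, strand):
    length = end - start
    n_exons = int(rng.integers(2, 7))
    exon_lens = rng.integers(100, 400, size=n_exons)
    while exon_lens.sum() > 0.6 * length and n_exons > 2:
        n_exons -= 1
        exon_lens = exon_lens[:n_exons]
    intron_total = length - int(exon_lens.sum())
    gaps = 50 + rng.multinomial(max(intron_total - 50 * (n_exons - 1), 0),
                                np.ones(n_exons - 1) / (n_exons - 1))
    exons = []
    s = start
    for i in range(n_exons):
        exons.append((s, s + int(exon_lens[i])))
        s = exons[-1][1] + (int(gaps[i]) if i < n_exons - 1 else 0)
    shift = end - exons[-1][1]
    exons = [(a + shift if i == n_exons - 1 else a,
              b + shift if i == n_exons - 1 else b)
             for i, (a, b) in enumerate(exons)]
    u5 = int(rng.integers(20, min(120, exons[0][1] - exons[0][0])))
    u3 = int(rng.integers(20, min(120, exons[-1][1] - exons[-1][0])))
    if strand == "-":
        u5, u3 = u3, u5
    cds_start = exons[0][0] + u5
    cds_end = exons[-1][1] - u3
    rows = []
    for a, b in exons:
        rows.append((gene_id, "exon", chrom, a, b))
        ca, cb = max(a, cds_start), min(b, cds_end)
        if cb > ca:
            rows.append((gene_id, "CDS", chrom, ca, cb))
    left = (gene_id, "five_prime_UTR" if strand == "+" else "three_prime_UTR",
            chrom, exons[0][0], cds_start)
    right = (gene_id, "three_prime_UTR" if strand == "+" else "five_prime_UTR",
             chrom, cds_end, exons[-1][1])
    rows.extend([left, right])
    return rows


#: Chromatin-state frequencies: states 1-12 functional, 13 = low-signal
#: heterochromatin (dominant), 14/15 repeat-dominated and rare.
_STATE_PROBS = np.array([0.046] * 12 + [0.445, 0.0015, 0.0015])


def _simulate_chromatin(rng, chrom_lengths, mean_seg=10_000) -> pd.DataFrame:
    rows = []
    probs = _STATE_PROBS / _STATE_PROBS.sum()
    for chrom, L in chrom_lengths.items():
        pos = 0
        while pos < L:
            seg = min(int(max(200, rng.exponential(mean_seg))), L - pos)
            state = int(rng.choice(15, p=probs)) + 1
            rows.append((chrom, pos, pos + seg, state))
            pos += seg
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def _simulate_dhs(rng, chrom_lengths, config):
    cell_types = list(config.dhs_cell_types)
    clades = default_clades(cell_types)
    width, jitter = config.dhs_width, config.dhs_jitter
    spacing = width + 2 * jitter + 200
    p_ubiq = config.dhs_ubiquitous_fraction
    p_clade = config.dhs_clade_fraction
    sets: Dict[str, list] = {ct: [] for ct in cell_types}
    truth_rows = []
    for chrom, L in chrom_lengths.items():
        n = int(round(L / 1e6 * config.dhs_clusters_per_mb))
        n_slots = max(L // spacing - 1, 0)
        n = min(n, n_slots)
        slots = np.sort(rng.choice(n_slots, size=n, replace=False))
        for slot in slots:
            start = int(slot) * spacing + jitter + 50
            u = rng.random()
            if u < p_ubiq:
                members = list(cell_types)
            elif u < p_ubiq + p_clade:
                members = list(clades[int(rng.integers(len(clades)))])
            else:
                members = [cell_types[int(rng.integers(len(cell_types)))]]
            for ct in members:
                off = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                sets[ct].append((chrom, start + off, start + off + width))
            if config.dhs_focal_cell_type in members:
                p_tx = config.dhs_transcribed_prob_focal
            else:
                p_tx = config.dhs_transcribed_prob_other
            truth_rows.append((chrom, start, start + width,
                               tuple(sorted(members)), bool(rng.random() < p_tx)))
    atlas = {ct: GenomeIntervals.from_records(recs) for ct, recs in sets.items()}
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end",
                                              "members", "transcribed"])
    return atlas, truth


def _random_intervals(rng, chrom_lengths, fraction, min_w, max_w) -> GenomeIntervals:
    recs = []
    for chrom, L in chrom_lengths.items():
        target = fraction * L
        covered = 0
        while covered < target:
            w = int(rng.integers(min_w, max_w + 1))
            s = int(rng.integers(0, max(L - w, 1)))
            recs.append((chrom, s, s + w))
            covered += w
    return GenomeIntervals.from_records(recs)


def _simulate_rna(rng, genes, dhs_truth, config) -> pd.DataFrame:
    rows = []
    for _, g in genes.genes.iterrows():
        if rng.random() >= config.transcribed_gene_fraction:
            continue
        for s in range(g.start, g.end - 100, 500):
            mapq = 37 if rng.random() < 0.9 else 10
            rows.append((g.chrom, s, s + 100, mapq))
    for _, d in dhs_truth.iterrows():
        if not d.transcribed:
            continue
        n_reads = 1 + int(rng.poisson(1.0))
        for _ in range(n_reads):
            s = int(rng.integers(max(d.start - 50, 0), d.end))
            mapq = 37 if rng.random() < 0.9 else 10
            rows.append((d.chrom, s, s + 100, mapq))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq"])


def simulate_indel_calls(truth: TruthSet, config: SimulationConfig) -> Dict[str, pd.DataFrame]:
    """Indel call tables per sample (chrom, pos, allele, score).

    Germline indels appear in both samples; somatic indels only in the
    tumor.  ``tumor_lowmapq`` is the tumor set re-scored from mapQ >= 1
    reads, used by the indel proximity filter; here it is a superset of
    the standard tumor calls.
    """
    rng = _rng(config, 5)

    def score():
        return float(np.round(rng.uniform(15.0, 90.0), 2))

    normal_rows, tumor_rows, low_rows = [], [], []
    for _, r in truth.germline_indels.iterrows():
        normal_rows.append((r.chrom, int(r.pos), r.allele, score()))
        tumor_rows.append((r.chrom, int(r.pos), r.allele, score()))
        low_rows.append((r.chrom, int(r.pos), r.allele, score()))
    for _, r in truth.somatic_indels.iterrows():
        tumor_rows.append((r.chrom, int(r.pos), r.allele, score()))
        low_rows.append((r.chrom, int(r.pos), r.allele, score()))
    cols = ["chrom", "pos", "allele", "score"]
    out = {
        "normal": pd.DataFrame(normal_rows, columns=cols),
        "tumor": pd.DataFrame(tumor_rows, columns=cols),
    }
    out["tumor_lowmapq"] = pd.DataFrame(low_rows, columns=cols)
    for k in out:
        out[k] = out[k].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# Validation fixture
# ----------------------------------------------------------------------

@dataclass
class ValidationSet:
    """Candidate somatic calls with orthogonal (Sanger-style) labels."""

    name: str
    variants: pd.DataFrame  # chrom, pos, ref, normal_genotype, somatic_allele, concordant
    normal_evidence: Dict[Tuple[str, int], SiteEvidence]
    tumor_evidence: Dict[Tuple[str, int], SiteEvidence]
    low_mapq_indels: List[Tuple[str, int]]


@dataclass
class ValidationFixture:
    tissue: ValidationSet
    cell_culture: ValidationSet


def _mixed_strand_reads(base, n, q=40, mapq=37):
    return [ReadObs(base, q, mapq, "+-"[i % 2]) for i in range(n)]


def _make_candidate(chrom, pos, trigger: Optional[str]):
    """One candidate call plus evidence; ``trigger`` names the filter
    (or None for a clean call)."""
    ref, alt = "A", "T"
    normal_reads = _mixed_strand_reads(ref, 30)
    if trigger == "normal_lookup":
        normal_reads += [ReadObs(alt, 35, 20, "+"), ReadObs(alt, 35, 20, "-")]
    if trigger == "strand_bias":
        tumor_reads = _mixed_strand_reads(ref, 12) + [
            ReadObs(alt, 40, 37, "+") for _ in range(5)]
    else:
        tumor_reads = _mixed_strand_reads(ref, 12) + _mixed_strand_reads(alt, 8)
    indels = [(chrom, pos + 7)] if trigger == "indel_proximity" else []
    variant = (chrom, pos, ref, ref + ref, alt)
    return variant, SiteEvidence(chrom, pos, ref, normal_reads), \
        SiteEvidence(chrom, pos, ref, tumor_reads), indels


def _build_set(name, chrom, n_concordant, flagged_triggers, n_clean_discordant):
    rows, nev, tev, indels = [], {}, {}, []
    pos = 1_000
    specs = ([(True, None)] * n_concordant
             + [(False, t) for t in flagged_triggers]
             + [(False, None)] * n_clean_discordant)
    for concordant, trigger in specs:
        variant, ne, te, ind = _make_candidate(chrom, pos, trigger)
        rows.append((*variant, concordant))
        nev[(chrom, pos)] = ne
        tev[(chrom, pos)] = te
        indels.extend(ind)
        pos += 1_000
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref",
                                           "normal_genotype", "somatic_allele",
                                           "concordant"])
    return ValidationSet(name, variants, nev, tev, indels)


def make_validation_fixture() -> ValidationFixture:
    """Candidate-call sets encoding the Sanger validation outcomes.

    Tissue set: 73 calls, 43 concordant (none filter-triggering), 30
    discordant of which 29 carry evidence triggering at least one of the
    three filters.  Cell-culture set: 78 calls, 75 concordant, 3
    discordant of which 2 trigger a filter.
    """
    cycle = ["normal_lookup", "indel_proximity", "strand_bias"]
    tissue = _build_set("tissue", "fixA", 43,
                        [cycle[i % 3] for i in range(29)], 1)
    cell = _build_set("cell_culture", "fixB", 75,
                      ["normal_lookup", "strand_bias"], 1)
    return ValidationFixture(tissue, cell)
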