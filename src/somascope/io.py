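"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; the 1-based
convention appears only at VCF and pileup-TSV boundaries.  Parsers are
strict and name the offending file and line on error.

The pileup dialect is a TSV with columns
``chrom  pos(1-based)  ref  depth  reads`` where ``reads`` is a
comma-separated list of per-read ``base:baseQ:mapQ:strand`` tuples;
files ending in ``.gz`` are gzip-compressed.
"""

from __future__ import annotations

import gzip
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genotyper import ReadObs, SiteEvidence
from .intervals import GenomeIntervals


class ParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")


def _open(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


# -- BED ---------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Strict 3+ column BED -> DataFrame(chrom, start, end[, name])."""
    rows = []
    with _open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, f"expected >= 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, i, f"non-integer coordinate: {exc}")
            if end < start:
                raise ParseError(path, i, f"end {end} < start {start}")
            rows.append((parts[0], start, end,
                         parts[3] if len(parts) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_bed_intervals(path) -> GenomeIntervals:
    return GenomeIntervals.from_frame(read_bed(path))


def write_bed(intervals, path, names: Optional[Iterable[str]] = None) -> None:
    if isinstance(intervals, GenomeIntervals):
        records = list(intervals.records())
    else:
        records = [(r.chrom, r.start, r.end) for r in
                   intervals.itertuples(index=False)]
    names = list(names) if names is not None else None
    with _open(path, "wt") as fh:
        for i, (chrom, start, end) in enumerate(records):
            name = f"\t{names[i]}" if names else ""
            fh.write(f"{chrom}\t{start}\t{end}{name}\n")


# -- pileup TSV --------------------------------------------------------

def write_pileup_tsv(pileup, path, chroms: Optional[Iterable[str]] = None) -> None:
    """Expand a PileupTable to the per-read TSV dialect (desk scale)."""
    chroms = list(chroms) if chroms else list(pileup.chroms)
    with _open(path, "wt") as fh:
        fh.write("#chrom\tpos\tref\tdepth\treads\n")
        for chrom in chroms:
            depth = pileup.depth(chrom)
            for pos in np.flatnonzero(depth > 0):
                site = pileup.site_evidence(chrom, int(pos))
                reads = ",".join(
                    f"{r.base}:{r.base_quality}:{r.mapping_quality}:{r.strand}"
                    for r in site.reads)
                fh.write(f"{chrom}\t{pos + 1}\t{site.ref}\t{site.depth}\t{reads}\n")


def read_pileup_tsv(path) -> List[SiteEvidence]:
    sites = []
    with _open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(path, i, f"expected 5 columns, got {len(parts)}")
            chrom, pos_s, ref, depth_s, reads_s = parts
            try:
                pos = int(pos_s) - 1
                depth = int(depth_s)
            except ValueError as exc:
                raise ParseError(path, i, f"bad integer field: {exc}")
            reads = []
            if reads_s:
                for tup in reads_s.split(","):
                    fields = tup.split(":")
                    if len(fields) != 4:
                        raise ParseError(path, i, f"bad read tuple {tup!r}")
                    base, bq, mq, strand = fields
                    if strand not in "+-":
                        raise ParseError(path, i, f"bad strand {strand!r}")
                    reads.append(ReadObs(base, int(bq), int(mq), strand))
            if len(reads) != depth:
                raise ParseError(path, i,
                                 f"depth {depth} != {len(reads)} read tuples")
            sites.append(SiteEvidence(chrom, pos, ref, reads))
    return sites


# -- VCF ---------------------------------------------------------------

def write_vcf(variants: pd.DataFrame, chrom_lengths: Dict[str, int],
              path) -> None:
    """Somatic calls -> VCF; FILTER carries the validation-filter flags."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in sorted(chrom_lengths.items()):
        header.contigs.add(chrom, length=length)
    header.info.add("MPV", 1, "Float",
                    "log10 odds of a non-reference genotype vs hom-ref")
    header.info.add("NGT", 1, "String", "Normal-sample genotype")
    header.filters.add("normal_lookup", None, None,
                       "Somatic allele observed in the normal sample")
    header.filters.add("indel_proximity", None, None,
                       "Within 10 bp of a low-mapQ indel call")
    header.filters.add("strand_bias", None, None,
                       "Somatic-allele reads confined to one strand")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos),
                stop=int(row.pos) + 1,
                alleles=(row.ref, row.somatic_allele))
            if hasattr(row, "mpv_score") and np.isfinite(row.mpv_score):
                rec.info["MPV"] = float(row.mpv_score)
            if hasattr(row, "normal_genotype"):
                rec.info["NGT"] = str(row.normal_genotype)
            flags = getattr(row, "filter_flags", "PASS")
            for f in str(flags).split(";"):
                rec.filter.add(f)
            out.write(rec)


def read_vcf(path) -> pd.DataFrame:
    """VCF -> DataFrame with 0-based positions and flattened filters."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append((rec.chrom, rec.pos - 1, rec.ref,
                         rec.alts[0] if rec.alts else ".",
                         ";".join(rec.filter.keys()) or "PASS",
                         float(rec.info["MPV"]) if "MPV" in rec.info else np.nan))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "somatic_allele",
                                       "filter_flags", "mpv_score"])


# -- positions ---------------------------------------------------------

def read_positions_tsv(path) -> Dict[str, np.ndarray]:
    """Two-column chrom<TAB>pos(0-based) file -> per-chromosome arrays."""
    by_chrom: Dict[str, list] = {}
    with _open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, i, "expected chrom<TAB>pos")
            try:
                by_chrom.setdefault(parts[0], []).append(int(parts[1]))
            except ValueError as exc:
                raise ParseError(path, i, f"bad position: {exc}")
    return {c: np.sort(np.asarray(v, dtype=np.int64))
            for c, v in by_chrom.items()}
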