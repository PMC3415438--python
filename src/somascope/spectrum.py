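"""Mutational spectra and transcribed-strand bias.

The 12 stranded substitution types collapse into 6 pyrimidine-keyed
classes: each class pairs a key mutation (reference base C or T) with
its reverse complement (e.g. C>T with G>A).  For variants that can be
oriented relative to a transcribed strand — here, intronic variants in
genes of known strand — the key/complement split itself becomes
informative: under transcription-coupled repair the two slots of a
class are depleted asymmetrically, which an exact binomial test against
a 50% expectation detects per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: The six collapsed classes, keyed by pyrimidine reference base.
CLASSES: Tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def collapse_type(ref: str, alt: str) -> Tuple[str, str]:
    """Map a ref>alt substitution to (class, slot in {key, complement})."""
    if ref in "CT":
        return f"{ref}>{alt}", "key"
    return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}", "complement"


@dataclass
class SpectrumCounts:
    """Counts over the 12 stranded types and the 6 collapsed classes."""

    key: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES})
    complement: Dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASSES})

    def add(self, ref: str, alt: str, n: int = 1) -> None:
        cls, slot = collapse_type(ref, alt)
        getattr(self, slot)[cls] += n

    def class_total(self, cls: str) -> int:
        return self.key[cls] + self.complement[cls]

    @property
    def total(self) -> int:
        return sum(self.class_total(c) for c in CLASSES)

    def class_fractions(self) -> Dict[str, float]:
        t = self.total
        return {c: self.class_total(c) / t if t else 0.0 for c in CLASSES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": CLASSES,
            "key": [self.key[c] for c in CLASSES],
            "complement": [self.complement[c] for c in CLASSES],
            "total": [self.class_total(c) for c in CLASSES],
        })


def collapse_spectrum(variants: pd.DataFrame) -> SpectrumCounts:
    """Collapsed spectrum of a variant table with ref and alt columns."""
    counts = SpectrumCounts()
    alt_col = "somatic_allele" if "somatic_allele" in variants.columns else "alt"
    for ref, alt in zip(variants["ref"], variants[alt_col]):
        counts.add(ref, alt)
    return counts


def orient_by_transcript(
    variants: pd.DataFrame,
    genes,
) -> SpectrumCounts:
    """Spectrum of intronic variants oriented to the transcribed strand.

    Variants in minus-strand genes are reverse-complemented before
    classification, so the key/complement slots read relative to the
    coding (non-transcribed) strand.  Variants outside introns, or in
    introns of genes on both strands, are excluded.
    """
    introns = genes.introns()
    alt_col = "somatic_allele" if "somatic_allele" in variants.columns else "alt"
    counts = SpectrumCounts()
    gene_tab = genes.genes
    for row in variants.itertuples(index=False):
        pos = int(row.pos)
        if not bool(introns.contains(row.chrom, np.array([pos]))[0]):
            continue
        hits = gene_tab[(gene_tab["chrom"] == row.chrom)
                        & (gene_tab["start"] <= pos)
                        & (gene_tab["end"] > pos)]
        strands = set(hits["strand"])
        if len(strands) != 1:
            continue  # unorientable: genes on both strands (or none)
        ref, alt = row.ref, getattr(row, alt_col)
        if strands == {"-"}:
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        counts.add(ref, alt)
    return counts


def strand_bias_test(counts: SpectrumCounts,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided exact binomial test of key vs complement per class.

    Classes with zero total are reported with a NaN p-value.
    """
    rows = []
    for cls in CLASSES:
        k, c = counts.key[cls], counts.complement[cls]
        n = k + c
        if n == 0:
            p = np.nan
        else:
            p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        rows.append((cls, k, c, n, p, bool(n and p < alpha)))
    return pd.DataFrame(rows, columns=["class", "key", "complement", "n",
                                       "p_value", "significant"])
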