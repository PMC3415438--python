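"""Tumor purity from somatic allele fractions.

At a clonal heterozygous somatic site in diploid, copy-neutral
territory, the expected fraction of reads carrying the somatic allele
is purity / 2: a pure tumor peaks at 0.5 and normal-cell admixture
shifts the peak left.  The contamination estimate is

    percent normal = (0.5 - observed mode) * 2 * 100

with the mode located by Gaussian-kernel smoothing (bandwidth 0.02) of
the fraction histogram at 0.01 resolution, restricted to (0, 0.5].
Only mapQ >= 30 reads contribute to the fractions, and sites below a
minimum depth are excluded to keep the fraction grid fine enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeIntervals

GRID = np.round(np.arange(0, 101) / 100.0, 2)
DEFAULT_BANDWIDTH = 0.02
DEFAULT_MIN_SITES = 100
DEFAULT_MIN_DEPTH = 10


class InsufficientSitesError(ValueError):
    pass


@dataclass
class AlleleFractionDistribution:
    """Somatic-allele read fractions and their smoothed histogram."""

    fractions: np.ndarray
    depths: np.ndarray
    bandwidth: float = DEFAULT_BANDWIDTH
    grid: np.ndarray = field(default_factory=lambda: GRID.copy())

    @property
    def n_sites(self) -> int:
        return len(self.fractions)

    def histogram(self) -> np.ndarray:
        """Counts on the 0.01 grid (fractions rounded to nearest point)."""
        idx = np.clip(np.round(self.fractions * 100).astype(int), 0, 100)
        return np.bincount(idx, minlength=len(self.grid)).astype(float)

    def smoothed(self) -> np.ndarray:
        h = self.histogram()
        x = self.grid
        kernel = np.exp(-0.5 * ((x[:, None] - x[None, :]) / self.bandwidth) ** 2)
        return kernel @ h

    def mode(self) -> float:
        """Smoothed-histogram argmax over (0, 0.5]."""
        sm = self.smoothed()
        window = (self.grid > 0) & (self.grid <= 0.5)
        return float(self.grid[window][int(np.argmax(sm[window]))])

    def expected_binomial(self) -> np.ndarray:
        """Pure-tumor reference: Binomial(depth, 0.5) pooled over sites,
        expressed on the fraction grid (peaks at 0.5)."""
        pmf = np.zeros(len(self.grid))
        for d in np.unique(self.depths):
            w = (self.depths == d).sum()
            k = np.arange(int(d) + 1)
            idx = np.clip(np.round(100 * k / d).astype(int), 0, 100)
            np.add.at(pmf, idx, w * stats.binom.pmf(k, int(d), 0.5))
        return pmf / pmf.sum() if pmf.sum() else pmf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.grid,
                             "count": self.histogram(),
                             "smoothed": self.smoothed(),
                             "expected_pure": self.expected_binomial()})


def somatic_allele_fractions(
    variants: pd.DataFrame,
    tumor_pileup,
    non_cnv: Optional[GenomeIntervals] = None,
    min_mapq: int = 30,
    min_depth: int = DEFAULT_MIN_DEPTH,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> AlleleFractionDistribution:
    """One somatic-allele read fraction per heterozygous somatic site.

    ``variants`` needs chrom, pos, somatic_allele columns; sites inside
    CNV territory (outside ``non_cnv`` when given) or below ``min_depth``
    retained reads are excluded.
    """
    from .genotyper import BASE_INDEX

    fracs, depths = [], []
    for chrom, sub in variants.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(np.int64)
        retained = tumor_pileup.retained_counts_at(str(chrom), pos, min_mapq)
        keep = np.ones(len(sub), dtype=bool)
        if non_cnv is not None:
            keep = non_cnv.contains(str(chrom), pos)
        for counts, allele, ok in zip(retained, sub["somatic_allele"], keep):
            if not ok:
                continue
            total = counts.sum()
            if total < min_depth:
                continue
            fracs.append(counts[BASE_INDEX[allele]].sum() / total)
            depths.append(total)
    return AlleleFractionDistribution(np.asarray(fracs, dtype=float),
                                      np.asarray(depths, dtype=np.int64),
                                      bandwidth=bandwidth)


def estimate_contamination(
    dist: AlleleFractionDistribution,
    expected_mode: float = 0.5,
    min_sites: int = DEFAULT_MIN_SITES,
) -> float:
    """Percent normal cells: (expected_mode - observed mode) * 2 * 100."""
    if dist.n_sites < min_sites:
        raise InsufficientSitesError(
            f"{dist.n_sites} sites < required {min_sites}")
    return max((expected_mode - dist.mode()) * 2.0 * 100.0, 0.0)
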