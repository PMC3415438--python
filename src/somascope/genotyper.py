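"""Bayesian per-site genotype (MPG) and variant (MPV) scoring.

For a filtered stack of reads at one site, the likelihood of a diploid
genotype ``{a1, a2}`` is the product over reads of

    P(b | a1, a2) = 0.5 * P(b | a1) + 0.5 * P(b | a2)
    P(b | a)      = 1 - e      if b == a
                  = e / 3      otherwise,   e = 10^(-baseQ / 10)

with a flat prior over the 10 unordered diploid genotypes.  The MPG
score is the posterior odds of the best versus the second-best genotype
(confidence in the genotype itself); the MPV score is the odds of any
non-reference genotype versus homozygous reference (confidence that the
sample differs from the reference).  Scores are expressed in
natural-log units: a clean read at a homozygous site then contributes
ln 2 = 0.69 to MPG, which is what makes the standard callability
thresholds — MPG >= 10 together with an MPG-to-Q20-depth ratio >= 0.5,
and MPV >= 10 with no ratio requirement — attainable genome-wide (a
log10 scale would cap the homozygous per-read ratio at 0.30 and no
amount of coverage could ever reach 0.5).

Two code paths are provided: a transparent per-site path operating on
:class:`SiteEvidence`, and :func:`score_pileup`, a vectorized path over
per-site count tensors used genome-wide.  The two are held equal by the
test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: The 10 unordered diploid genotypes in lexicographic order.  Ties in
#: posterior mass are broken toward the earlier entry.
GENOTYPES: Tuple[Tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(BASES, 2)
)
GENOTYPE_STRINGS = tuple(a + b for a, b in GENOTYPES)
#: Index of the homozygous genotype for each base code (AA, CC, GG, TT).
HOM_INDEX = np.array([GENOTYPES.index((b, b)) for b in BASES])

SCORE_CAP = 255.0

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_MPG = 10.0
DEFAULT_MIN_MPV = 10.0
DEFAULT_MIN_RATIO = 0.5


class ReadObs(NamedTuple):
    base: str
    base_quality: int
    mapping_quality: int
    strand: str  # '+' or '-'


@dataclass
class SiteEvidence:
    """Stack of read observations at a single 0-based position."""

    chrom: str
    pos: int
    ref: str
    reads: List[ReadObs] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.reads)


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    ref: str
    genotype: Tuple[str, str]
    mpg_score: float
    q20_depth: int

    @property
    def coverage_ratio(self) -> float:
        return self.mpg_score / self.q20_depth if self.q20_depth else 0.0


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    best_variant_genotype: Tuple[str, str]
    mpv_score: float
    q20_depth: int


def filter_evidence(
    site: SiteEvidence,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> SiteEvidence:
    """Retain reads meeting both quality thresholds; N bases are dropped."""
    kept = [
        r
        for r in site.reads
        if r.mapping_quality >= min_mapq
        and r.base_quality >= min_baseq
        and r.base in BASE_INDEX
    ]
    return SiteEvidence(site.chrom, site.pos, site.ref, kept)


def _log_likelihoods(site: SiteEvidence) -> Optional[np.ndarray]:
    """Log-likelihood of each of the 10 genotypes, or None with no reads."""
    if not site.reads:
        return None
    ll = np.zeros(len(GENOTYPES))
    for read in site.reads:
        e = 10.0 ** (-read.base_quality / 10.0)
        p_match, p_mis = 1.0 - e, e / 3.0
        for g, (a1, a2) in enumerate(GENOTYPES):
            p1 = p_match if read.base == a1 else p_mis
            p2 = p_match if read.base == a2 else p_mis
            ll[g] += np.log(0.5 * p1 + 0.5 * p2)
    return ll


def genotype_posteriors(site: SiteEvidence) -> Optional[np.ndarray]:
    """Flat-prior posterior over the 10 diploid genotypes; None = no-call."""
    ll = _log_likelihoods(site)
    if ll is None:
        return None
    post = np.exp(ll - logsumexp(ll))
    return post / post.sum()


def _odds_score(log_num: float, log_den: float) -> float:
    """Natural-log odds from two log masses, capped at +-SCORE_CAP."""
    return float(np.clip(log_num - log_den, -SCORE_CAP, SCORE_CAP))


def call_mpg(site: SiteEvidence, *, prefiltered: bool = False) -> Optional[GenotypeCall]:
    """Most Probable Genotype call; None when no read survives filtering."""
    if not prefiltered:
        site = filter_evidence(site)
    ll = _log_likelihoods(site)
    if ll is None:
        return None
    order = np.argsort(-ll, kind="stable")
    best, second = order[0], order[1]
    score = _odds_score(ll[best], ll[second])
    return GenotypeCall(site.chrom, site.pos, site.ref,
                        GENOTYPES[best], max(score, 0.0), site.depth)


def call_mpv(site: SiteEvidence, *, prefiltered: bool = False) -> Optional[VariantCall]:
    """Most Probable Variant call; None when no read survives filtering."""
    if not prefiltered:
        site = filter_evidence(site)
    ll = _log_likelihoods(site)
    if ll is None:
        return None
    hom_ref = int(HOM_INDEX[BASE_INDEX[site.ref]])
    others = [g for g in range(len(GENOTYPES)) if g != hom_ref]
    score = _odds_score(logsumexp(ll[others]), ll[hom_ref])
    best_var = others[int(np.argmax(ll[others]))]
    return VariantCall(site.chrom, site.pos, site.ref,
                       GENOTYPES[best_var], score, site.depth)


def is_callable_mpg(
    call: Optional[GenotypeCall],
    min_score: float = DEFAULT_MIN_MPG,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> bool:
    if call is None:
        return False
    return call.mpg_score >= min_score and call.coverage_ratio >= min_ratio


def is_callable_mpv(call: Optional[VariantCall], min_score: float = DEFAULT_MIN_MPV) -> bool:
    return call is not None and call.mpv_score >= min_score


# ----------------------------------------------------------------------
# Vectorized path over count tensors
# ----------------------------------------------------------------------

def likelihood_table(qual_values: Sequence[int]) -> np.ndarray:
    """Per-read log-likelihood contributions, shape (10, 4, n_qual).

    ``table[g, b, q]`` is log P(observed base b | genotype g) for a read
    with base quality ``qual_values[q]``.
    """
    q = np.asarray(qual_values, dtype=float)
    e = 10.0 ** (-q / 10.0)
    p_match, p_mis = 1.0 - e, e / 3.0  # each shape (nq,)
    table = np.empty((len(GENOTYPES), 4, len(q)))
    for g, (a1, a2) in enumerate(GENOTYPES):
        for b, base in enumerate(BASES):
            p1 = p_match if base == a1 else p_mis
            p2 = p_match if base == a2 else p_mis
            table[g, b] = np.log(0.5 * p1 + 0.5 * p2)
    return table


def score_pileup(
    counts: np.ndarray,
    ref_codes: np.ndarray,
    qual_values: Sequence[int],
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> dict:
    """Score many sites at once from quality-stratified base counts.

    Parameters
    ----------
    counts
        Integer array ``(n_sites, 4, n_qual)`` of retained read counts
        per observed base and base-quality class.  Mapping-quality
        filtering is assumed done by the caller (counts from mapQ-passing
        reads only).
    ref_codes
        ``(n_sites,)`` array of reference base codes 0..3.
    qual_values
        Phred value of each quality class, aligned with axis 2.

    Returns a dict of arrays: ``genotype_index``, ``mpg_score``,
    ``q20_depth``, ``coverage_ratio``, ``mpv_score``,
    ``variant_genotype_index``, ``called`` (any retained read).
    """
    qual_values = np.asarray(qual_values)
    keep_q = qual_values >= min_baseq
    c = np.asarray(counts, dtype=np.float64)[:, :, keep_q]
    table = likelihood_table(qual_values[keep_q])
    ll = np.einsum("sbq,gbq->sg", c, table)  # (n_sites, 10)
    depth = c.sum(axis=(1, 2))
    called = depth > 0

    order = np.argsort(-ll, axis=1, kind="stable")
    best = order[:, 0]
    second = order[:, 1]
    rows = np.arange(len(ll))
    mpg = np.clip(ll[rows, best] - ll[rows, second], 0.0, SCORE_CAP)

    hom_ref = HOM_INDEX[np.asarray(ref_codes)]
    ll_ref = ll[rows, hom_ref]
    # logsumexp over the 9 non-reference genotypes
    masked = ll.copy()
    masked[rows, hom_ref] = -np.inf
    m = masked.max(axis=1)
    log_alt = m + np.log(np.exp(masked - m[:, None]).sum(axis=1))
    mpv = np.clip(log_alt - ll_ref, -SCORE_CAP, SCORE_CAP)
    var_best = masked.argmax(axis=1)

    ratio = np.divide(mpg, depth, out=np.zeros_like(mpg), where=depth > 0)
    return {
        "genotype_index": best,
        "mpg_score": np.where(called, mpg, 0.0),
        "q20_depth": depth.astype(np.int64),
        "coverage_ratio": np.where(called, ratio, 0.0),
        "mpv_score": np.where(called, mpv, 0.0),
        "variant_genotype_index": var_best,
        "called": called,
    }
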