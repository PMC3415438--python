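import numpy as np
import pytest

from somascope.genotyper import BASES, GENOTYPES, ReadObs, SiteEvidence


# ----------------------------------------------------------------------
# Independent exhaustive-enumeration oracle for the genotyper
# ----------------------------------------------------------------------

def enumeration_posteriors(reads):
    """Brute-force flat-prior posterior over the 10 diploid genotypes.

    Pure-Python product of per-read likelihoods, kept deliberately
    separate from the package's log-space implementation.
    """
    likelihoods = []
    for a1, a2 in GENOTYPES:
        lik = 1.0
        for base, baseq in reads:
            e = 10.0 ** (-baseq / 10.0)
            p1 = (1.0 - e) if base == a1 else e / 3.0
            p2 = (1.0 - e) if base == a2 else e / 3.0
            lik *= 0.5 * p1 + 0.5 * p2
        likelihoods.append(lik)
    total = sum(likelihoods)
    return [l / total for l in likelihoods]


def random_stack(rng, max_reads=50, chrom="chr1", pos=0):
    """A random read stack as (SiteEvidence, [(base, baseq), ...])."""
    n = int(rng.integers(1, max_reads + 1))
    ref = BASES[rng.integers(4)]
    reads, raw = [], []
    for _ in range(n):
        base = BASES[rng.integers(4)]
        baseq = int(rng.choice([20, 30, 40]))
        reads.append(ReadObs(base, baseq, 37, "+-"[rng.integers(2)]))
        raw.append((base, baseq))
    return SiteEvidence(chrom, pos, ref, reads), raw


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_928)


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb pure-tumor simulation shared across tests."""
    import somascope as s

    config = s.SimulationConfig(genome_length=200_000, purity=1.0, seed=11)
    ref = s.simulate_reference(config)
    truth = s.simulate_truth(ref, config)
    normal, tumor = s.simulate_pileups(ref, truth, config)
    return config, ref, truth, normal, tumor


@pytest.fixture(scope="session")
def validation_fixture():
    from somascope.sim import make_validation_fixture

    return make_validation_fixture()
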