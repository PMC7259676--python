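import numpy as np
import pytest

from wasppop.io_metadata import GenotypeMatrix, HaplotypeSet


def make_genotypes(calls, pos=None, chrom=None, sample_ids=None):
    """Build a GenotypeMatrix from a nested list of dosages (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if sample_ids is None:
        sample_ids = [f"S{i:02d}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["G"] * n_sites, dtype=object),
        calls=calls,
    )


def random_genotypes(rng, n_samples, n_sites, missing_rate=0.0):
    p = rng.uniform(0.05, 0.95, size=n_sites)
    calls = rng.binomial(2, p, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return make_genotypes(calls)


def make_haplotypes(seqs, ids=None):
    if ids is None:
        ids = [f"H{i:02d}" for i in range(len(seqs))]
    return HaplotypeSet(list(ids), list(seqs))


@pytest.fixture(scope="session")
def ring_cohort():
    """One default stepping-stone cohort (20-deme ring, sigma 0.5 km),
    shared by tests that only inspect it."""
    from wasppop.synthetic_data import SimulationConfig, simulate

    return simulate(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
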