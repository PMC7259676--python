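"""Diversity statistics and F_ST estimators against independent oracles."""

import itertools

import numpy as np
import pytest

from wasppop.popgen_stats import (
    PairwiseMatrix,
    het_and_fis,
    mean_offdiagonal,
    mito_pi_and_fst,
    pairwise_wc_fst,
    wc_fst,
    windowed_pi,
)

from conftest import make_genotypes, make_haplotypes, random_genotypes


# ---------------------------------------------------------------------------
# independent oracles


def wc_fst_bruteforce(calls_a, calls_b):
    """Weir & Cockerham (1984) two-population weighted estimator, written
    with explicit per-site loops, independent of the vectorized path."""
    num = den = 0.0
    r = 2
    for j in range(calls_a.shape[1]):
        col_a = calls_a[:, j][calls_a[:, j] >= 0]
        col_b = calls_b[:, j][calls_b[:, j] >= 0]
        n1, n2 = len(col_a), len(col_b)
        if n1 == 0 or n2 == 0:
            continue
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        p1 = col_a.sum() / (2 * n1)
        p2 = col_b.sum() / (2 * n2)
        h1 = (col_a == 1).sum() / n1
        h2 = (col_b == 1).sum() / n2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def hudson_fst_bruteforce(seqs_a, seqs_b):
    """Hudson 1 - Hw/Hb by exhaustive pair enumeration."""

    def diff(x, y):
        return sum(cx != cy for cx, cy in zip(x, y)) / len(x)

    within_a = [diff(x, y) for x, y in itertools.combinations(seqs_a, 2)]
    within_b = [diff(x, y) for x, y in itertools.combinations(seqs_b, 2)]
    between = [diff(x, y) for x in seqs_a for y in seqs_b]
    hw = 0.5 * (np.mean(within_a) + np.mean(within_b))
    hb = np.mean(between)
    return 1 - hw / hb


# ---------------------------------------------------------------------------


class TestWindowedPi:
    def test_zero_variants_zero_pi(self):
        g = make_genotypes(np.zeros((4, 3), dtype=np.int8), pos=[10, 20, 30])
        df, mean = windowed_pi(g, 10_000)
        assert mean == 0.0
        assert (df["pi"] == 0).all()

    def test_single_site_hand_value(self):
        # n = 2 diploids, genotypes {0, 2}: p = 0.5,
        # pi = 2*0.5*0.5*(4/3)/10000 = 6.6667e-5
        g = make_genotypes([[0], [2]], pos=[500])
        _, mean = windowed_pi(g, 10_000)
        assert mean == pytest.approx(2 * 0.5 * 0.5 * (4 / 3) / 10_000, rel=1e-12)

    def test_windows_tile_per_chromosome(self):
        g = make_genotypes(
            [[0, 2, 1], [2, 0, 1]], pos=[5_000, 15_000, 5_000],
            chrom=["chr1", "chr1", "chr2"],
        )
        df, _ = windowed_pi(g, 10_000)
        assert len(df) == 3  # two chr1 windows + one chr2 window

    def test_empty_population_rejected(self, rng):
        g = random_genotypes(rng, 3, 10)
        with pytest.raises(KeyError):
            windowed_pi(g, 10_000, pop=["nope"])


class TestHetAndFis:
    def test_all_homozygote_fis_one(self):
        g = make_genotypes([[0, 2], [2, 0], [0, 0], [2, 2]])
        He, Ho, Fis = het_and_fis(g)
        assert Ho == 0.0
        assert Fis == pytest.approx(1.0)

    def test_hwe_iid_fis_near_zero(self):
        rng = np.random.default_rng(31)
        vals = []
        for _ in range(12):
            p = rng.uniform(0.2, 0.8, size=500)
            calls = rng.binomial(2, p, size=(30, 500)).astype(np.int8)
            vals.append(het_and_fis(make_genotypes(calls))[2])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_wahlund_effect_positive_fis(self):
        # two demes in exact HWE at p = 0.2 and 0.8 (n = 25 each), pooled:
        # heterozygote deficit relative to the pooled p = 0.5 expectation
        def hwe_block(p, n):
            n_hom_alt = round(p * p * n)
            n_het = round(2 * p * (1 - p) * n)
            return [2] * n_hom_alt + [1] * n_het + [0] * (n - n_hom_alt - n_het)

        col = np.array(hwe_block(0.2, 25) + hwe_block(0.8, 25), dtype=np.int8)
        calls = np.tile(col[:, None], (1, 5))
        _, Ho, Fis = het_and_fis(make_genotypes(calls))
        # closed-form Wahlund: Ho = 0.32, pooled 2pq = 0.5 -> Fis ~ 0.36
        assert Ho == pytest.approx(0.32)
        assert Fis > 0.3

    def test_monomorphic_fis_undefined(self):
        g = make_genotypes(np.zeros((4, 3), dtype=np.int8))
        with pytest.warns(UserWarning, match="Fis undefined"):
            He, Ho, Fis = het_and_fis(g)
        assert np.isnan(Fis)


class TestWcFst:
    def test_toy_two_pop_one_site(self):
        # popA: dosages [2,2,1,1] -> p = 0.75, Ho = 0.5
        # popB: dosages [0,0,1,1] -> p = 0.25, Ho = 0.5
        calls = np.array([[2], [2], [1], [1], [0], [0], [1], [1]], dtype=np.int8)
        g = make_genotypes(calls)
        a, b = g.sample_ids[:4], g.sample_ids[4:]
        assert wc_fst(g, a, b) == pytest.approx(
            wc_fst_bruteforce(calls[:4], calls[4:]), abs=1e-12
        )

    def test_matches_bruteforce_random_instances(self):
        rng = np.random.default_rng(4242)
        for trial in range(50):
            nA = rng.integers(2, 11)
            nB = rng.integers(2, 11)
            L = rng.integers(2, 21)
            p = rng.uniform(0.05, 0.95, size=L)
            q = np.clip(p + rng.normal(0, 0.2, size=L), 0.02, 0.98)
            callsA = rng.binomial(2, p, size=(nA, L)).astype(np.int8)
            callsB = rng.binomial(2, q, size=(nB, L)).astype(np.int8)
            miss = rng.random((nA + nB, L)) < 0.1
            calls = np.vstack([callsA, callsB])
            calls[miss] = -1
            g = make_genotypes(calls)
            try:
                expect = wc_fst_bruteforce(calls[:nA], calls[nA:])
            except ZeroDivisionError:
                continue
            got = wc_fst(g, g.sample_ids[:nA], g.sample_ids[nA:])
            assert got == pytest.approx(expect, abs=1e-10), f"trial {trial}"

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.3, 0.7, size=2000)
        calls = rng.binomial(2, p, size=(40, 2000)).astype(np.int8)
        g = make_genotypes(calls)
        fst = wc_fst(g, g.sample_ids[:20], g.sample_ids[20:])
        assert abs(fst) < 0.01  # may be slightly negative

    def test_fixed_difference_is_one(self):
        calls = np.array([[0] * 5] * 4 + [[2] * 5] * 4, dtype=np.int8)
        g = make_genotypes(calls)
        assert wc_fst(g, g.sample_ids[:4], g.sample_ids[4:]) == pytest.approx(1.0)

    def test_symmetry_flip_and_order_invariance(self, rng):
        g = random_genotypes(rng, 10, 50, missing_rate=0.1)
        a, b = g.sample_ids[:5], g.sample_ids[5:]
        f = wc_fst(g, a, b)
        assert wc_fst(g, b, a) == pytest.approx(f, abs=1e-14)
        flipped = g.calls.copy()
        flipped[flipped >= 0] = 2 - flipped[flipped >= 0]
        assert wc_fst(make_genotypes(flipped), a, b) == pytest.approx(f, abs=1e-12)
        perm = rng.permutation(g.n_sites)
        assert wc_fst(make_genotypes(g.calls[:, perm]), a, b) == pytest.approx(f, abs=1e-12)

    def test_small_population_rejected(self, rng):
        g = random_genotypes(rng, 4, 10)
        with pytest.raises(ValueError, match="two samples"):
            wc_fst(g, g.sample_ids[:1], g.sample_ids[1:])

    def test_pairwise_matrix_and_mean(self, rng):
        g = random_genotypes(rng, 12, 80)
        pops = {"A": g.sample_ids[:4], "B": g.sample_ids[4:8], "C": g.sample_ids[8:]}
        m = pairwise_wc_fst(g, pops)
        assert m.labels == ["A", "B", "C"]
        np.testing.assert_allclose(m.values, m.values.T)
        expected_mean = np.mean([m.get("A", "B"), m.get("A", "C"), m.get("B", "C")])
        assert mean_offdiagonal(m) == pytest.approx(expected_mean)


class TestMitoPiFst:
    def test_identical_sequences(self):
        h = make_haplotypes(["ACGT"] * 4)
        with pytest.warns(UserWarning, match="F_ST undefined"):
            pi, m = mito_pi_and_fst(h, {"A": h.sample_ids[:2], "B": h.sample_ids[2:]})
        assert pi["A"] == 0.0
        assert m.get("A", "B") == 0.0

    def test_fixed_five_step_difference(self):
        a = "AAAAAAAAAA"
        b = "CCCCCAAAAA"
        h = make_haplotypes([a, a, b, b])
        pi, m = mito_pi_and_fst(h, {"A": h.sample_ids[:2], "B": h.sample_ids[2:]})
        assert pi["A"] == 0.0 and pi["B"] == 0.0
        assert m.get("A", "B") == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(55)
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=30)) for _ in range(6)]
        h = make_haplotypes(seqs)
        pops = {"A": h.sample_ids[:3], "B": h.sample_ids[3:]}
        pi, m = mito_pi_and_fst(h, pops)
        assert m.get("A", "B") == pytest.approx(
            hudson_fst_bruteforce(seqs[:3], seqs[3:]), abs=1e-12
        )
        within = [
            sum(c1 != c2 for c1, c2 in zip(x, y)) / 30
            for x, y in itertools.combinations(seqs[:3], 2)
        ]
        assert pi["A"] == pytest.approx(np.mean(within), abs=1e-12)

    def test_ambiguous_columns_dropped_globally(self):
        h = make_haplotypes(["NAAAA", "NAAAC", "NCCCA", "NCCCC"])
        pi, m = mito_pi_and_fst(h, {"A": h.sample_ids[:2], "B": h.sample_ids[2:]})
        # column 0 dropped for everyone: 4 usable sites
        assert pi["A"] == pytest.approx(1 / 4)

    def test_singleton_population_rejected_for_fst(self):
        h = make_haplotypes(["AAAA", "AAAC", "CCCC"])
        with pytest.raises(ValueError, match=">=2 sequences"):
            mito_pi_and_fst(h, {"A": h.sample_ids[:2], "B": h.sample_ids[2:]})


def test_pairwise_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        PairwiseMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
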