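"""Geographic distances, IBD regression, Rousset dispersal, sex-bias test."""

import numpy as np
import pandas as pd
import pytest

from wasppop.ibd_dispersal import (
    expected_mito_fst,
    geo_distance_matrix,
    ibd_regression,
    linearize_fst,
    rousset_sigma,
    sex_bias_test,
)
from wasppop.io_metadata import SampleTable
from wasppop.popgen_stats import PairwiseMatrix


def meta_from(rows):
    return SampleTable(
        pd.DataFrame(
            rows, columns=["sample_id", "site_label", "region_label", "latitude", "longitude", "year"]
        )
    )


def sym(labels, tri):
    n = len(labels)
    m = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tri[k]
            k += 1
    return PairwiseMatrix(list(labels), m)


class TestGeoDistance:
    def test_self_distance_zero(self):
        t = meta_from([("a", "x", "R", 42.0, -77.0, 2015), ("b", "x", "R", 42.0, -77.0, 2015)])
        m = geo_distance_matrix(t, "region_label")
        assert m.values[0, 0] == 0.0

    def test_known_east_west_separation(self):
        # 42N 77W (central New York) to 42N 71W (Massachusetts): ~495.6 km
        t = meta_from(
            [("a", "x", "CNY", 42.0, -77.0, 2015), ("b", "y", "MA", 42.0, -71.0, 2015)]
        )
        m = geo_distance_matrix(t, "region_label")
        assert m.get("CNY", "MA") == pytest.approx(495.6, abs=1.0)

    def test_antipodal_half_circumference(self):
        t = meta_from([("a", "x", "P", 0.0, 0.0, 2015), ("b", "y", "Q", 0.0, 180.0, 2015)])
        m = geo_distance_matrix(t, "region_label")
        assert m.get("P", "Q") == pytest.approx(np.pi * 6371.0088, rel=1e-6)

    def test_centroid_of_members(self):
        t = meta_from(
            [
                ("a", "x", "R", 42.0, -77.0, 2015),
                ("b", "x", "R", 44.0, -77.0, 2015),
                ("c", "y", "S", 43.0, -77.0, 2015),
            ]
        )
        m = geo_distance_matrix(t, "region_label")
        assert m.get("R", "S") == pytest.approx(0.0, abs=1e-9)

    def test_missing_coordinates_listed(self):
        t = meta_from([("a", "x", "R", 42.0, -77.0, 2015), ("b", "x", "R", np.nan, -77.0, 2015)])
        with pytest.raises(ValueError, match="b"):
            geo_distance_matrix(t, "region_label")


class TestLinearize:
    @pytest.mark.parametrize(
        "f,expected",
        [(0.0, 0.0), (0.5, 1.0), (0.0525, 0.0525 / (1 - 0.0525))],
    )
    def test_values(self, f, expected):
        assert linearize_fst(f) == pytest.approx(expected, rel=1e-12)

    def test_unit_fst_flagged_infinite(self):
        assert np.isinf(linearize_fst(1.0))


class TestIbdRegression:
    def test_exact_fit_recovery(self):
        # points generated from the printed Eastern-US fit with zero noise
        labels = ["P1", "P2", "P3", "P4", "P5"]
        rng = np.random.default_rng(2)
        km = sym(labels, rng.uniform(50, 700, size=10))
        slope, intercept = 1.27e-4, -0.01
        lin = slope * km.values + intercept
        np.fill_diagonal(lin, 0)
        fst = PairwiseMatrix(labels, lin / (1 + lin))  # invert linearization
        res = ibd_regression(fst, km)
        assert res.slope_b == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.n_pairs == 10

    def test_collinear_slope_two(self):
        labels = ["A", "B", "C", "D"]
        km = sym(labels, [1, 2, 3, 4, 5, 6])
        lin = 2.0 * km.values
        np.fill_diagonal(lin, 0)
        fst = PairwiseMatrix(labels, lin / (1 + lin))
        res = ibd_regression(fst, km)
        assert res.slope_b == pytest.approx(2.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        labels = ["A", "B"]
        with pytest.raises(ValueError, match=">=3"):
            ibd_regression(sym(labels, [0.1]), sym(labels, [10.0]))

    def test_unit_fst_pair_excluded(self):
        labels = ["A", "B", "C", "D"]
        tri = [0.1, 0.2, 0.3, 0.2, 0.1, 1.0]  # one pair at fixation
        res = ibd_regression(sym(labels, tri), sym(labels, [1, 2, 3, 4, 5, 6]))
        assert res.n_pairs == 5

    def test_mantel_p_deterministic_and_small_for_strong_ibd(self):
        labels = [f"P{i}" for i in range(6)]
        rng = np.random.default_rng(5)
        km = sym(labels, rng.uniform(10, 500, size=15))
        lin = 2e-4 * km.values + rng.normal(0, 1e-4, size=km.values.shape)
        lin = (lin + lin.T) / 2
        np.fill_diagonal(lin, 0)
        fst = PairwiseMatrix(labels, lin / (1 + lin))
        r1 = ibd_regression(fst, km, permutations=999, seed=11)
        r2 = ibd_regression(fst, km, permutations=999, seed=11)
        assert r1.mantel_p == r2.mantel_p
        assert r1.mantel_p < 0.05


class TestRoussetSigma:
    @pytest.mark.parametrize(
        "b,De,sigma",
        [
            (1.27e-4, 1080.0, 761.0),
            (1.27e-4, 2500.0, 501.0),
            (0.0021, 1080.0, 188.0),
            (0.0021, 2500.0, 124.0),
            (9.54e-5, 2500.0, 578.0),
            (9.54e-5, 1080.0, 879.0),
        ],
    )
    def test_study_slopes_and_densities(self, b, De, sigma):
        assert rousset_sigma(b, De).sigma_m == pytest.approx(sigma, rel=0.01)

    def test_density_scaling_law(self):
        # sigma ~ De^(-1/2): quadrupling the density halves sigma
        s1 = rousset_sigma(1e-4, 1000.0).sigma_m
        s4 = rousset_sigma(1e-4, 4000.0).sigma_m
        assert s4 == pytest.approx(s1 / 2, rel=1e-12)

    def test_inverse_recovers_slope(self):
        b = 3.21e-4
        est = rousset_sigma(b, 1080.0)
        b_back = 1.0 / (4 * np.pi * 1080.0 * (est.sigma_m / 1000.0) ** 2)
        assert b_back == pytest.approx(b, rel=1e-12)

    def test_negative_slope_refused_with_explanation(self):
        with pytest.raises(ValueError, match="not positive"):
            rousset_sigma(-1e-4, 1080.0)

    def test_caveats_attached(self):
        cav = " ".join(rousset_sigma(1e-4, 1080.0).caveats)
        assert "overestimate of De" in cav
        assert "haplodiploid" in cav.lower()


class TestExpectedMitoFst:
    def test_fixed_points_exact(self):
        assert expected_mito_fst(0.0) == 0.0
        assert expected_mito_fst(1.0) == 1.0

    def test_printed_mean_nuclear_fst(self):
        assert expected_mito_fst(0.0525) == pytest.approx(4 * 0.0525 / (1 + 3 * 0.0525), rel=1e-12)

    def test_monotone_and_concave_on_grid(self):
        grid = np.linspace(0, 1, 1000)
        vals = expected_mito_fst(grid)
        assert (np.diff(vals) > 0).all()
        assert (np.diff(vals, 2) < 1e-12).all()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            expected_mito_fst(1.2)


class TestSexBiasTest:
    def _matrices(self, diffs, base=0.05):
        """10-pair (5-label) matrices where observed mito = expected + diff."""
        labels = ["A", "B", "C", "D", "E"]
        nuc = sym(labels, np.full(10, base))
        exp = expected_mito_fst(base)
        mito = sym(labels, exp + np.asarray(diffs))
        return nuc, mito

    def test_exact_agreement_t_zero(self):
        nuc, mito = self._matrices(np.zeros(10))
        res = sex_bias_test(nuc, mito)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_constant_difference_degenerate(self):
        nuc, mito = self._matrices(np.full(10, 0.04))
        res = sex_bias_test(nuc, mito)
        assert np.isinf(res.t_statistic)
        assert res.metadata["degenerate_zero_variance"]

    def test_t_matches_hand_computation(self):
        rng = np.random.default_rng(17)
        diffs = rng.normal(-0.02, 0.03, size=10)
        nuc, mito = self._matrices(diffs)
        res = sex_bias_test(nuc, mito)
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(10))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.df == 9

    def test_direction_conventions_oppose(self):
        # observed well below expectation on every pair
        nuc, mito = self._matrices(np.linspace(-0.08, -0.05, 10))
        res = sex_bias_test(nuc, mito)
        assert res.p_value < 0.05
        assert res.direction == "male-biased"          # empirical inference rule
        assert res.direction_excess_mito == "female-biased"  # standard theory

    def test_too_few_pairs(self):
        labels = ["A", "B"]
        with pytest.raises(ValueError, match="two population pairs"):
            sex_bias_test(sym(labels, [0.05]), sym(labels, [0.1]))
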