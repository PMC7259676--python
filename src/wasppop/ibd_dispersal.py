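"""Isolation by distance and dispersal inference.

The core inference chain: great-circle distances between population
centroids; ordinary least squares of linearized F_ST, F/(1-F), on
distance; Rousset's relation between the regression slope b (per km) and
the mean squared parent-offspring axial dispersal distance,

    sigma^2 = 1 / (4 * pi * De * b),

with De the effective density of breeders per km^2 (approximated by nest
density); and the mitochondrial-vs-nuclear comparison for sex-biased
dispersal, where under equal male and female dispersal in a diploid
population

    F_ST(mito) = 4 F / (1 + 3 F),   F = F_ST(nuclear).

Caveats carried on every dispersal estimate: an overestimate of De
underestimates dispersal distance (sigma scales as De^-1/2), and
haplodiploid alleles coalesce at 3/4 the diploid rate, inflating b and
hence likely overestimating dispersal distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import haversine_distances

from .io_metadata import SampleTable
from .popgen_stats import PairwiseMatrix

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "IBDRegressionResult",
    "DispersalEstimate",
    "SexBiasResult",
    "geo_distance_matrix",
    "linearize_fst",
    "ibd_regression",
    "rousset_sigma",
    "expected_mito_fst",
    "sex_bias_test",
]


@dataclass
class IBDRegressionResult:
    """OLS fit of linearized F_ST on geographic distance over population pairs."""

    slope_b: float            # per km
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float            # OLS two-sided p for the slope
    mantel_p: float | None    # permutation p (labels permuted), None if not run
    n_pairs: int
    pairs: pd.DataFrame       # popA, popB, distance_km, fst, fst_linearized

    def to_dict(self) -> dict:
        return {
            "slope_b_per_km": self.slope_b,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "p_value_ols": self.p_value,
            "p_value_mantel": self.mantel_p,
            "n_pairs": self.n_pairs,
        }


@dataclass
class DispersalEstimate:
    """Axial parent-offspring dispersal distance from Rousset's method."""

    sigma_m: float            # meters
    De: float                 # breeders per km^2
    slope_b: float            # per km
    caveats: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sigma_m": self.sigma_m,
            "De_per_km2": self.De,
            "slope_b_per_km": self.slope_b,
            "caveats": self.caveats,
        }


@dataclass
class SexBiasResult:
    """Observed vs expected mitochondrial F_ST over population pairs."""

    pairs: pd.DataFrame       # popA, popB, fst_nuc, fst_mito_obs, fst_mito_exp, difference
    mean_observed: float
    mean_expected: float
    t_statistic: float
    df: int
    p_value: float
    direction: str            # per the empirical rule: expected > observed -> male-biased
    direction_excess_mito: str  # per standard theory: observed > expected -> male-biased
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_observed_fst_mito": self.mean_observed,
            "mean_expected_fst_mito": self.mean_expected,
            "mean_difference_obs_minus_exp": self.mean_observed - self.mean_expected,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "direction": self.direction,
            "direction_excess_mito": self.direction_excess_mito,
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------


def geo_distance_matrix(meta: SampleTable, grouping: str = "region_label") -> PairwiseMatrix:
    """Great-circle distance matrix (km) between group centroids.

    Group coordinates are centroids of member sample lat/long (decimal
    degrees); distances are haversine on a sphere of radius 6371.0088 km.
    """
    df = meta.df
    bad = df[df["latitude"].isna() | df["longitude"].isna()]
    if len(bad):
        raise ValueError(f"samples without coordinates: {bad['sample_id'].tolist()}")
    cent = df.groupby(grouping, sort=False)[["latitude", "longitude"]].mean()
    labels = [str(x) for x in cent.index]
    rad = np.radians(cent[["latitude", "longitude"]].to_numpy(dtype=float))
    km = haversine_distances(rad) * EARTH_RADIUS_KM
    np.fill_diagonal(km, 0.0)
    return PairwiseMatrix(labels, km, "geo_km")


def linearize_fst(fst):
    """Rousset's linearization F/(1 - F); F = 1 maps to +inf (flagged by
    callers and excluded from regression)."""
    f = np.asarray(fst, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(f == 1.0, np.inf, f / (1.0 - f))
    return float(out) if np.isscalar(fst) or out.ndim == 0 else out


def _mantel_p(x: np.ndarray, y: np.ndarray, permutations: int, seed: int | None) -> float:
    """Two-sided Mantel permutation p for the correlation between two
    symmetric matrices, permuting the labels of one matrix."""
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    finite = np.isfinite(x[iu]) & np.isfinite(y[iu])
    obs = np.corrcoef(x[iu][finite], y[iu][finite])[0, 1]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = x[np.ix_(perm, perm)][iu]
        ok = np.isfinite(xp) & np.isfinite(y[iu])
        r = np.corrcoef(xp[ok], y[iu][ok])[0, 1]
        if abs(r) >= abs(obs) - 1e-15:
            hits += 1
    return (hits + 1) / (permutations + 1)


def ibd_regression(
    fst: PairwiseMatrix,
    dist: PairwiseMatrix,
    permutations: int = 0,
    seed: int | None = None,
) -> IBDRegressionResult:
    """OLS of linearized F_ST on distance (km) over all unordered pairs.

    Pairs with non-finite linearized F_ST or distance are excluded. The OLS
    p-value is reported as primary; when ``permutations`` > 0 a seeded
    Mantel permutation p (two-sided, labels of the F_ST matrix permuted)
    is reported alongside, since pairwise points are not independent.
    """
    d = dist.align_to(fst.labels)
    rows = []
    for (a, b, f), (_, _, km) in zip(fst.offdiag_pairs(), d.offdiag_pairs()):
        rows.append((a, b, km, f, linearize_fst(f) if np.isfinite(f) else np.nan))
    pairs = pd.DataFrame(rows, columns=["popA", "popB", "distance_km", "fst", "fst_linearized"])
    ok = np.isfinite(pairs["fst_linearized"]) & np.isfinite(pairs["distance_km"])
    x = pairs.loc[ok, "distance_km"].to_numpy()
    y = pairs.loc[ok, "fst_linearized"].to_numpy()
    if len(x) < 3:
        raise ValueError(f"need >=3 finite pairs for regression, have {len(x)}")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    n = len(x)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    mantel = None
    if permutations > 0:
        lin = linearize_fst(fst.align_to(fst.labels).values)
        mantel = _mantel_p(np.asarray(lin), d.values, permutations, seed)
    return IBDRegressionResult(
        slope_b=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        p_value=float(fit.pvalue),
        mantel_p=mantel,
        n_pairs=n,
        pairs=pairs,
    )


def rousset_sigma(b: float, De: float) -> DispersalEstimate:
    """Axial dispersal distance sigma (meters) from an IBD slope.

    sigma = 1000 * sqrt(1 / (4 * pi * De * b)) with b per km and De
    breeders per km^2. A non-positive slope yields no real estimate and
    raises with an explanation (no isolation-by-distance signal).
    """
    if De <= 0:
        raise ValueError("De must be positive")
    if b <= 0:
        raise ValueError(
            "IBD slope is not positive: no isolation-by-distance signal, "
            "dispersal distance cannot be estimated (sigma would be imaginary)"
        )
    sigma_km = np.sqrt(1.0 / (4.0 * np.pi * De * b))
    return DispersalEstimate(
        sigma_m=float(1000.0 * sigma_km),
        De=float(De),
        slope_b=float(b),
        caveats=[
            "an overestimate of De will likely underestimate dispersal distance",
            "haplodiploid alleles coalesce at ~3/4 the diploid rate, inflating the "
            "slope and likely overestimating dispersal distance",
        ],
    )


def expected_mito_fst(fst_nuc):
    """Expected mitochondrial F_ST under equal male and female dispersal:
    4F/(1+3F) for diploid nuclear F in [0, 1]; fixed points 0 and 1,
    monotone increasing, concave."""
    f = np.asarray(fst_nuc, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("nuclear F_ST must be within [0, 1]")
    out = 4.0 * f / (1.0 + 3.0 * f)
    return float(out) if np.isscalar(fst_nuc) or out.ndim == 0 else out


def sex_bias_test(fst_nuc: PairwiseMatrix, fst_mito: PairwiseMatrix) -> SexBiasResult:
    """Compare observed mitochondrial F_ST with its nuclear-predicted value.

    Per population pair, expected F_ST(mito) = 4F/(1+3F) from the observed
    nuclear F (clamped into [0, 1] for prediction only); a two-sided
    one-sample t-test is run on the differences (observed - expected)
    against zero. Zero variance with a nonzero mean yields |t| = inf
    (flagged in metadata).

    Two direction conventions are reported: ``direction`` follows the
    empirical inference rule used on these wasps (mean expected > mean
    observed -> "male-biased"); ``direction_excess_mito`` follows the
    standard expectation that male-biased dispersal leaves EXCESS
    mitochondrial structure (mean observed > mean expected ->
    "male-biased"). They are opposite readings of the same signed
    difference; consult metadata.
    """
    mito = fst_mito.align_to(fst_nuc.labels)
    rows = []
    for (a, b, fn), (_, _, fm) in zip(fst_nuc.offdiag_pairs(), mito.offdiag_pairs()):
        fe = expected_mito_fst(min(max(fn, 0.0), 1.0))
        rows.append((a, b, fn, fm, fe, fm - fe))
    pairs = pd.DataFrame(
        rows,
        columns=["popA", "popB", "fst_nuc", "fst_mito_obs", "fst_mito_exp", "difference"],
    )
    if len(pairs) < 2:
        raise ValueError("sex-bias test needs at least two population pairs")
    diffs = pairs["difference"].to_numpy()
    mean_obs = float(pairs["fst_mito_obs"].mean())
    mean_exp = float(pairs["fst_mito_exp"].mean())
    sd = diffs.std(ddof=1)
    # zero variance up to rounding noise: t would be meaningless
    degenerate = sd <= max(abs(diffs.mean()), 1.0) * 1e-12
    if degenerate:
        t = float("inf") * np.sign(diffs.mean()) if diffs.mean() != 0 else 0.0
        p = 0.0 if diffs.mean() != 0 else 1.0
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
    df = len(diffs) - 1
    significant = p < 0.05
    if not significant or mean_obs == mean_exp:
        direction = direction_excess = "none"
    else:
        direction = "male-biased" if mean_exp > mean_obs else "female-biased"
        direction_excess = "male-biased" if mean_obs > mean_exp else "female-biased"
    return SexBiasResult(
        pairs=pairs,
        mean_observed=mean_obs,
        mean_expected=mean_exp,
        t_statistic=float(t),
        df=df,
        p_value=float(p),
        direction=direction,
        direction_excess_mito=direction_excess,
        metadata={
            "degenerate_zero_variance": bool(degenerate),
            "direction_convention": (
                "direction: empirical rule (mean expected > mean observed => male-biased); "
                "direction_excess_mito: standard theory (observed mito F_ST above the "
                "4F/(1+3F) expectation => reduced male gene flow relative to female, "
                "i.e. female philopatry with male-biased dispersal leaves excess "
                "mitochondrial structure)"
            ),
        },
    )


def pair_table(
    fst_nuc: PairwiseMatrix,
    fst_mito: PairwiseMatrix | None,
    dist: PairwiseMatrix,
) -> pd.DataFrame:
    """Long-format pair table joining distance, nuclear and mito F_ST."""
    d = dist.align_to(fst_nuc.labels)
    rows = []
    for (a, b, fn), (_, _, km) in zip(fst_nuc.offdiag_pairs(), d.offdiag_pairs()):
        row = {
            "popA": a,
            "popB": b,
            "distance_km": km,
            "fst_nuc": fn,
            "fst_nuc_linearized": linearize_fst(fn) if np.isfinite(fn) else np.nan,
        }
        if fst_mito is not None:
            fm = fst_mito.align_to(fst_nuc.labels).get(a, b)
            row["fst_mito"] = fm
            row["fst_mito_expected"] = expected_mito_fst(min(max(fn, 0.0), 1.0))
        rows.append(row)
    return pd.DataFrame(rows)
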