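"""Windowed diversity and differentiation statistics.

Nuclear statistics (pi, He, Ho, F_IS) are computed in physical windows
(default 10,000 bp) from alt-allele dosages; nuclear pairwise F_ST uses the
Weir & Cockerham (1984) weighted estimator; mitochondrial diversity and
F_ST come from pairwise sequence differences (Hudson's 1 - Hw/Hb on the
concatenated haploid genes).

Conventions:

* pi uses the full window span as denominator (the windowed-pi convention
  of VCFtools), so magnitudes are comparable to whole-genome Table-style
  values (~1e-3 .. 1e-4), not per-callable-site values.
* F_IS aggregates as a ratio of sums across windows, 1 - sum(Ho_w)/sum(He_w),
  which is stable when individual windows have tiny He.
* Negative F_ST estimates are preserved in raw output (they are legitimate
  small-sample outcomes); clamp only at presentation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_metadata import MISSING, GenotypeMatrix, HaplotypeSet

__all__ = [
    "PairwiseMatrix",
    "PopGenSummary",
    "windowed_pi",
    "het_and_fis",
    "wc_fst",
    "pairwise_wc_fst",
    "mito_pi_and_fst",
    "mean_offdiagonal",
    "population_summaries",
]


@dataclass
class PairwiseMatrix:
    """Labelled symmetric matrix of a pairwise statistic (F_ST, distance...)."""

    labels: list[str]
    values: np.ndarray
    statistic: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def offdiag_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            out.append((self.labels[i], self.labels[j], float(self.values[i, j])))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def align_to(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.statistic)


@dataclass
class PopGenSummary:
    """One population's diversity summary (one row of a Table-1-style report)."""

    label: str
    n: int
    pi: float
    pi_mt: float
    He: float
    Ho: float
    Fis: float
    region_radius_km: float = float("nan")
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Window machinery


def _window_index(chrom: np.ndarray, pos: np.ndarray, window_bp: int) -> np.ndarray:
    """Integer window id per site; windows tile [1, 1+w), [1+w, 1+2w), ... per
    chromosome and ids are unique across chromosomes."""
    wid = (pos - 1) // window_bp
    codes = pd.factorize(chrom)[0].astype(np.int64)
    return codes * (int(wid.max()) + 1 if len(wid) else 1) + wid


def _site_freqs(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt frequency and non-missing diploid count per site."""
    called = calls != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return p, n


def windowed_pi(
    g: GenotypeMatrix, window_bp: int = 10_000, pop: list[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Nucleotide diversity per physical window and its mean.

    Per window: pi = sum over sites of 2*p*q * 2n/(2n-1), divided by the
    window span in bp (p = alt frequency over non-missing calls, n =
    non-missing diploid count at the site; the 2n/(2n-1) factor is the
    unbiased correction). The mean is over windows containing at least one
    genotyped site. Returns (per-window DataFrame, mean pi).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    sub = g.take_samples(pop) if pop is not None else g
    if sub.n_samples == 0:
        raise ValueError("empty population")
    p, n = _site_freqs(sub.calls)
    usable = n >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(
            n > 0, 2.0 * p * (1.0 - p) * (2.0 * n / np.maximum(2.0 * n - 1.0, 1.0)), 0.0
        )
    wid = _window_index(sub.chrom, sub.pos, window_bp)
    df = (
        pd.DataFrame(
            {
                "window": wid,
                "chrom": sub.chrom,
                "win_start": ((sub.pos - 1) // window_bp) * window_bp + 1,
                "site_pi": np.where(usable, site_pi, 0.0),
                "genotyped": usable.astype(int),
            }
        )
        .groupby(["window", "chrom", "win_start"], as_index=False)
        .agg(pi_sum=("site_pi", "sum"), n_genotyped=("genotyped", "sum"))
    )
    df["pi"] = df["pi_sum"] / window_bp
    informative = df[df["n_genotyped"] > 0]
    mean_pi = float(informative["pi"].mean()) if len(informative) else float("nan")
    return df[["chrom", "win_start", "pi", "n_genotyped"]], mean_pi


def het_and_fis(
    g: GenotypeMatrix, window_bp: int = 10_000, pop: list[str] | None = None
) -> tuple[float, float, float]:
    """Expected/observed heterozygosity and the inbreeding coefficient F_IS.

    Per polymorphic site: He = 2*p*q * 2n/(2n-1) (Nei's unbiased expected
    heterozygosity, the same small-sample correction the pi formula
    carries, so F_IS is unbiased under Hardy-Weinberg), Ho = observed
    heterozygote fraction. Per window these are averaged over its
    polymorphic sites; the reported He and Ho are window means and
    F_IS = 1 - sum_w(Ho_w)/sum_w(He_w). With no polymorphic site F_IS is
    undefined (NaN, with a warning).
    """
    sub = g.take_samples(pop) if pop is not None else g
    if sub.n_samples < 2:
        raise ValueError("He/Ho/Fis need at least two samples")
    p, n = _site_freqs(sub.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 2.0 * p * (1.0 - p) * (2.0 * n / np.maximum(2.0 * n - 1.0, 1.0))
    called = sub.calls != MISSING
    het = (sub.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    poly = (n > 0) & (p > 0) & (p < 1)
    if not poly.any():
        warnings.warn("no polymorphic sites: Fis undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    wid = _window_index(sub.chrom, sub.pos, window_bp)
    df = pd.DataFrame({"window": wid[poly], "he": he[poly], "ho": ho[poly]})
    win = df.groupby("window").mean()
    He = float(win["he"].mean())
    Ho = float(win["ho"].mean())
    Fis = float(1.0 - win["ho"].sum() / win["he"].sum())
    return He, Ho, Fis


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for two populations.

    Returns (a, a+b+c) arrays over sites usable in both populations
    (>=1 non-missing call each); other sites contribute zero.
    """
    r = 2.0
    p_a, n_a = _site_freqs(calls_a)
    p_b, n_b = _site_freqs(calls_b)
    het_a = (calls_a == 1).sum(axis=0)
    het_b = (calls_b == 1).sum(axis=0)
    usable = (n_a >= 1) & (n_b >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_a = het_a / np.maximum(n_a, 1)
        h_b = het_b / np.maximum(n_b, 1)
        nbar = (n_a + n_b) / r
        nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1.0)
        pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
        s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n_a * h_a + n_b * h_b) / (r * nbar)
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    a = np.where(usable, a, 0.0)
    total = np.where(usable, a + b + c, 0.0)
    # sites where nbar == 1 (a single diploid in each pop) are undefined
    bad = usable & (nbar <= 1.0)
    a[bad] = 0.0
    total[bad] = 0.0
    return np.nan_to_num(a), np.nan_to_num(total)


def wc_fst(g: GenotypeMatrix, popA: list[str], popB: list[str]) -> float:
    """Weir & Cockerham (1984) weighted two-population F_ST.

    F_ST = sum_sites(a) / sum_sites(a + b + c) with the standard among-,
    between- and within-individual variance components; sites entirely
    missing in either population are skipped. Requires >=2 samples per
    population.
    """
    if len(popA) < 2 or len(popB) < 2:
        raise ValueError("each population needs at least two samples")
    a, total = _wc_components(g.take_samples(popA).calls, g.take_samples(popB).calls)
    denom = total.sum()
    if denom == 0:
        raise ValueError("no usable variant sites for F_ST")
    return float(a.sum() / denom)


def pairwise_wc_fst(g: GenotypeMatrix, pops: dict[str, list[str]]) -> PairwiseMatrix:
    """Pairwise nuclear F_ST matrix over a population partition."""
    labels = list(pops)
    n = len(labels)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = wc_fst(g, pops[labels[i]], pops[labels[j]])
    return PairwiseMatrix(labels, vals, "fst_nuclear")


def mean_offdiagonal(m: PairwiseMatrix) -> float:
    """Unweighted mean of the off-diagonal (all pairwise comparisons)."""
    vals = [v for _, _, v in m.offdiag_pairs() if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Mitochondrial diversity & Hudson F_ST


def _clean_codes(h: HaplotypeSet, ids: list[str]) -> np.ndarray:
    """Encoded sequences for ``ids`` with every column containing an
    ambiguous base (N, gap...) in ANY retained sample dropped globally."""
    codes = h.subset(ids).to_codes()
    good = ~(codes == 255).any(axis=0)
    return codes[:, good]


def mito_pi_and_fst(
    h: HaplotypeSet, pops: dict[str, list[str]]
) -> tuple[dict[str, float], PairwiseMatrix]:
    """Per-population mitochondrial diversity and pairwise Hudson F_ST.

    pi_mt = mean pairwise Hamming difference per usable site within a
    population (NaN for populations of one). Pairwise
    F_ST = 1 - Hw/Hb with Hw the unweighted average of the two
    within-population mean pairwise differences and Hb the mean
    between-population difference. Columns with an ambiguous base in any
    retained sample are dropped globally before all computations.
    """
    all_ids = [sid for ids in pops.values() for sid in ids]
    codes = _clean_codes(h, all_ids)
    n_sites = codes.shape[1]
    if n_sites == 0:
        raise ValueError("no unambiguous alignment columns")
    # proportion-different distances between all retained samples
    d = squareform(pdist(codes, metric="hamming")) if len(all_ids) > 1 else np.zeros((1, 1))
    index = {sid: k for k, sid in enumerate(all_ids)}

    def mean_within(ids: list[str]) -> float:
        if len(ids) < 2:
            return float("nan")
        idx = [index[s] for s in ids]
        sub = d[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), 1)].mean())

    pi_mt = {}
    for label, ids in pops.items():
        w = mean_within(ids)
        if np.isnan(w):
            warnings.warn(f"population {label!r} has <2 sequences: pi_mt undefined", stacklevel=2)
        pi_mt[label] = w

    labels = list(pops)
    vals = np.zeros((len(labels), len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        ids_a, ids_b = pops[labels[i]], pops[labels[j]]
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(
                f"Hudson F_ST needs >=2 sequences per population "
                f"({labels[i]}: {len(ids_a)}, {labels[j]}: {len(ids_b)})"
            )
        hw = 0.5 * (mean_within(ids_a) + mean_within(ids_b))
        ia = [index[s] for s in ids_a]
        ib = [index[s] for s in ids_b]
        hb = float(d[np.ix_(ia, ib)].mean())
        if hb == 0.0:
            warnings.warn(
                f"no between-population differences for {labels[i]}-{labels[j]}: "
                "F_ST undefined, reported 0",
                stacklevel=2,
            )
            fst = 0.0
        else:
            fst = 1.0 - hw / hb
        vals[i, j] = vals[j, i] = fst
    return pi_mt, PairwiseMatrix(labels, vals, "fst_mito")


# ---------------------------------------------------------------------------
# Table-style report


def population_summaries(
    g: GenotypeMatrix,
    h: HaplotypeSet | None,
    pops: dict[str, list[str]],
    window_bp: int = 10_000,
    radii_km: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-population diversity table (label, N, pi, pi_mt, He, Ho, Fis)."""
    pi_mt: dict[str, float] = {}
    if h is not None:
        usable = {k: [s for s in v if s in set(h.sample_ids)] for k, v in pops.items()}
        pi_mt = {
            k: (mito_pi_and_fst(h, {k: ids})[0][k] if len(ids) >= 2 else float("nan"))
            for k, ids in usable.items()
        }
    rows = []
    for label, ids in pops.items():
        _, mean_pi = windowed_pi(g, window_bp, ids)
        He, Ho, Fis = het_and_fis(g, window_bp, ids)
        rows.append(
            PopGenSummary(
                label=label,
                n=len(ids),
                pi=mean_pi,
                pi_mt=pi_mt.get(label, float("nan")),
                He=He,
                Ho=Ho,
                Fis=Fis,
                region_radius_km=(radii_km or {}).get(label, float("nan")),
            )
        )
    return pd.DataFrame(
        [
            {
                "location": s.label,
                "r_km": s.region_radius_km,
                "N": s.n,
                "pi": s.pi,
                "pi_mt": s.pi_mt,
                "He": s.He,
                "Ho": s.Ho,
                "Fis": s.Fis,
            }
            for s in rows
        ]
    )
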