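"""Pairwise kinship (KING-robust) and relatedness pruning.

The study design requires unrelated individuals: nestmates share a mother,
so one individual per nest is kept and any residual pair with kinship
phi > 0.1 loses a member. The KING-robust within-pair estimator is used:
it needs no allele-frequency estimates and is robust to population
structure, which matters here because the samples span differentiated
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_metadata import MISSING, GenotypeMatrix

__all__ = ["KinshipMatrix", "king_kinship", "prune_related"]


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship coefficients with per-pair site counts.

    ``phi[i, j]`` is NaN for pairs with an undefined estimate (no shared
    heterozygous sites). The diagonal is the self-comparison, ~0.5 for a
    non-inbred sample.
    """

    sample_ids: list[str]
    phi: np.ndarray
    n_shared_sites: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def pairs_above(self, threshold: float) -> list[tuple[int, int, float]]:
        """Off-diagonal pairs with finite phi > threshold, sorted worst-first.

        Ties in phi break on the lexicographically ordered id pair so the
        pruning order is reproducible.
        """
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                v = self.phi[i, j]
                if np.isfinite(v) and v > threshold:
                    out.append((i, j, float(v)))
        out.sort(key=lambda t: (-t[2], self.sample_ids[t[0]], self.sample_ids[t[1]]))
        return out


def king_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust within-pair kinship for every sample pair.

    For a pair (i, j), over sites called in both::

        phi = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))

    where N_Aa,Aa counts double heterozygotes, N_AA,aa opposite homozygotes,
    and N_Aa(.) each sample's heterozygote count on the shared sites. Pairs
    with a zero denominator get NaN (flagged, excluded from pruning).
    """
    if g.n_samples < 2:
        raise ValueError("kinship requires at least two samples")
    calls = g.calls
    het = (calls == 1).astype(np.float64)
    hom_ref = (calls == 0).astype(np.float64)
    hom_alt = (calls == 2).astype(np.float64)
    called = (calls != MISSING).astype(np.float64)

    n_shared = called @ called.T
    n_het_het = het @ het.T
    n_opp_hom = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    # heterozygote counts restricted to sites called in the partner
    het_i = het @ called.T          # [i, j] = het count of i on shared sites
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_het_het - 2.0 * n_opp_hom) / denom, np.nan)
    return KinshipMatrix(list(g.sample_ids), phi, n_shared.astype(np.int64))


def prune_related(
    k: KinshipMatrix, g: GenotypeMatrix, threshold: float = 0.1
) -> tuple[GenotypeMatrix, list[dict]]:
    """Remove one member of each pair with kinship above ``threshold``.

    Greedy: while any retained pair exceeds the threshold, take the worst
    pair and drop the member with the higher missing-genotype fraction
    (tie: the lexicographically larger sample id). Returns the pruned
    matrix and a removal log of dicts (removed, partner, phi, reason).
    Undefined (NaN) kinship never triggers removal; such pairs are logged
    via a warning.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if k.sample_ids != g.sample_ids:
        raise ValueError("kinship and genotype matrices disagree on samples")
    n_undef = int(np.isnan(k.phi[np.triu_indices(k.n, 1)]).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} pair(s) with undefined kinship treated as unrelated",
            stacklevel=2,
        )
    missing_frac = g.missing_fraction()
    active = set(range(k.n))
    removed: list[dict] = []
    while True:
        candidates = [
            (i, j, v) for i, j, v in k.pairs_above(threshold) if i in active and j in active
        ]
        if not candidates:
            break
        i, j, v = candidates[0]
        mi, mj = missing_frac[i], missing_frac[j]
        if mi > mj:
            drop, keep = i, j
        elif mj > mi:
            drop, keep = j, i
        else:
            drop, keep = (i, j) if k.sample_ids[i] > k.sample_ids[j] else (j, i)
        active.remove(drop)
        removed.append(
            {
                "removed": k.sample_ids[drop],
                "partner": k.sample_ids[keep],
                "phi": float(v),
                "reason": f"kinship {v:.4f} > {threshold} "
                f"(missing fraction {missing_frac[drop]:.4f} vs {missing_frac[keep]:.4f})",
            }
        )
    kept_ids = [s for idx, s in enumerate(k.sample_ids) if idx in active]
    return g.take_samples(kept_ids), removed
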