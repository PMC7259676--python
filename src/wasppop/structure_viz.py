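"""Model-free structure summaries: identity-by-state distances, classical
(metric) MDS, balanced subsampling, and minimum-spanning haplotype networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_metadata import MISSING, GenotypeMatrix, HaplotypeSet
from .popgen_stats import PairwiseMatrix

__all__ = [
    "MDSResult",
    "HaplotypeNetwork",
    "ibs_distance",
    "classical_mds",
    "build_haplotype_network",
    "balanced_subsample",
]


@dataclass
class MDSResult:
    """Classical MDS embedding: axes ordered by decreasing eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray   # samples x k
    eigenvalues: np.ndarray   # k

    def to_frame(self) -> pd.DataFrame:
        cols = [f"C{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class HaplotypeNetwork:
    """Unique haplotypes with counts and a minimum-spanning network.

    ``nodes``: haplotype id -> dict(count, samples, populations).
    ``edges``: (idA, idB, steps, is_alternative); non-alternative edges form
    a spanning tree; alternative edges could replace a tree edge at equal
    total weight.
    """

    nodes: dict[str, dict]
    edges: list[tuple[str, str, int, bool]]
    haplotype_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return sum(n["count"] for n in self.nodes.values())

    def tree_edges(self) -> list[tuple[str, str, int]]:
        return [(a, b, w) for a, b, w, alt in self.edges if not alt]

    def total_tree_weight(self) -> int:
        return sum(w for _, _, w in self.tree_edges())

    def node_frame(self) -> pd.DataFrame:
        rows = []
        for hid, nd in self.nodes.items():
            rows.append(
                {
                    "haplotype": hid,
                    "count": nd["count"],
                    "samples": ",".join(nd["samples"]),
                    "populations": ";".join(f"{k}:{v}" for k, v in nd["populations"].items()),
                }
            )
        return pd.DataFrame(rows)

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["nodeA", "nodeB", "steps", "is_alternative"])

    def to_graph(self) -> nx.Graph:
        gr = nx.Graph()
        for hid, nd in self.nodes.items():
            gr.add_node(hid, count=nd["count"])
        for a, b, w, alt in self.edges:
            gr.add_edge(a, b, weight=w, is_alternative=alt)
        return gr


# ---------------------------------------------------------------------------


def ibs_distance(g: GenotypeMatrix) -> PairwiseMatrix:
    """1 - mean allele sharing over shared non-missing sites.

    Per shared site the dosage difference |gi - gj| in {0, 1, 2} maps to
    allele sharing {1, 0.5, 0}; the distance is one minus its mean. Pairs
    with no shared sites get NaN (flagged with a warning).
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = g.calls
    called = (calls != MISSING).astype(np.float64)
    dose = np.where(calls != MISSING, calls, 0).astype(np.float64)
    dose2 = dose**2
    shared = called @ called.T
    # sum over shared sites of |gi - gj|, via (gi - gj)^2 decomposition:
    # |gi - gj| in {0,1,2}; (gi-gj)^2 in {0,1,4} -> |d| = d^2 - 2*[d^2==4].
    # Simpler: |d| = d^2 for d in {0,1}; for d=2, |d|=2 while d^2=4.
    # Count opposite homozygotes separately.
    sq = dose2 @ called.T + called @ dose2.T - 2.0 * dose @ dose.T
    hom_ref = (calls == 0).astype(np.float64)
    hom_alt = (calls == 2).astype(np.float64)
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    abs_diff = sq - 2.0 * n_opp  # subtract (4 - 2) per opposite-homozygote site
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, abs_diff / (2.0 * shared), np.nan)
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        warnings.warn("some sample pairs share no called sites (distance NaN)", stacklevel=2)
    return PairwiseMatrix(list(g.sample_ids), dist, "ibs_distance")


def classical_mds(d: PairwiseMatrix, k: int = 10) -> MDSResult:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centers -1/2 * J D^2 J, eigendecomposes, and returns the top-k
    axes scaled by sqrt of their (positive) eigenvalues. Negative
    eigenvalues (non-Euclidean input) are dropped with a warning, possibly
    truncating k. Each axis's sign is canonicalized so its
    largest-magnitude loading is positive.
    """
    D = np.asarray(d.values, dtype=float)
    n = D.shape[0]
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0.0) * 1e-12
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from k={k}", stacklevel=2
        )
        k = n_pos
    vals_k, vecs_k = vals[:k], vecs[:, :k]
    coords = vecs_k * np.sqrt(vals_k)
    for a in range(k):
        lead = np.argmax(np.abs(coords[:, a]))
        if coords[lead, a] < 0:
            coords[:, a] = -coords[:, a]
    return MDSResult(list(d.labels), coords, vals_k)


def balanced_subsample(
    groups: dict[str, list[str]], n_per_group: int, seed: int | None = None
) -> list[str]:
    """Seeded random subsample of at most ``n_per_group`` ids per group,
    used to avoid over-representation of densely sampled regions."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for label in groups:
        ids = list(groups[label])
        if len(ids) > n_per_group:
            ids = list(rng.choice(ids, size=n_per_group, replace=False))
        out.extend(sorted(ids))
    return out


# ---------------------------------------------------------------------------
# Haplotype network


def _hamming_steps(codes: np.ndarray) -> np.ndarray:
    if codes.shape[0] == 1:
        return np.zeros((1, 1), dtype=int)
    d = squareform(pdist(codes, metric="hamming")) * codes.shape[1]
    return np.rint(d).astype(int)


def build_haplotype_network(
    h: HaplotypeSet, pops: dict[str, list[str]] | None = None
) -> HaplotypeNetwork:
    """Minimum-spanning network over unique haplotypes.

    Identical sequences collapse to one node (counts and per-population
    composition attached). Edges are Hamming distances in mutational
    steps; the spanning tree is Kruskal's with the deterministic tie-break
    (weight, nodeA, nodeB). Non-tree edges that could replace a tree edge
    at identical total weight (exact ties only) are included flagged
    ``is_alternative``. Columns containing an ambiguous base in any sample
    are dropped first.
    """
    if h.n == 0:
        raise ValueError("empty haplotype set")
    codes = h.to_codes()
    good = ~(codes == 255).any(axis=0)
    codes = codes[:, good]
    pop_of: dict[str, str] = {}
    if pops:
        for label, ids in pops.items():
            for sid in ids:
                pop_of[sid] = label

    seen: dict[bytes, str] = {}
    nodes: dict[str, dict] = {}
    hap_seq: dict[str, str] = {}
    members: dict[str, list[int]] = {}
    for i, sid in enumerate(h.sample_ids):
        key = codes[i].tobytes()
        if key not in seen:
            hid = f"H{len(seen) + 1}"
            seen[key] = hid
            nodes[hid] = {"count": 0, "samples": [], "populations": {}}
            members[hid] = []
            hap_seq[hid] = "".join("ACGT"[c] for c in codes[i])
        hid = seen[key]
        nodes[hid]["count"] += 1
        nodes[hid]["samples"].append(sid)
        members[hid].append(i)
        pop = pop_of.get(sid, "all")
        nodes[hid]["populations"][pop] = nodes[hid]["populations"].get(pop, 0) + 1

    hids = list(nodes)
    uniq = np.stack([codes[members[hid][0]] for hid in hids])
    steps = _hamming_steps(uniq)

    edges_all = sorted(
        (int(steps[i, j]), hids[i], hids[j])
        for i, j in itertools.combinations(range(len(hids)), 2)
    )
    uf = nx.utils.UnionFind(hids)
    tree: list[tuple[str, str, int]] = []
    rest: list[tuple[str, str, int]] = []
    for w, a, b in edges_all:
        if uf[a] != uf[b]:
            uf.union(a, b)
            tree.append((a, b, w))
        else:
            rest.append((a, b, w))

    mst = nx.Graph()
    mst.add_nodes_from(hids)
    for a, b, w in tree:
        mst.add_edge(a, b, weight=w)
    alternatives: list[tuple[str, str, int]] = []
    for a, b, w in rest:
        path = nx.shortest_path(mst, a, b)
        max_on_path = max(
            mst.edges[u, v]["weight"] for u, v in zip(path[:-1], path[1:])
        )
        if w == max_on_path:  # exact tie: swapping keeps total weight
            alternatives.append((a, b, w))

    edges = [(a, b, w, False) for a, b, w in tree] + [
        (a, b, w, True) for a, b, w in alternatives
    ]
    return HaplotypeNetwork(nodes=nodes, edges=edges, haplotype_sequences=hap_seq)
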