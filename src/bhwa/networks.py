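"""Signed similarity networks, triangle coherency, and the permutation null.

A three-node loop (triangle) in a signed similarity network is coherent
when the product of its three edge signs is positive — the structural-
balance rule: all-positive triangles and triangles with exactly two
negative edges close consistently, while one or three negative edges make
the loop self-contradictory. The census runs on the unfiltered network of
all defined pairs; the permutation null shuffles each entity's disturbance
values across the taxon axis within each rank and recomputes the
coherent/incoherent ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import networkx as nx
import numpy as np
import pandas as pd

from .core import SimilarityTable, _aggregate_matrices, _rank_pair_stats, rank_matrices
from .taxonomy import MultiRankEvidence

__all__ = [
    "SignedNetwork",
    "LoopCensus",
    "RandomizationResult",
    "build_network",
    "theoretical_max_loops",
    "loop_census",
    "randomization_test",
]


@dataclass
class SignedNetwork:
    """Nodes plus signed weighted edges (at most one per unordered pair)."""

    nodes: list[str]
    edges: pd.DataFrame  # node_i, node_j, similarity, fdr, sign

    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for r in self.edges.itertuples():
            g.add_edge(r.node_i, r.node_j, similarity=r.similarity,
                       fdr=r.fdr, sign=int(r.sign))
        return g

    def sign_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Node x node matrix of edge signs (0 = no edge)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        S = np.zeros((len(self.nodes), len(self.nodes)), dtype=np.int64)
        for r in self.edges.itertuples():
            i, j = idx[r.node_i], idx[r.node_j]
            S[i, j] = S[j, i] = int(r.sign)
        return S, self.nodes


@dataclass
class LoopCensus:
    total_loops: int
    coherent: int
    incoherent: int
    theoretical_max: int

    @property
    def ratio(self) -> float:
        """Coherent/incoherent; NaN sentinel when incoherent = 0."""
        if self.incoherent == 0:
            return float("nan")
        return self.coherent / self.incoherent


@dataclass
class RandomizationResult:
    iterations: int
    seed: int
    null_ratios: np.ndarray
    observed: LoopCensus
    observed_ratio: float
    null_median: float
    fold_vs_median: float
    empirical_p: float
    n_undefined: int = 0
    null_model: str = "within_entity"

    def __post_init__(self):
        assert len(self.null_ratios) == self.iterations


def build_network(
    similarities: SimilarityTable, fdr_threshold: float | None = 0.05
) -> SignedNetwork:
    """Signed network from one run's similarities.

    With ``fdr_threshold=None`` every defined non-self pair becomes an edge
    (the loop-census network); otherwise only pairs with fdr strictly below
    the threshold are kept. Zero-similarity pairs carry no edge. Raises if
    filtering empties the network.
    """
    df = similarities.table
    nonself = df["entity_i"] != df["entity_j"]
    keep = nonself & df["sim_weighted"].notna() & (df["sim_weighted"] != 0)
    if fdr_threshold is not None:
        keep &= df["fdr"] < fdr_threshold
    edges = df.loc[keep, ["entity_i", "entity_j", "sim_weighted", "fdr"]].rename(
        columns={"entity_i": "node_i", "entity_j": "node_j", "sim_weighted": "similarity"}
    )
    if not len(edges):
        raise ValueError("empty network: no pair survives the filter")
    edges["sign"] = np.sign(edges["similarity"]).astype(int)
    nodes = sorted(set(similarities.entities_a) | set(similarities.entities_b))
    return SignedNetwork(nodes=nodes, edges=edges.reset_index(drop=True))


def theoretical_max_loops(n_nodes: int) -> int:
    """Number of node triples: n(n-1)(n-2)/6."""
    if n_nodes < 3:
        raise ValueError("a three-node loop needs at least 3 nodes")
    return comb(n_nodes, 3)


def _census_from_sign_matrix(S: np.ndarray) -> LoopCensus:
    # Exact integer trace identities: for E = |S| (adjacency),
    # trace(E^3)/6 counts triangles, and each triangle contributes +-6 to
    # trace(S^3) according to its sign product, so trace(S^3)/6 equals
    # coherent - incoherent.
    E = np.abs(S)
    total = int(np.trace(E @ E @ E)) // 6
    diff = int(np.trace(S @ S @ S)) // 6
    coherent = (total + diff) // 2
    n = S.shape[0]
    tmax = theoretical_max_loops(n) if n >= 3 else 0
    return LoopCensus(total_loops=total, coherent=coherent,
                      incoherent=total - coherent, theoretical_max=tmax)


def loop_census(network: SignedNetwork) -> LoopCensus:
    """Count coherent/incoherent three-node loops (sign-product rule)."""
    S, _ = network.sign_matrix()
    return _census_from_sign_matrix(S)


def permute_within_rows(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row across the taxon axis.

    Preserves every row's multiset of values — the permutation null keeps
    each entity's disturbance profile, only scrambling which taxa carry it.
    """
    order = rng.random(D.shape).argsort(axis=1)
    return np.take_along_axis(D, order, axis=1)


def _sign_matrix_from_matrices(mats, null_rng=None, null_model="within_entity"):
    per_rank = []
    for D in mats:
        if null_rng is not None:
            if null_model == "within_entity":
                D = permute_within_rows(D, null_rng)
            elif null_model == "global":
                D = null_rng.permutation(D.ravel()).reshape(D.shape)
            else:
                raise ValueError(f"unknown null model {null_model!r}")
        per_rank.append(_rank_pair_stats(D))
    agg = _aggregate_matrices(per_rank, with_p=False)
    S = np.where(agg["defined"], np.sign(agg["sim_weighted"]), 0.0)
    np.fill_diagonal(S, 0)
    return S.astype(np.int64)


def randomization_test(
    evidence: MultiRankEvidence,
    iterations: int = 10_000,
    seed: int = 0,
    null_model: str = "within_entity",
) -> RandomizationResult:
    """Permutation null for the coherent/incoherent loop ratio.

    Each iteration permutes, within each rank, every entity's vector of D
    values across the taxon axis (preserving each row's multiset of
    values), recomputes all pairwise weighted similarities, and takes the
    loop-census ratio on the unfiltered network. Deterministic for a fixed
    seed. Iterations whose census has no incoherent loop yield a NaN
    sentinel, excluded from the null median (their count is reported).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    entities = evidence.entities()
    mats = [dm.D for dm in rank_matrices(evidence, entities).values()]
    if not mats:
        raise ValueError("no rank could be quantified (all degenerate)")

    observed = _census_from_sign_matrix(_sign_matrix_from_matrices(mats))
    rng = np.random.default_rng(seed)
    null_ratios = np.empty(iterations)
    for it in range(iterations):
        S = _sign_matrix_from_matrices(mats, null_rng=rng, null_model=null_model)
        null_ratios[it] = _census_from_sign_matrix(S).ratio

    n_undefined = int(np.isnan(null_ratios).sum())
    if n_undefined == iterations:
        raise ValueError("degenerate evidence: every null ratio is undefined")
    null_median = float(np.nanmedian(null_ratios))
    obs_ratio = observed.ratio
    fold = obs_ratio / null_median if null_median and not np.isnan(obs_ratio) else float("nan")
    defined = null_ratios[~np.isnan(null_ratios)]
    emp_p = float(np.mean(defined >= obs_ratio)) if not np.isnan(obs_ratio) else float("nan")
    return RandomizationResult(
        iterations=iterations, seed=seed, null_ratios=null_ratios,
        observed=observed, observed_ratio=obs_ratio, null_median=null_median,
        fold_vs_median=fold, empirical_p=emp_p, n_undefined=n_undefined,
        null_model=null_model,
    )
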