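"""Complete-linkage clustering of entities and similarity-matrix comparison.

Entities are clustered on distance 1 - similarity (range [0, 2]) with
complete-linkage agglomeration; the dendrogram can be cut into k clusters
(labels C1..Ck ordered by cluster size) and exported as Newick with merge
heights as branch lengths. Two similarity matrices over the same entities
(e.g. microbiota-based vs etiology-based) are compared by Pearson
correlation of their common off-diagonal upper-triangle values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

__all__ = [
    "ClusterAssignment",
    "ComparisonResult",
    "cluster_entities",
    "compare_similarity_matrices",
    "linkage_to_newick",
]

_UNSAFE = re.compile(r"[\s,():;\[\]']")


def _newick_label(label: str) -> str:
    return _UNSAFE.sub("_", str(label))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_newick_label(labels[node.id])}:{length:.12g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.12g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


@dataclass
class ClusterAssignment:
    """Entity -> cluster label (C1..Ck) with the underlying linkage."""

    labels: dict[str, str]
    linkage: np.ndarray
    entities: list[str]
    k: int

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, self.entities)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for entity, label in self.labels.items():
            out.setdefault(label, []).append(entity)
        return {label: sorted(members) for label, members in sorted(out.items())}


def cluster_entities(similarity: pd.DataFrame, k: int) -> ClusterAssignment:
    """Complete-linkage clustering of a symmetric similarity matrix.

    ``similarity`` is a square DataFrame in [-1, 1] with unit diagonal.
    Undefined entries are rejected with a message naming the pairs. Labels
    C1..Ck are ordered by decreasing cluster size, ties broken by the
    alphabetically first member.
    """
    entities = list(similarity.index)
    n = len(entities)
    if list(similarity.columns) != entities:
        raise ValueError("similarity matrix must have identical row/column entities")
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    values = similarity.to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values))
    if len(bad):
        pairs = sorted({tuple(sorted((entities[i], entities[j]))) for i, j in bad})
        raise ValueError(f"undefined similarity for pairs: {pairs[:10]}")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-9):
        raise ValueError("similarity matrix must have unit diagonal")

    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    members: dict[int, list[str]] = {}
    for entity, c in zip(entities, raw):
        members.setdefault(int(c), []).append(entity)
    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    labels = {}
    for rank_idx, (_, ents) in enumerate(ordered, start=1):
        for e in ents:
            labels[e] = f"C{rank_idx}"
    return ClusterAssignment(labels=labels, linkage=Z, entities=entities, k=len(ordered))


@dataclass
class ComparisonResult:
    pearson_r: float
    p: float
    n_pairs: int
    per_category: pd.DataFrame | None = None


def compare_similarity_matrices(
    A: pd.DataFrame,
    B: pd.DataFrame,
    categories: dict[str, str] | None = None,
) -> ComparisonResult:
    """Pearson correlation of two similarity matrices' common pairs.

    Compares off-diagonal upper-triangle values defined in both matrices
    over the shared entity set; with ``categories`` (entity -> category)
    also reports within-category correlations. Raises with fewer than 3
    common pairs.
    """
    common = sorted(set(A.index) & set(B.index))
    if len(common) < 3:
        raise ValueError("need at least 3 shared entities")
    a = A.loc[common, common].to_numpy(dtype=float)
    b = B.loc[common, common].to_numpy(dtype=float)
    iu = np.triu_indices(len(common), k=1)
    av, bv = a[iu], b[iu]
    ok = ~(np.isnan(av) | np.isnan(bv))
    if ok.sum() < 3:
        raise ValueError("need at least 3 pairs defined in both matrices")
    r, p = stats.pearsonr(av[ok], bv[ok])

    per_category = None
    if categories is not None:
        rows = []
        cats = sorted({categories[e] for e in common if e in categories})
        for cat in cats:
            ents = [e for e in common if categories.get(e) == cat]
            if len(ents) < 3:
                continue
            sub_a = A.loc[ents, ents].to_numpy(dtype=float)
            sub_b = B.loc[ents, ents].to_numpy(dtype=float)
            sub_iu = np.triu_indices(len(ents), k=1)
            sav, sbv = sub_a[sub_iu], sub_b[sub_iu]
            sok = ~(np.isnan(sav) | np.isnan(sbv))
            if sok.sum() < 3:
                continue
            cr, cp = stats.pearsonr(sav[sok], sbv[sok])
            rows.append({"category": cat, "pearson_r": cr, "p": cp,
                         "n_pairs": int(sok.sum())})
        per_category = pd.DataFrame(rows)
    return ComparisonResult(pearson_r=float(r), p=float(p),
                            n_pairs=int(ok.sum()), per_category=per_category)
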