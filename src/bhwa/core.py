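"""The BHWA core: disturbance quantification and weighted similarity.

For each taxonomic rank the signed evidence tallies become a disturbance
strength

    D[i, m] = alpha[i, m] * C[i, m] * ln(N / n[m])

where alpha is the net change direction of taxon m under entity i, C the
net evidence count, N the number of entities with any evidence at the
rank, and n[m] the number of entities associated with taxon m. The
ln(N/n) factor is an IDF-style coefficient: taxa disturbed by nearly every
entity are down-weighted, entity-specific taxa up-weighted.

Per rank, similarity between two entities is the cosine of their
disturbance vectors. Treating the cosine as a correlation-like statistic
over its taxon support of size m gives t = SIM * sqrt(df / (1 - SIM^2))
with df = m - 2, hence a deviation sigma = SIM / t = sqrt((1 - SIM^2)/df)
that is finite and positive for all |SIM| < 1 (including SIM = 0). Each
rank's weight is W = 1/sigma, and the six ranks aggregate into

    SIM_ij = sum_r W_r SIM_r / sum_r W_r,   sigma_bar = sqrt(1 / sum_r W_r)

with a two-tailed Student-t p-value for t = SIM_ij / sigma_bar on
df = (sum of contributing supports) - 2 degrees of freedom, followed by
Benjamini-Hochberg FDR control over the run's non-self pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import EvidenceTable
from .ranks import RANKS
from .taxonomy import MultiRankEvidence

__all__ = [
    "DegenerateRankError",
    "DisturbanceMatrix",
    "RankSimilarity",
    "AggregateSimilarity",
    "SimilarityTable",
    "apply_min_disturbance_filter",
    "quantify_disturbance",
    "rank_similarity",
    "aggregate_weighted",
    "bh_fdr",
    "pairwise_similarity",
]

# |SIM| is clamped just below 1 before the t-statistic so that
# identical-vector pairs get a very large but finite weight.
SIM_CLAMP = 1.0 - 1e-12


class DegenerateRankError(ValueError):
    """A rank with fewer than two entities cannot be quantified."""


@dataclass
class DisturbanceMatrix:
    """Per-rank entity x taxon disturbance strengths.

    ``entities`` are the matrix rows (a caller-supplied ordering may
    include entities with no evidence at this rank; their rows are zero and
    ``present`` is False). ``N`` counts present entities only; ``n[m]`` the
    present entities with any evidence for taxon m.
    """

    rank: str
    entities: list[str]
    taxa: list[str]
    D: np.ndarray
    alpha: np.ndarray
    C: np.ndarray
    N: int
    n: np.ndarray
    present: np.ndarray


@dataclass(frozen=True)
class RankSimilarity:
    rank: str
    sim: float
    m_shared: int
    t: float
    sigma: float
    weight: float
    contributing: bool


@dataclass(frozen=True)
class AggregateSimilarity:
    sim_weighted: float
    sigma_bar: float
    t_score: float
    df: int
    p: float


@dataclass
class SimilarityTable:
    """Long-format weighted similarities for one run (one FDR family).

    Columns: entity_i, entity_j, sim_weighted, sigma_bar, t_score, df, p,
    fdr, then sim_<rank>, w_<rank>, m_<rank> for each rank (NaN where the
    rank did not contribute). Within-set runs list each unordered pair once
    plus self rows with similarity 1 (excluded from the FDR family); cross
    runs list all |A| x |B| pairs.
    """

    table: pd.DataFrame
    mode: str
    entities_a: list[str]
    entities_b: list[str]

    def __len__(self) -> int:
        return len(self.table)

    def matrix(self, column: str = "sim_weighted") -> pd.DataFrame:
        """Square symmetric matrix view (within-set runs only)."""
        if self.mode == "cross":
            raise ValueError("matrix() is defined for within-set runs only")
        ents = self.entities_a
        mat = pd.DataFrame(np.nan, index=ents, columns=ents)
        for row in self.table.itertuples():
            mat.loc[row.entity_i, row.entity_j] = getattr(row, column)
            mat.loc[row.entity_j, row.entity_i] = getattr(row, column)
        return mat


def apply_min_disturbance_filter(
    evidence: EvidenceTable, threshold: int = 3
) -> EvidenceTable:
    """Drop entities documented with fewer than *threshold* distinct taxa.

    Counted at the reported-rank layer (distinct microbe names in the raw
    table), in a single pass; taxa referenced only by removed entities
    disappear with them. Raises if nothing survives.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rec = evidence.records
    n_taxa = rec.groupby("entity_name")["microbe_name"].nunique()
    keep = set(n_taxa[n_taxa >= threshold].index)
    filtered = rec[rec["entity_name"].isin(keep)].reset_index(drop=True)
    if not len(filtered):
        raise ValueError(
            f"min-disturbance filter (threshold={threshold}) removed every entity"
        )
    return replace(evidence, records=filtered)


def quantify_disturbance(
    counts: MultiRankEvidence, rank: str, entities: Sequence[str] | None = None
) -> DisturbanceMatrix:
    """Disturbance-strength matrix for one rank.

    alpha = sign(c_inc - c_dec), C = |c_inc - c_dec| (net direction; ties
    give alpha = 0 and D = 0), D = alpha * C * ln(N / n). Raises
    DegenerateRankError when fewer than two entities carry evidence at the
    rank (ln(N/n) is degenerate there).
    """
    df = counts.counts.get(rank)
    if df is None or df["entity"].nunique() < 2:
        raise DegenerateRankError(f"rank {rank!r} has fewer than 2 entities")
    present_set = sorted(df["entity"].unique())
    if entities is None:
        entities = present_set
    else:
        entities = list(entities)
        missing = set(present_set) - set(entities)
        if missing:
            raise ValueError(f"entity ordering omits entities with evidence: {sorted(missing)}")
    taxa = sorted(df["taxon"].unique())
    e_idx = {e: i for i, e in enumerate(entities)}
    t_idx = {t: j for j, t in enumerate(taxa)}

    inc = np.zeros((len(entities), len(taxa)), dtype=np.int64)
    dec = np.zeros_like(inc)
    for row in df.itertuples():
        inc[e_idx[row.entity], t_idx[row.taxon]] = row.c_inc
        dec[e_idx[row.entity], t_idx[row.taxon]] = row.c_dec

    net = inc - dec
    alpha = np.sign(net)
    C = np.abs(net)
    any_evidence = (inc + dec) > 0
    present = any_evidence.any(axis=1)
    N = int(present.sum())
    n = any_evidence.sum(axis=0)  # entities associated with each taxon
    with np.errstate(divide="ignore"):
        idf = np.log(N / n.astype(float))
    idf[n == 0] = 0.0
    D = alpha * C * idf[np.newaxis, :]
    return DisturbanceMatrix(
        rank=rank, entities=list(entities), taxa=taxa, D=D, alpha=alpha, C=C,
        N=N, n=n, present=present,
    )


def rank_similarity(Di, Dj, rank: str = "") -> RankSimilarity:
    """Cosine similarity of two disturbance vectors with t, sigma and weight.

    The support is the set of taxa where either vector is nonzero; its size
    m gives df = m - 2. A rank contributes only when df >= 1 and both
    vectors are nonzero.
    """
    Di = np.asarray(Di, dtype=float)
    Dj = np.asarray(Dj, dtype=float)
    if Di.shape != Dj.shape:
        raise ValueError("vectors must be indexed over the same taxon universe")
    ni = float(np.linalg.norm(Di))
    nj = float(np.linalg.norm(Dj))
    m = int(((Di != 0) | (Dj != 0)).sum())
    df = m - 2
    sim = float(Di @ Dj / (ni * nj)) if ni > 0 and nj > 0 else float("nan")
    if ni == 0 or nj == 0 or df < 1:
        return RankSimilarity(rank, sim, m, float("nan"), float("nan"), float("nan"), False)
    clamped = min(max(sim, -SIM_CLAMP), SIM_CLAMP)
    sigma = float(np.sqrt((1.0 - clamped**2) / df))
    t = clamped / sigma  # == clamped * sqrt(df / (1 - clamped^2))
    return RankSimilarity(rank, sim, m, t, sigma, 1.0 / sigma, True)


def aggregate_weighted(ranks: Sequence[RankSimilarity]) -> AggregateSimilarity:
    """Inverse-deviation weighted aggregation across contributing ranks."""
    contrib = [r for r in ranks if r.contributing]
    if not contrib:
        raise ValueError("no contributing rank: weighted similarity undefined")
    w = np.array([r.weight for r in contrib])
    s = np.array([r.sim for r in contrib])
    wsum = float(w.sum())
    sim_weighted = float((w * s).sum() / wsum)
    sigma_bar = float(np.sqrt(1.0 / wsum))
    t_score = sim_weighted / sigma_bar
    df = int(sum(r.m_shared for r in contrib)) - 2
    p = float(2.0 * stats.t.sf(abs(t_score), df))
    return AggregateSimilarity(sim_weighted, sigma_bar, t_score, df, p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized pairwise machinery (shared with the randomization null)

def _rank_pair_stats(DA: np.ndarray, DB: np.ndarray | None = None):
    """Pairwise cosine/support/weight matrices for one rank.

    Returns (sim, m, W, contrib): sim is NaN where a norm is zero; W is 0
    on non-contributing pairs so it drops out of the aggregation sums.
    """
    B = DA if DB is None else DB
    na = np.linalg.norm(DA, axis=1)
    nb = np.linalg.norm(B, axis=1)
    denom = np.outer(na, nb)
    G = DA @ B.T
    sim = np.divide(G, denom, out=np.full_like(G, np.nan), where=denom > 0)
    nzA = (DA != 0).astype(np.int64)
    nzB = (B != 0).astype(np.int64)
    m = nzA.sum(axis=1)[:, None] + nzB.sum(axis=1)[None, :] - nzA @ nzB.T
    df = m - 2
    contrib = (df >= 1) & (na[:, None] > 0) & (nb[None, :] > 0)
    clamped = np.clip(sim, -SIM_CLAMP, SIM_CLAMP)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.sqrt((1.0 - clamped**2) / np.maximum(df, 1))
        W = np.where(contrib, 1.0 / sigma, 0.0)
    return sim, m, W, contrib


def _aggregate_matrices(per_rank, with_p: bool = True):
    """Aggregate per-rank stat matrices into weighted-similarity matrices."""
    num = den = 0.0
    msum = None
    for sim, m, W, contrib in per_rank:
        num = num + W * np.where(contrib, sim, 0.0)
        den = den + W
        msum = (0 if msum is None else msum) + np.where(contrib, m, 0)
    defined = den > 0
    sim_w = np.divide(num, den, out=np.full_like(den, np.nan), where=defined)
    out = {"sim_weighted": sim_w, "defined": defined}
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_bar = np.where(defined, np.sqrt(1.0 / den), np.nan)
    out["sigma_bar"] = sigma_bar
    out["df"] = np.where(defined, msum - 2, 0).astype(int)
    t = np.divide(sim_w, sigma_bar, out=np.full_like(den, np.nan), where=defined)
    out["t_score"] = t
    if with_p:
        p = np.full_like(den, np.nan)
        p[defined] = 2.0 * stats.t.sf(np.abs(t[defined]), out["df"][defined])
        out["p"] = p
    return out


def _align_columns(dm_a: DisturbanceMatrix, dm_b: DisturbanceMatrix, align: str):
    """Reindex two rank matrices onto a shared taxon axis (union or intersection)."""
    if align == "union":
        taxa = sorted(set(dm_a.taxa) | set(dm_b.taxa))
    elif align == "intersection":
        taxa = sorted(set(dm_a.taxa) & set(dm_b.taxa))
    else:
        raise ValueError(f"unknown alignment {align!r}")

    def reindex(dm):
        idx = {t: j for j, t in enumerate(dm.taxa)}
        out = np.zeros((dm.D.shape[0], len(taxa)))
        for j, t in enumerate(taxa):
            if t in idx:
                out[:, j] = dm.D[:, idx[t]]
        return out

    return reindex(dm_a), reindex(dm_b)


def rank_matrices(
    evidence: MultiRankEvidence, entities: Sequence[str] | None = None
) -> dict[str, DisturbanceMatrix]:
    """Quantify every non-degenerate rank on a fixed entity ordering."""
    entities = list(entities) if entities is not None else evidence.entities()
    out: dict[str, DisturbanceMatrix] = {}
    for rank in RANKS:
        try:
            out[rank] = quantify_disturbance(evidence, rank, entities=entities)
        except DegenerateRankError:
            continue
    return out


def pairwise_similarity(
    evidence_a: MultiRankEvidence,
    evidence_b: MultiRankEvidence | None = None,
    mode: str | None = None,
    align: str = "union",
) -> SimilarityTable:
    """All pairwise weighted similarities for one run (one FDR family).

    Within-set runs (``evidence_b`` omitted) produce each unordered pair
    once plus self rows (similarity 1, excluded from the FDR family).
    Cross-set runs quantify each side with its own N and n, align taxon
    vectors per rank on the union (default) or intersection of the two
    universes, and produce every (a, b) pair.
    """
    ents_a = evidence_a.entities()
    if len(ents_a) < 2 and evidence_b is None:
        raise ValueError("need at least 2 entities for pairwise similarity")
    cross = evidence_b is not None
    mode = mode or ("cross" if cross else "within")

    per_rank = {}
    if cross:
        ents_b = evidence_b.entities()
        if not ents_a or not ents_b:
            raise ValueError("both entity sets must be non-empty")
        mats_a = rank_matrices(evidence_a, ents_a)
        mats_b = rank_matrices(evidence_b, ents_b)
        for rank in RANKS:
            if rank in mats_a and rank in mats_b:
                DA, DB = _align_columns(mats_a[rank], mats_b[rank], align)
                per_rank[rank] = _rank_pair_stats(DA, DB)
    else:
        ents_b = ents_a
        mats_a = rank_matrices(evidence_a, ents_a)
        for rank, dm in mats_a.items():
            per_rank[rank] = _rank_pair_stats(dm.D)

    if not per_rank:
        raise ValueError("no rank could be quantified (all degenerate)")
    agg = _aggregate_matrices(per_rank.values())

    rows = []
    if cross:
        pair_index = [(i, j) for i in range(len(ents_a)) for j in range(len(ents_b))]
    else:
        pair_index = [
            (i, j) for i in range(len(ents_a)) for j in range(i, len(ents_a))
        ]
    for i, j in pair_index:
        if not cross and i == j:
            rows.append({"entity_i": ents_a[i], "entity_j": ents_a[j],
                         "sim_weighted": 1.0, "sigma_bar": np.nan,
                         "t_score": np.nan, "df": np.nan, "p": np.nan})
            continue
        defined = bool(agg["defined"][i, j])
        row = {
            "entity_i": ents_a[i],
            "entity_j": ents_b[j],
            "sim_weighted": agg["sim_weighted"][i, j] if defined else np.nan,
            "sigma_bar": agg["sigma_bar"][i, j],
            "t_score": agg["t_score"][i, j],
            "df": agg["df"][i, j] if defined else np.nan,
            "p": agg["p"][i, j] if defined else np.nan,
        }
        for rank, (sim, m, W, contrib) in per_rank.items():
            ok = bool(contrib[i, j])
            row[f"sim_{rank}"] = sim[i, j] if ok else np.nan
            row[f"w_{rank}"] = W[i, j] if ok else np.nan
            row[f"m_{rank}"] = m[i, j] if ok else np.nan
        rows.append(row)

    table = pd.DataFrame(rows)
    nonself = table["entity_i"] != table["entity_j"]
    family = nonself & table["p"].notna()
    table["fdr"] = np.nan
    if family.any():
        table.loc[family, "fdr"] = bh_fdr(table.loc[family, "p"].to_numpy())
    return SimilarityTable(table=table, mode=mode, entities_a=ents_a,
                           entities_b=list(ents_b))
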