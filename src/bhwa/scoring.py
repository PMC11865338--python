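"""Body-site-specific disturbance scores.

Microbiota evidence is segmented by the anatomical site the samples came
from; sites documenting only a single disease are dropped (no within-site
contrast is possible). Within each retained site the disturbance strengths
are recomputed site-locally (N and n of the IDF coefficient count only the
site's diseases), squashed into (-1, 1) by the logistic map

    D_hat = 2 / (1 + e^(-D)) - 1   (identically tanh(D/2))

and a disease's disturbance score at the site is the Euclidean norm of its
normalized strengths across all six ranks:

    DS_i = sqrt( sum_ranks sum_taxa D_hat^2 ).

Larger DS = greater capacity of the disease to disturb that site's
microbiota. The sign of each cell (increase vs decrease) is lost in DS but
retained in the normalized-strength table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import DegenerateRankError, quantify_disturbance
from .io import EvidenceTable
from .ranks import RANKS
from .taxonomy import MultiRankEvidence, TaxonomyTable, propagate_up

logger = logging.getLogger(__name__)

__all__ = [
    "BodySitePartition",
    "partition_by_body_site",
    "sigmoid_normalize",
    "disturbance_score",
    "disturbance_scores",
    "normalized_strengths",
]


@dataclass
class BodySitePartition:
    """Evidence for one body site, propagated across ranks."""

    site: str
    evidence: MultiRankEvidence
    n_diseases: int


def partition_by_body_site(
    evidence: EvidenceTable,
    taxonomy: TaxonomyTable,
    entity_type: str = "disease",
) -> dict[str, BodySitePartition]:
    """Segment evidence by body site and drop single-disease sites.

    Rows without a body-site label are excluded (logged). Each partition's
    evidence is propagated with the shared taxonomy; quantification inside
    a partition is site-local by construction. Raises if no site survives.
    """
    rec = evidence.subset(entity_type).records
    unlabeled = int((rec["body_site"] == "").sum())
    if unlabeled:
        logger.info("excluding %d evidence rows without a body-site label", unlabeled)
    rec = rec[rec["body_site"] != ""]

    partitions: dict[str, BodySitePartition] = {}
    dropped = []
    for site, sub in rec.groupby("body_site"):
        n_diseases = sub["entity_name"].nunique()
        if n_diseases < 2:
            dropped.append(site)
            continue
        sub_table = EvidenceTable(records=sub.reset_index(drop=True))
        partitions[site] = BodySitePartition(
            site=site,
            evidence=propagate_up(sub_table, taxonomy),
            n_diseases=n_diseases,
        )
    if dropped:
        logger.info("dropped single-disease sites: %s", sorted(dropped))
    if not partitions:
        raise ValueError("no body site survives the single-disease filter")
    return partitions


def sigmoid_normalize(D):
    """Squash disturbance strength into (-1, 1): 2/(1 + e^(-D)) - 1.

    Odd and strictly increasing; scores near +1 indicate increased
    relative abundance under the disease, near -1 decreased.
    """
    return 2.0 * expit(np.asarray(D, dtype=float)) - 1.0


def _site_rank_matrices(partition: BodySitePartition):
    for rank in RANKS:
        try:
            yield rank, quantify_disturbance(partition.evidence, rank)
        except DegenerateRankError:
            continue


def disturbance_score(
    partition: BodySitePartition, disease: str
) -> tuple[float, dict[str, float]]:
    """DS of one disease at one site, with per-rank squared contributions.

    DS^2 is the sum of the per-rank contributions; DS = 0 iff every
    site-local strength is 0. Raises KeyError if the disease carries no
    evidence at the site.
    """
    if disease not in partition.evidence.entities():
        raise KeyError(f"disease {disease!r} absent from site {partition.site!r}")
    contributions = {rank: 0.0 for rank in RANKS}
    for rank, dm in _site_rank_matrices(partition):
        if disease not in dm.entities:
            continue
        row = dm.D[dm.entities.index(disease)]
        contributions[rank] = float((sigmoid_normalize(row) ** 2).sum())
    ds = float(np.sqrt(sum(contributions.values())))
    return ds, contributions


def disturbance_scores(
    partitions: dict[str, BodySitePartition] | BodySitePartition,
) -> pd.DataFrame:
    """DS table: one row per (disease, body site).

    Columns: disease, body_site, DS, n_cells (evidence-bearing
    (rank, taxon) cells, a strict upper bound sqrt(n_cells) > DS), and the
    per-rank squared contributions.
    """
    if isinstance(partitions, BodySitePartition):
        partitions = {partitions.site: partitions}
    rows = []
    for site in sorted(partitions):
        part = partitions[site]
        cells = {
            e: sum(
                int((df["entity"] == e).sum()) for df in part.evidence.counts.values()
            )
            for e in part.evidence.entities()
        }
        for disease in part.evidence.entities():
            ds, contrib = disturbance_score(part, disease)
            rows.append(
                {
                    "disease": disease,
                    "body_site": site,
                    "DS": ds,
                    "n_cells": cells[disease],
                    **{f"contrib_{r}": contrib[r] for r in RANKS},
                }
            )
    return pd.DataFrame(rows)


def normalized_strengths(partition: BodySitePartition) -> pd.DataFrame:
    """Long table of signed normalized strengths D_hat per cell.

    Retains the direction information that the Euclidean norm discards.
    """
    rows = []
    for rank, dm in _site_rank_matrices(partition):
        dhat = sigmoid_normalize(dm.D)
        for i, disease in enumerate(dm.entities):
            for j, taxon in enumerate(dm.taxa):
                if dm.D[i, j] != 0 or (dm.C[i, j] > 0):
                    rows.append(
                        {
                            "disease": disease,
                            "body_site": partition.site,
                            "rank": rank,
                            "taxon": taxon,
                            "D": dm.D[i, j],
                            "D_hat": dhat[i, j],
                        }
                    )
    return pd.DataFrame(rows)
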