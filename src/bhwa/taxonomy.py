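"""Taxonomic lineages and upward evidence propagation.

A disturbance reported at a low rank (e.g. an increase of a genus) also
says something at every strictly higher rank reachable through the genus's
lineage: the family, order, class and phylum that contain it were likewise
disturbed. Evidence is therefore propagated upward — never downward, since
a phylum-level report carries no information about any particular member
genus — and tallied into signed direction counts per (entity, taxon, rank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import pandas as pd

from .ranks import RANKS, higher_ranks

if TYPE_CHECKING:  # pragma: no cover
    from .io import EvidenceTable

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomyRecord",
    "TaxonomyTable",
    "MultiRankEvidence",
    "propagate_up",
    "aggregate_direction_counts",
]

COUNT_COLUMNS = ["entity", "taxon", "c_inc", "c_dec"]


@dataclass(frozen=True)
class TaxonomyRecord:
    """One taxon with its rank and its (possibly partial) lineage above."""

    name: str
    rank: str
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValueError(f"unsupported rank {self.rank!r} for taxon {self.name!r}")
        allowed = set(higher_ranks(self.rank))
        bad = set(self.lineage) - allowed
        if bad:
            raise ValueError(
                f"lineage of {self.name!r} ({self.rank}) assigns ranks {sorted(bad)} "
                "at or below the taxon's own rank"
            )


class TaxonomyTable:
    """Case-insensitive taxon-name -> TaxonomyRecord lookup.

    Identical duplicate records deduplicate; two records for one name with
    a different rank or lineage conflict and raise.
    """

    def __init__(self, records: Iterable[TaxonomyRecord] = ()):
        self._by_key: dict[str, TaxonomyRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: TaxonomyRecord) -> None:
        key = record.name.casefold()
        existing = self._by_key.get(key)
        if existing is not None and existing != record:
            raise ValueError(
                f"conflicting taxonomy records for taxon {record.name!r}: "
                f"{existing} vs {record}"
            )
        self._by_key[key] = record

    def get(self, name: str) -> TaxonomyRecord | None:
        return self._by_key.get(name.casefold())

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self._by_key


@dataclass
class MultiRankEvidence:
    """Signed direction counts per rank.

    ``counts`` maps each rank with any evidence to a frame with columns
    entity, taxon, c_inc, c_dec (c_inc + c_dec >= 1 on every row). A taxon
    name appears at exactly one rank across the whole object.
    """

    counts: dict[str, pd.DataFrame]
    n_unresolved: int = 0

    def entities(self) -> list[str]:
        names: set[str] = set()
        for df in self.counts.values():
            names.update(df["entity"])
        return sorted(names)

    def taxa(self, rank: str) -> list[str]:
        df = self.counts.get(rank)
        return sorted(df["taxon"].unique()) if df is not None else []

    def n_events(self, rank: str) -> int:
        df = self.counts.get(rank)
        return 0 if df is None else int((df["c_inc"] + df["c_dec"]).sum())


def propagate_up(evidence: "EvidenceTable", taxonomy: TaxonomyTable) -> MultiRankEvidence:
    """Propagate every evidence row to its reported rank and all higher ranks.

    Each row contributes one signed event at its reported rank and one at
    every strictly higher rank its lineage names. A microbe absent from the
    taxonomy is treated as a rank-labeled taxon on its own: it contributes
    at its reported rank only (counted in ``n_unresolved`` and logged). A
    taxonomy record whose rank contradicts the reported rank raises.
    """
    events: list[tuple[str, str, str, int]] = []  # (entity, taxon, rank, direction)
    n_unresolved = 0
    for row in evidence.records.itertuples():
        rank, microbe = row.rank, row.microbe_name
        rec = taxonomy.get(microbe)
        if rec is not None and rec.rank != rank:
            raise ValueError(
                f"microbe {microbe!r} reported at rank {rank!r} but the taxonomy "
                f"places it at {rec.rank!r}"
            )
        events.append((row.entity_name, microbe, rank, row.direction))
        if rec is None:
            n_unresolved += 1
            logger.debug("no lineage for %r; contributing at %s only", microbe, rank)
            continue
        for hrank in higher_ranks(rank):
            ancestor = rec.lineage.get(hrank)
            if ancestor:
                events.append((row.entity_name, ancestor, hrank, row.direction))
    mre = aggregate_direction_counts(events)
    mre.n_unresolved = n_unresolved
    return mre


def aggregate_direction_counts(
    events: Iterable[tuple[str, str, str, int]]
) -> MultiRankEvidence:
    """Tally propagated events into per-(entity, taxon, rank) counts."""
    events = list(events)
    if not events:
        return MultiRankEvidence(counts={})
    df = pd.DataFrame(events, columns=["entity", "taxon", "rank", "direction"])
    bad = df[~df["direction"].isin((1, -1))]
    if len(bad):
        raise ValueError(f"directions must be +1/-1; got {sorted(bad['direction'].unique())}")

    # a taxon name must live at exactly one rank
    rank_count = df.groupby("taxon")["rank"].nunique()
    homonyms = rank_count[rank_count > 1]
    if len(homonyms):
        raise ValueError(
            f"taxa appearing at more than one rank: {sorted(homonyms.index)}"
        )

    counts: dict[str, pd.DataFrame] = {}
    for rank in RANKS:
        sub = df[df["rank"] == rank]
        if not len(sub):
            continue
        tally = (
            sub.assign(
                c_inc=(sub["direction"] == 1).astype(int),
                c_dec=(sub["direction"] == -1).astype(int),
            )
            .groupby(["entity", "taxon"], as_index=False)[["c_inc", "c_dec"]]
            .sum()
            .sort_values(["entity", "taxon"], ignore_index=True)
        )
        counts[rank] = tally[COUNT_COLUMNS]
    return MultiRankEvidence(counts=counts)
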