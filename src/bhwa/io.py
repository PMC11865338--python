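"""Reading and writing the pipeline's external formats.

Evidence tables are long-format delimited text, one row per documented
microbiota disturbance (a fiber intervention or a disease state reported to
increase or decrease a taxon's relative abundance). Taxonomy tables map
microbe names to six-rank lineages, either as Greengenes-style prefixed
lineage strings or as explicit per-rank columns. All result tables are
written as TSV with full floating-point precision so that a write/read
round trip is the identity to at least 12 significant digits.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .ranks import GREENGENES_PREFIXES, RANKS

__all__ = [
    "Dialect",
    "EvidenceTable",
    "read_evidence",
    "read_taxonomy",
    "write_similarity",
    "read_similarity",
    "write_edges",
    "read_edges",
    "write_network_json",
    "write_census",
    "write_ds_table",
    "read_ds_table",
    "write_clusters",
    "write_newick",
]

ENTITY_TYPES = ("fiber", "disease")

_DIRECTION_TOKENS = {
    "increase": 1,
    "increased": 1,
    "+1": 1,
    "1": 1,
    "decrease": -1,
    "decreased": -1,
    "-1": -1,
}


@dataclass(frozen=True)
class Dialect:
    """Delimiter and column-name configuration for evidence tables.

    The curated-database schema is not standardized, so column names are
    remappable; defaults follow the package's own TSV convention.
    """

    delimiter: str = "\t"
    source_id: str = "source_id"
    entity_type: str = "entity_type"
    entity_name: str = "entity_name"
    microbe_name: str = "microbe_name"
    rank: str = "rank"
    direction: str = "direction"
    body_site: str = "body_site"
    notes: str = "notes"

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (
            self.source_id,
            self.entity_type,
            self.entity_name,
            self.microbe_name,
            self.rank,
            self.direction,
        )


DEFAULT_DIALECT = Dialect()

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace (no case folding here)."""
    return _WS.sub(" ", str(name).strip())


def canonicalize_names(series: pd.Series) -> pd.Series:
    """Whitespace-normalize and unify case variants to first-seen spelling.

    Matching is case-insensitive by contract; the first spelling observed
    for a case-folded key becomes the canonical display form.
    """
    cleaned = series.map(normalize_name)
    first: dict[str, str] = {}
    return cleaned.map(lambda v: first.setdefault(v.casefold(), v))


@dataclass
class EvidenceTable:
    """Parsed disturbance evidence plus the rows rejected while parsing.

    ``records`` columns: source_id, entity_type, entity_name, microbe_name,
    rank, direction (+1/-1 int), body_site (may be ""), notes.
    ``rejected`` carries the original row values plus a ``reason`` column;
    parsing never silently drops rows (len(records) + len(rejected) equals
    the input row count).
    """

    records: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, entity_type: str) -> "EvidenceTable":
        """Rows for one entity type (fiber or disease)."""
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type: {entity_type!r}")
        sub = self.records[self.records["entity_type"] == entity_type]
        return replace(self, records=sub.reset_index(drop=True))

    def entities(self) -> list[str]:
        return sorted(self.records["entity_name"].unique())


RECORD_COLUMNS = [
    "source_id",
    "entity_type",
    "entity_name",
    "microbe_name",
    "rank",
    "direction",
    "body_site",
    "notes",
]


def evidence_from_frame(df: pd.DataFrame) -> EvidenceTable:
    """Build an EvidenceTable from an already-typed in-memory frame."""
    out = df.copy()
    for col in ("body_site", "notes"):
        if col not in out.columns:
            out[col] = ""
    out["entity_name"] = canonicalize_names(out["entity_name"])
    out["microbe_name"] = canonicalize_names(out["microbe_name"])
    out["direction"] = out["direction"].astype(int)
    return EvidenceTable(
        records=out[RECORD_COLUMNS].reset_index(drop=True),
        rejected=pd.DataFrame(columns=[*RECORD_COLUMNS, "reason"]),
    )


def read_evidence(path, dialect: Dialect | None = None) -> EvidenceTable:
    """Read a long-format evidence table.

    Rows with unknown rank or direction tokens, an unknown entity type, or
    empty names are collected into ``rejected`` with a reason, not silently
    dropped. Raises on a missing file, a missing mandatory column, or a
    table with no parseable rows.
    """
    dialect = dialect or DEFAULT_DIALECT
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.mandatory if c not in raw.columns]
    if missing:
        raise ValueError(f"evidence table {path} missing mandatory columns: {missing}")

    rows, rejects = [], []
    for _, row in raw.iterrows():
        rank = normalize_name(row[dialect.rank]).lower()
        etype = normalize_name(row[dialect.entity_type]).lower()
        direction = _DIRECTION_TOKENS.get(normalize_name(row[dialect.direction]).lower())
        entity = normalize_name(row[dialect.entity_name])
        microbe = normalize_name(row[dialect.microbe_name])
        reason = None
        if rank not in RANKS:
            reason = f"unsupported rank {row[dialect.rank]!r}"
        elif direction is None:
            reason = f"unknown direction token {row[dialect.direction]!r}"
        elif etype not in ENTITY_TYPES:
            reason = f"unknown entity type {row[dialect.entity_type]!r}"
        elif not entity or not microbe:
            reason = "empty entity or microbe name"
        parsed = {
            "source_id": normalize_name(row[dialect.source_id]),
            "entity_type": etype,
            "entity_name": entity,
            "microbe_name": microbe,
            "rank": rank,
            "direction": direction if direction is not None else 0,
            "body_site": normalize_name(row.get(dialect.body_site, "")),
            "notes": str(row.get(dialect.notes, "")),
        }
        if reason is None:
            rows.append(parsed)
        else:
            rejects.append({**parsed, "reason": reason})

    if not rows:
        raise ValueError(f"evidence table {path} contains no parseable rows")
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records["entity_name"] = canonicalize_names(records["entity_name"])
    records["microbe_name"] = canonicalize_names(records["microbe_name"])
    records["direction"] = records["direction"].astype(int)
    rejected = pd.DataFrame(rejects, columns=[*RECORD_COLUMNS, "reason"])
    return EvidenceTable(records=records, rejected=rejected)


def parse_greengenes_lineage(lineage: str):
    """Parse a "k__...;p__...;...;s__..." string.

    Returns (taxon_name, rank, lineage_above) where taxon_name is the
    deepest non-empty entry at a supported rank and lineage_above maps each
    higher rank to its (non-empty) ancestor name. The kingdom slot is
    accepted and ignored. Raises on a wrong prefix set.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    if len(parts) != len(GREENGENES_PREFIXES):
        raise ValueError(f"malformed lineage string (expected 7 fields): {lineage!r}")
    by_rank: dict[str, str] = {}
    for part, (prefix, rank) in zip(parts, GREENGENES_PREFIXES):
        if not part.startswith(prefix):
            raise ValueError(f"malformed lineage field {part!r} (expected prefix {prefix!r})")
        name = normalize_name(part[len(prefix) :])
        if name and rank != "kingdom":
            by_rank[rank] = name
    # deepest supported rank present = the taxon itself
    for rank in RANKS:
        if rank in by_rank:
            taxon = by_rank.pop(rank)
            return taxon, rank, by_rank
    raise ValueError(f"lineage string names no taxon at a supported rank: {lineage!r}")


def read_taxonomy(path, format: str = "greengenes_string"):
    """Read a taxonomy lineage table into a TaxonomyTable.

    ``greengenes_string``: TSV with a ``lineage`` column of prefixed
    lineage strings (one taxon per row, the deepest named rank).
    ``two_column_lineage``: TSV with ``taxon_name``, ``rank`` and one
    column per rank (species..phylum) naming ancestors above the taxon's
    own rank.

    Identical duplicate rows deduplicate; conflicting lineages for one
    taxon raise an error naming the taxon.
    """
    from .taxonomy import TaxonomyRecord, TaxonomyTable

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    if format == "greengenes_string":
        if "lineage" not in raw.columns:
            raise ValueError(f"taxonomy table {path} lacks a 'lineage' column")
        for lineage in raw["lineage"]:
            taxon, rank, above = parse_greengenes_lineage(lineage)
            records.append(TaxonomyRecord(name=taxon, rank=rank, lineage=above))
    elif format == "two_column_lineage":
        needed = {"taxon_name", "rank"}
        if not needed.issubset(raw.columns):
            raise ValueError(f"taxonomy table {path} lacks columns {sorted(needed)}")
        for _, row in raw.iterrows():
            rank = normalize_name(row["rank"]).lower()
            if rank not in RANKS:
                raise ValueError(f"unsupported rank {row['rank']!r} for {row['taxon_name']!r}")
            above = {
                r: normalize_name(row[r])
                for r in RANKS
                if r in raw.columns and normalize_name(row.get(r, ""))
            }
            records.append(
                TaxonomyRecord(
                    name=normalize_name(row["taxon_name"]), rank=rank, lineage=above
                )
            )
    else:
        raise ValueError(f"unknown taxonomy format {format!r}")
    return TaxonomyTable(records)


# ---------------------------------------------------------------------------
# result tables

def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_similarity(table, path) -> None:
    """Write a similarity table (long format) as TSV."""
    df = table.table if hasattr(table, "table") else table
    if len(df) == 0:
        raise ValueError("refusing to write an empty similarity table")
    _write_tsv(df, path)


def read_similarity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edges(network, path) -> None:
    """Write a signed edge list: node_i, node_j, sign (+/-), similarity, fdr."""
    edges = network.edges.copy()
    if len(edges) == 0:
        raise ValueError("refusing to write an empty edge list")
    edges["sign"] = edges["sign"].map({1: "+", -1: "-"})
    _write_tsv(edges[["node_i", "node_j", "sign", "similarity", "fdr"]], path)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["sign"] = df["sign"].map({"+": 1, "-": -1})
    return df


def write_network_json(network, path) -> None:
    """JSON export for web display: {nodes: [{id}], edges: [{...}]}."""
    payload = {
        "nodes": [{"id": n} for n in network.nodes],
        "edges": [
            {
                "source": r.node_i,
                "target": r.node_j,
                "sim": float(r.similarity),
                "fdr": None if pd.isna(r.fdr) else float(r.fdr),
                "sign": int(r.sign),
            }
            for r in network.edges.itertuples()
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_census(census, path, randomization=None) -> None:
    """Write a loop-census report, optionally with the permutation null."""
    row = {
        "total_loops": census.total_loops,
        "coherent": census.coherent,
        "incoherent": census.incoherent,
        "ratio": census.ratio,
        "theoretical_max": census.theoretical_max,
    }
    if randomization is not None:
        row.update(
            iterations=randomization.iterations,
            seed=randomization.seed,
            null_median=randomization.null_median,
            fold_vs_median=randomization.fold_vs_median,
            empirical_p=randomization.empirical_p,
            undefined_null_ratios=randomization.n_undefined,
        )
    _write_tsv(pd.DataFrame([row]), path)


def write_ds_table(df: pd.DataFrame, path) -> None:
    if len(df) == 0:
        raise ValueError("refusing to write an empty disturbance-score table")
    _write_tsv(df, path)


def read_ds_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clusters(assignment, path) -> None:
    df = pd.DataFrame(
        {"entity": list(assignment.labels), "cluster": list(assignment.labels.values())}
    )
    _write_tsv(df, path)


def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick if newick.endswith("\n") else newick + "\n")
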