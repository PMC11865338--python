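import numpy as np
import pandas as pd
import pytest

from bhwa.io import EvidenceTable, evidence_from_frame
from bhwa.taxonomy import MultiRankEvidence, TaxonomyRecord, TaxonomyTable

LINEAGE_LACTO = {
    "family": "Lactobacillaceae",
    "order": "Lactobacillales",
    "class": "Bacilli",
    "phylum": "Firmicutes",
}


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    """A handful of real-looking lineages spanning two phyla."""
    return TaxonomyTable(
        [
            TaxonomyRecord("Lactobacillus", "genus", dict(LINEAGE_LACTO)),
            TaxonomyRecord(
                "Bacteroides",
                "genus",
                {"family": "Bacteroidaceae", "order": "Bacteroidales",
                 "class": "Bacteroidia", "phylum": "Bacteroidetes"},
            ),
            TaxonomyRecord(
                "Prevotella",
                "genus",
                {"family": "Prevotellaceae", "order": "Bacteroidales",
                 "class": "Bacteroidia", "phylum": "Bacteroidetes"},
            ),
            TaxonomyRecord("Firmicutes", "phylum"),
            TaxonomyRecord("Bacteroidetes", "phylum"),
        ]
    )


def make_evidence(rows) -> EvidenceTable:
    """Rows: (source, entity_type, entity, microbe, rank, direction[, site])."""
    records = []
    for row in rows:
        site = row[6] if len(row) > 6 else ""
        records.append(
            {
                "source_id": row[0],
                "entity_type": row[1],
                "entity_name": row[2],
                "microbe_name": row[3],
                "rank": row[4],
                "direction": row[5],
                "body_site": site,
                "notes": "",
            }
        )
    return evidence_from_frame(pd.DataFrame(records))


def make_counts(rank_tallies: dict) -> MultiRankEvidence:
    """Build MultiRankEvidence from {rank: {(entity, taxon): (inc, dec)}}."""
    counts = {}
    for rank, tally in rank_tallies.items():
        rows = [
            {"entity": e, "taxon": t, "c_inc": ci, "c_dec": cd}
            for (e, t), (ci, cd) in sorted(tally.items())
        ]
        counts[rank] = pd.DataFrame(rows)
    return MultiRankEvidence(counts=counts)


def random_instance(rng: np.random.Generator, max_entities=6, max_taxa=10, n_ranks=3):
    """A random small direction-count instance for oracle comparison."""
    ranks = ["species", "genus", "phylum"][:n_ranks]
    n_ent = int(rng.integers(2, max_entities + 1))
    entities = [f"E{i}" for i in range(n_ent)]
    tallies = {}
    for rank in ranks:
        n_tax = int(rng.integers(2, max_taxa + 1))
        tally = {}
        for e in entities:
            for k in range(n_tax):
                if rng.random() < 0.5:
                    ci = int(rng.integers(0, 4))
                    cd = int(rng.integers(0, 4))
                    if ci + cd >= 1:
                        tally[(e, f"{rank}_t{k}")] = (ci, cd)
        if tally:
            tallies[rank] = tally
    return entities, tallies


@pytest.fixture
def evidence_rows_basic():
    """Five well-formed rows, three fibers x assorted microbes."""
    return [
        ("s1", "fiber", "Inulin", "Lactobacillus", "genus", 1),
        ("s2", "fiber", "Inulin", "Bacteroides", "genus", -1),
        ("s3", "fiber", "Pectin", "Lactobacillus", "genus", 1),
        ("s4", "fiber", "Pectin", "Prevotella", "genus", 1),
        ("s5", "fiber", "Cellulose", "Bacteroidetes", "phylum", -1),
    ]
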