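"""Synthetic evidence databases with planted block structure.

The generator emulates the statistical shape of curated disturbance
databases: a six-rank taxonomy tree, per-entity sparse signed taxon
profiles dominated by genus-level reports, and a handful of evidence rows
per entity. Entities are partitioned into blocks; each block carries a
signed direction profile over genera (planted at genus rank and propagated
upward by the real taxonomy machinery), so block membership is recoverable
from the weighted similarities — the ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EvidenceTable, evidence_from_frame
from .taxonomy import TaxonomyRecord, TaxonomyTable

__all__ = ["SynthConfig", "SynthData", "generate", "write_bundle"]

DEFAULT_RANK_PROBS = {"species": 0.08, "genus": 0.84, "family": 0.05, "phylum": 0.03}


@dataclass(frozen=True)
class SynthConfig:
    """Generator conditions.

    Defaults mirror a small curated fiber database: ~20 entities with 6-14
    evidence rows each over ~40 genera, genus-level reports dominating,
    and a modest per-row direction-conflict rate (most taxa show both
    increases and decreases across a real corpus).
    """

    n_entities_a: int = 20
    n_entities_b: int = 0
    entity_type_a: str = "fiber"
    entity_type_b: str = "disease"
    n_blocks: int = 2
    within_block_agreement: float = 0.9
    between_block_agreement: float = 0.1
    evidence_per_entity: tuple[int, int] = (6, 14)
    conflict_rate: float = 0.1
    n_genera: int = 40
    n_species_per_genus: int = 2
    n_families: int = 12
    n_orders: int = 8
    n_classes: int = 6
    n_phyla: int = 4
    rank_probs: tuple[tuple[str, float], ...] = tuple(DEFAULT_RANK_PROBS.items())
    body_sites: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("within_block_agreement", "between_block_agreement", "conflict_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_entities_a + self.n_entities_b == 0:
            raise ValueError("no entities requested")
        if self.n_blocks > max(self.n_entities_a, self.n_entities_b):
            raise ValueError("more blocks than entities")
        lo, hi = self.evidence_per_entity
        if not 1 <= lo <= hi:
            raise ValueError("evidence_per_entity must be a non-empty integer range")
        if hi > self.n_genera:
            raise ValueError("evidence_per_entity upper bound exceeds the genus universe")


@dataclass
class SynthData:
    evidence: EvidenceTable
    taxonomy: TaxonomyTable
    truth: dict = field(default_factory=dict)


def _build_taxonomy(cfg: SynthConfig, rng: np.random.Generator):
    """Random six-rank tree: species < genus < family < order < class < phylum."""
    fam_of = rng.integers(0, cfg.n_families, size=cfg.n_genera)
    ord_of = rng.integers(0, cfg.n_orders, size=cfg.n_families)
    cls_of = rng.integers(0, cfg.n_classes, size=cfg.n_orders)
    phy_of = rng.integers(0, cfg.n_phyla, size=cfg.n_classes)

    genus = [f"Genus{g:03d}" for g in range(cfg.n_genera)]
    family = [f"Family{f:02d}" for f in range(cfg.n_families)]
    order = [f"Order{o:02d}" for o in range(cfg.n_orders)]
    klass = [f"Class{c:02d}" for c in range(cfg.n_classes)]
    phylum = [f"Phylum{p:02d}" for p in range(cfg.n_phyla)]

    records = []
    lineage_of_genus = {}
    for g in range(cfg.n_genera):
        f = fam_of[g]
        o = ord_of[f]
        c = cls_of[o]
        p = phy_of[c]
        lin = {"family": family[f], "order": order[o], "class": klass[c],
               "phylum": phylum[p]}
        lineage_of_genus[genus[g]] = lin
        records.append(TaxonomyRecord(name=genus[g], rank="genus", lineage=lin))
        for s in range(cfg.n_species_per_genus):
            records.append(
                TaxonomyRecord(
                    name=f"{genus[g]} sp{s + 1}",
                    rank="species",
                    lineage={"genus": genus[g], **lin},
                )
            )
    for f in range(cfg.n_families):
        o = ord_of[f]
        c = cls_of[o]
        records.append(
            TaxonomyRecord(name=family[f], rank="family",
                           lineage={"order": order[o], "class": klass[cls_of[o]],
                                    "phylum": phylum[phy_of[cls_of[o]]]})
        )
    for o in range(cfg.n_orders):
        c = cls_of[o]
        records.append(
            TaxonomyRecord(name=order[o], rank="order",
                           lineage={"class": klass[c], "phylum": phylum[phy_of[c]]})
        )
    for c in range(cfg.n_classes):
        records.append(
            TaxonomyRecord(name=klass[c], rank="class",
                           lineage={"phylum": phylum[phy_of[c]]})
        )
    for p in range(cfg.n_phyla):
        records.append(TaxonomyRecord(name=phylum[p], rank="phylum"))
    return TaxonomyTable(records), genus, lineage_of_genus


def generate(config: SynthConfig) -> SynthData:
    """Sample an evidence table, taxonomy, and ground truth from the config.

    Block direction profiles are drawn over genera: blocks beyond the first
    agree with block 0 per taxon with probability
    ``between_block_agreement``. Each entity's own profile deviates from
    its block independently per taxon with probability
    ``(1 - within_block_agreement)/2`` (so agreement 1.0 copies the block
    exactly), and each sampled evidence row flips its direction with
    probability ``conflict_rate``. Output is deterministic in the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    taxonomy, genera, lineage_of_genus = _build_taxonomy(cfg, rng)

    base_profile = rng.choice([1, -1], size=cfg.n_genera)
    block_profiles = {0: base_profile}
    for b in range(1, cfg.n_blocks):
        agree = rng.random(cfg.n_genera) < cfg.between_block_agreement
        block_profiles[b] = np.where(agree, base_profile, -base_profile)

    entities = []
    for i in range(cfg.n_entities_a):
        entities.append((f"{cfg.entity_type_a.capitalize()}A{i:02d}",
                         cfg.entity_type_a, i % cfg.n_blocks))
    for i in range(cfg.n_entities_b):
        entities.append((f"{cfg.entity_type_b.capitalize()}B{i:02d}",
                         cfg.entity_type_b, i % cfg.n_blocks))

    rank_names, rank_p = zip(*cfg.rank_probs)
    rank_p = np.asarray(rank_p, dtype=float)
    rank_p = rank_p / rank_p.sum()
    flip_p = (1.0 - cfg.within_block_agreement) / 2.0

    rows = []
    entity_profiles = {}
    blocks = {}
    lo, hi = cfg.evidence_per_entity
    for name, etype, block in entities:
        blocks[name] = block
        deviate = rng.random(cfg.n_genera) < flip_p
        profile = np.where(deviate, -block_profiles[block], block_profiles[block])
        entity_profiles[name] = profile
        n_rows = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(cfg.n_genera, size=n_rows, replace=False)
        for row_idx, g in enumerate(chosen):
            genus_name = genera[g]
            rank = str(rng.choice(rank_names, p=rank_p))
            if rank == "genus":
                microbe = genus_name
            elif rank == "species":
                s = int(rng.integers(0, cfg.n_species_per_genus))
                microbe = f"{genus_name} sp{s + 1}"
            else:
                microbe = lineage_of_genus[genus_name][rank]
            direction = int(profile[g])
            if rng.random() < cfg.conflict_rate:
                direction = -direction
            rows.append(
                {
                    "source_id": f"study_{name}_{row_idx:03d}",
                    "entity_type": etype,
                    "entity_name": name,
                    "microbe_name": microbe,
                    "rank": rank,
                    "direction": direction,
                    "body_site": (
                        str(rng.choice(cfg.body_sites)) if cfg.body_sites else ""
                    ),
                    "notes": "",
                }
            )

    evidence = evidence_from_frame(pd.DataFrame(rows))
    truth = {
        "blocks": blocks,
        "block_profiles": {b: dict(zip(genera, map(int, p)))
                           for b, p in block_profiles.items()},
        "entity_profiles": {e: dict(zip(genera, map(int, p)))
                            for e, p in entity_profiles.items()},
    }
    return SynthData(evidence=evidence, taxonomy=taxonomy, truth=truth)


def write_bundle(data: SynthData, outdir) -> dict[str, Path]:
    """Write evidence/taxonomy/ground-truth TSVs in the standard dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "evidence": outdir / "evidence.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.tsv",
    }
    data.evidence.records.to_csv(paths["evidence"], sep="\t", index=False)

    tax_rows = []
    for rec in sorted(data.taxonomy, key=lambda r: (r.rank, r.name)):
        tax_rows.append({"taxon_name": rec.name, "rank": rec.rank,
                         **{r: rec.lineage.get(r, "") for r in
                            ("species", "genus", "family", "order", "class", "phylum")}})
    pd.DataFrame(tax_rows).to_csv(paths["taxonomy"], sep="\t", index=False)

    truth_rows = [{"entity": e, "block": b} for e, b in sorted(data.truth["blocks"].items())]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
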