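"""The six supported taxonomic ranks, ordered from most to least specific."""

RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

# Greengenes/SILVA-style lineage prefixes; kingdom is parsed but not a
# supported rank (it carries no discriminating signal between entities).
GREENGENES_PREFIXES: tuple[tuple[str, str], ...] = (
    ("k__", "kingdom"),
    ("p__", "phylum"),
    ("c__", "class"),
    ("o__", "order"),
    ("f__", "family"),
    ("g__", "genus"),
    ("s__", "species"),
)


def higher_ranks(rank: str) -> tuple[str, ...]:
    """Ranks strictly above *rank* (e.g. genus -> family..phylum)."""
    return RANKS[RANK_INDEX[rank] + 1 :]


def is_rank(token: str) -> bool:
    return token in RANK_INDEX
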