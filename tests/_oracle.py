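"""Independent brute-force re-derivations used as test oracles.

Everything here is written with plain Python loops and ``math`` directly
from the defining formulas (signed IDF-weighted strength, cosine over the
taxon support, deviation sqrt((1-SIM^2)/df), inverse-deviation weighting),
deliberately sharing no code with the vectorized implementation it checks.
"""

import itertools
import math

CLAMP = 1.0 - 1e-12


def oracle_disturbance(tally: dict, entity, taxon, entities, n_by_taxon):
    """D = alpha * C * ln(N/n) for one cell of one rank."""
    c_inc, c_dec = tally.get((entity, taxon), (0, 0))
    net = c_inc - c_dec
    alpha = (net > 0) - (net < 0)
    return alpha * abs(net) * math.log(len(entities) / n_by_taxon[taxon])


def oracle_weighted_similarity(counts: dict, i, j):
    """Weighted similarity of entities i, j from raw direction counts.

    ``counts`` maps rank -> {(entity, taxon): (c_inc, c_dec)}. Returns the
    weighted similarity, or None when no rank contributes.
    """
    num = den = 0.0
    for tally in counts.values():
        entities = sorted({e for e, _ in tally})
        if len(entities) < 2:
            continue
        taxa = sorted({t for _, t in tally})
        n_by_taxon = {
            t: sum(1 for e in entities if (e, t) in tally) for t in taxa
        }
        Di = [oracle_disturbance(tally, i, t, entities, n_by_taxon) for t in taxa]
        Dj = [oracle_disturbance(tally, j, t, entities, n_by_taxon) for t in taxa]
        ni = math.sqrt(sum(x * x for x in Di))
        nj = math.sqrt(sum(x * x for x in Dj))
        support = sum(1 for a, b in zip(Di, Dj) if a != 0 or b != 0)
        df = support - 2
        if ni == 0 or nj == 0 or df < 1:
            continue
        sim = sum(a * b for a, b in zip(Di, Dj)) / (ni * nj)
        clamped = max(-CLAMP, min(CLAMP, sim))
        sigma = math.sqrt((1.0 - clamped * clamped) / df)
        num += sim / sigma
        den += 1.0 / sigma
    if den == 0.0:
        return None
    return num / den


def brute_force_census(network):
    """Triple scan over all node combinations (the slow, obvious census)."""
    g = network.to_networkx()
    coherent = incoherent = 0
    for a, b, c in itertools.combinations(sorted(g.nodes), 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            prod = g[a][b]["sign"] * g[b][c]["sign"] * g[a][c]["sign"]
            if prod > 0:
                coherent += 1
            else:
                incoherent += 1
    return coherent, incoherent
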