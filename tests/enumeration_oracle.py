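"""Brute-force enumeration oracles for reduced genomes.

These enumerate every MI / MII / loss outcome with its exact probability,
independently of both the Monte-Carlo simulator and the product-form
oracle, and are tractable for genomes of 1-3 chromosomes.

State codes follow the package convention: 0=none, 1=monoA, 2=monoB,
3=heterodisomy.
"""

from __future__ import annotations

import itertools

import numpy as np


def _spore_outcomes_from_daughter(d: int, pa: float, pb: float):
    """All (state, probability) outcomes of one spore from MII of a
    daughter in state ``d``, by enumerating per-copy loss indicators."""
    if d == 0:
        return [(0, 1.0)]
    if d in (1, 2):
        return [(d, 1.0 - pa), (0, pa)]
    # heterodisomy: enumerate (lose A, lose B)
    out = {}
    for lose_a, lose_b in itertools.product((False, True), repeat=2):
        p = (pb if lose_a else 1 - pb) * (pb if lose_b else 1 - pb)
        state = (0 if lose_a else 1) | (0 if lose_b else 2)
        out[state] = out.get(state, 0.0) + p
    return list(out.items())


def enumerate_daughter_conditional(p_dis, pa: float, pb: float) -> dict:
    """Exact category fractions of one full MI daughter's spore pair.

    ``p_dis[i]`` is the probability that the daughter carries both homologs
    of chromosome i (conditional on carrying at least one of every
    chromosome).  Categories: copies / altered_copies / single / mii_dead.
    """
    per_chrom = []
    for p in np.atleast_1d(p_dis):
        entries = []
        for d, p_d in ((3, p), (1, (1 - p) / 2), (2, (1 - p) / 2)):
            for s1, p1 in _spore_outcomes_from_daughter(d, pa, pb):
                for s2, p2 in _spore_outcomes_from_daughter(d, pa, pb):
                    entries.append((s1, s2, p_d * p1 * p2))
        per_chrom.append(entries)

    fractions = {"copies": 0.0, "altered_copies": 0.0, "single": 0.0, "mii_dead": 0.0}
    for combo in itertools.product(*per_chrom):
        prob = float(np.prod([e[2] for e in combo]))
        s1 = tuple(e[0] for e in combo)
        s2 = tuple(e[1] for e in combo)
        v1 = all(s != 0 for s in s1)
        v2 = all(s != 0 for s in s2)
        if v1 and v2:
            fractions["copies" if s1 == s2 else "altered_copies"] += prob
        elif v1 or v2:
            fractions["single"] += prob
        else:
            fractions["mii_dead"] += prob
    return fractions


def enumerate_full_tetrads(same_pole, pa: float, pb: float) -> dict:
    """Exact unconditional category probabilities over whole tetrads.

    ``same_pole[i]`` is the probability that both homologs of chromosome i
    move to one MI pole.  Returns probabilities for all six categories
    (copies, altered_copies, single, mii_dead, mi_dead, multi), classified
    exactly as the simulator does: by the number of viable spores, identity
    of the viable pair, and whether any MI daughter carried a full set.
    """
    per_chrom = []
    for c in np.atleast_1d(same_pole):
        entries = []  # (d1_state, s1, s2, s3, s4, prob)
        for d1, p_d in ((3, c / 2), (0, c / 2), (1, (1 - c) / 2), (2, (1 - c) / 2)):
            d2 = 3 - d1
            for s1, p1 in _spore_outcomes_from_daughter(d1, pa, pb):
                for s2, p2 in _spore_outcomes_from_daughter(d1, pa, pb):
                    for s3, p3 in _spore_outcomes_from_daughter(d2, pa, pb):
                        for s4, p4 in _spore_outcomes_from_daughter(d2, pa, pb):
                            entries.append(
                                (d1, s1, s2, s3, s4, p_d * p1 * p2 * p3 * p4)
                            )
        per_chrom.append(entries)

    probs = dict.fromkeys(
        ("copies", "altered_copies", "single", "mii_dead", "mi_dead", "multi"), 0.0
    )
    for combo in itertools.product(*per_chrom):
        prob = float(np.prod([e[5] for e in combo]))
        d1 = tuple(e[0] for e in combo)
        spores = [tuple(e[k] for e in combo) for k in (1, 2, 3, 4)]
        viable = [all(s != 0 for s in sp) for sp in spores]
        n_v = sum(viable)
        full1 = all(d != 0 for d in d1)
        full2 = all(d != 3 for d in d1)
        if n_v >= 3:
            probs["multi"] += prob
        elif n_v == 2:
            a, b = (sp for sp, v in zip(spores, viable) if v)
            probs["copies" if a == b else "altered_copies"] += prob
        elif n_v == 1:
            probs["single"] += prob
        elif full1 or full2:
            probs["mii_dead"] += prob
        else:
            probs["mi_dead"] += prob
    return probs
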