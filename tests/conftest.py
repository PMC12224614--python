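import itertools

import numpy as np
import pytest

from petscan import motif_engine as me


@pytest.fixture(scope="session")
def defaults():
    """Bundled tier definitions and component registry."""
    return me.load_definitions(None)


@pytest.fixture(scope="session")
def reference():
    return me.reference_sequence()


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_scan(residues: str, pattern: str):
    """Position-by-position scan, independent of the regex-based engine.

    Enumerates every start and every bounded-gap expansion and checks the
    residue sets elementwise.  Returns a set of (start, end) spans.
    """
    elements = me.parse_pattern(pattern)
    spans = set()

    def match_from(pos, el_idx, start):
        if el_idx == len(elements):
            spans.add((start, pos))
            return
        el = elements[el_idx]
        if el[0] == "set":
            if pos < len(residues) and residues[pos] in el[1]:
                match_from(pos + 1, el_idx + 1, start)
        else:
            for g in range(el[1], el[2] + 1):
                if pos + g <= len(residues):
                    match_from(pos + g, el_idx + 1, start)

    for start in range(len(residues)):
        match_from(start, 0, start)
    return spans


def oracle_classify(seq: me.ProteinSequence, tiers, components) -> str:
    """Exhaustive enumeration over all component placement combinations.

    Independent of the engine's backtracking: takes the raw per-component
    match lists and tries every combination against every constraint
    (including the shared-serine rule linking ser_met to the elbow).
    """
    matches = {
        c.name: c.scan(seq.residues.upper()) for c in components.values()
    }
    best = "M0"
    for tier in tiers:
        names = sorted(tier.required_components)
        pools = [matches[n] for n in names]
        if any(not p for p in pools):
            continue
        constraints = list(tier.constraints)
        if {"ser_met", "nucleophile_elbow"} <= tier.required_components:
            constraints.append(me.DistanceConstraint("nucleophile_elbow", "ser_met", 0, 0))
        anchor = {n: components[n].anchor for n in names}
        found = False
        for combo in itertools.product(*pools):
            pos = {n: m.start + anchor[n] for n, m in zip(names, combo)}
            if all(
                c.min_sep <= pos[c.to_component] - pos[c.from_component] <= c.max_sep
                for c in constraints
            ):
                found = True
                break
        if found and tier.rank > int(best[1]):
            best = tier.tier
    return best


@pytest.fixture(scope="session")
def random_proteins():
    """Seeded random sequences (no planted structure)."""
    rng = np.random.default_rng(42)
    letters = sorted(me.AMINO_ACIDS)
    return [
        me.ProteinSequence(
            f"rand_{i}", "".join(rng.choice(letters, size=int(rng.integers(200, 301))))
        )
        for i in range(100)
    ]
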