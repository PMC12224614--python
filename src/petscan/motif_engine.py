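"""Hierarchical M1-M5 motif classification of PET hydrolase candidates.

PET hydrolases (PETases) are serine hydrolases of the dienelactone-hydrolase
(DLH) alpha/beta fold.  A DLH domain alone does not make an enzyme a PETase:
functional PETases additionally carry a specific constellation of sequence
features — the G-x-S-x-G nucleophile elbow with the catalytic serine, a
four-glycine run packing that helix into the core, aromatic clamp residues
that sandwich the PET ring, the full Ser/Asp/His catalytic triad, a
methionine directly after the catalytic serine (oxyanion hole), a conserved
DxDxR(Y)xxFxC block, and a stabilizing internal disulfide — all at
characteristic separations along the chain.

This module compiles those features as five cumulative motif tiers of
increasing stringency (M1 ⊂ M2 ⊂ ... ⊂ M5) and classifies protein sequences
into the highest tier they satisfy.  Patterns use PROSITE-style syntax
(``[PG]-G-[YF]``, ``x(2,3)`` bounded wildcards) and tiers add pairwise
min/max distance constraints between component anchor residues.  A sequence
is awarded tier Mk when *some* combination of component placements satisfies
every component and constraint of Mk (existential semantics); only complete
M5 marks a functional PETase.
"""

from __future__ import annotations

import io
import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("petscan")

#: the 20 standard amino acids
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ambiguity letter accepted in input sequences; matches no residue set
AMBIGUOUS = "X"
ALPHABET = AMINO_ACIDS | {AMBIGUOUS}

TIER_NAMES = ("M1", "M2", "M3", "M4", "M5")

COMPONENT_NAMES = (
    "nucleophile_elbow",
    "glycine_quad",
    "aromatic_clamp_1",
    "catalytic_asp",
    "catalytic_his",
    "pg_g_yf",
    "ser_met",
    "dxdxr_block",
    "disulfide_cys",
)


class PatternError(ValueError):
    """Malformed PROSITE-style pattern syntax."""


class DefinitionError(ValueError):
    """Invalid or non-cumulative tier definitions."""


class InputError(ValueError):
    """Sequence input violating the accepted alphabet."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an identifier.

    ``residues`` may contain the 20 standard one-letter codes plus ``X``.
    Internally coordinates are 0-based half-open; reported coordinates are
    1-based inclusive.
    """

    id: str
    residues: str
    description: str = ""

    def validate(self) -> None:
        if not self.residues:
            raise InputError(f"{self.id}: empty sequence")
        bad = set(self.residues.upper()) - ALPHABET
        if bad:
            raise InputError(
                f"{self.id}: residues outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass(frozen=True)
class MotifComponent:
    """One motif component: a compiled PROSITE-style pattern plus anchor.

    ``anchor`` is the 0-based offset, within the fixed-length prefix of the
    pattern, of the functionally defining residue (e.g. the serine of the
    nucleophile elbow); distance constraints are measured anchor-to-anchor.
    """

    name: str
    pattern: str
    anchor: int = 0
    role: str = ""
    # fixed-length expansions of the pattern, as compiled regexes
    _variants: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self):
        elements = parse_pattern(self.pattern, component=self.name)
        # length of the prefix whose offsets are identical in every expansion
        fixed_prefix = 0
        for el in elements:
            if el[0] == "gap" and el[1] != el[2]:
                break
            fixed_prefix += 1 if el[0] == "set" else el[1]
        if not 0 <= self.anchor < fixed_prefix:
            raise PatternError(
                f"{self.name}: anchor {self.anchor} not within the fixed "
                f"prefix (length {fixed_prefix}) of the pattern"
            )
        object.__setattr__(self, "_variants", _expand_variants(elements, self.name))

    def scan(self, residues: str) -> list["MotifMatch"]:
        """All placements of this component in ``residues`` (overlaps allowed)."""
        out = []
        seen = set()
        for rx in self._variants:
            for m in rx.finditer(residues):
                start, text = m.start(), m.group(1)
                key = (start, start + len(text))
                if key not in seen:
                    seen.add(key)
                    out.append(
                        MotifMatch(self.name, start, start + len(text), text)
                    )
        out.sort(key=lambda mm: (mm.start, mm.end))
        return out


@dataclass(frozen=True)
class DistanceConstraint:
    """Bounded separation, in residues, between two component anchors.

    Separation is ``anchor(to) - anchor(from)``; ``min_sep >= 0`` therefore
    also enforces N-to-C order of the two components.
    """

    from_component: str
    to_component: str
    min_sep: int
    max_sep: int

    def __post_init__(self):
        if self.min_sep < 0 or self.max_sep < self.min_sep:
            raise DefinitionError(
                f"constraint {self.from_component}->{self.to_component}: "
                f"need 0 <= min ({self.min_sep}) <= max ({self.max_sep})"
            )

    def satisfied(self, from_anchor: int, to_anchor: int) -> bool:
        return self.min_sep <= to_anchor - from_anchor <= self.max_sep


@dataclass(frozen=True)
class MotifTierDefinition:
    tier: str
    required_components: frozenset
    constraints: tuple

    @property
    def rank(self) -> int:
        return int(self.tier[1])


@dataclass(frozen=True)
class MotifMatch:
    component: str
    start: int  # 0-based
    end: int  # exclusive
    matched_text: str

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


@dataclass(frozen=True)
class TierClassification:
    """Outcome for one sequence: highest satisfied tier plus a witness."""

    sequence_id: str
    tier: str  # M0..M5
    placements: tuple = ()
    failed_at: str | None = None

    @property
    def rank(self) -> int:
        return int(self.tier[1])


# ---------------------------------------------------------------------------
# pattern compilation
# ---------------------------------------------------------------------------

_SET_RE = re.compile(r"^\[([A-Z]+)\]$")
_GAP_RE = re.compile(r"^x(?:\((\d+)(?:,(\d+))?\))?$")

#: safety bound on the number of fixed-length expansions of one pattern
_MAX_VARIANTS = 64


def parse_pattern(text: str, component: str = "?") -> list:
    """Parse PROSITE-style ``text`` into a list of elements.

    Elements are ``("set", frozenset)`` for one constrained position or
    ``("gap", min, max)`` for a bounded wildcard run.  A bare ``x`` is a gap
    of exactly one unconstrained position.
    """
    if not text or not text.strip():
        raise PatternError(f"{component}: empty pattern")
    elements: list = []
    for raw in text.strip().split("-"):
        tok = raw.strip()
        if not tok:
            raise PatternError(f"{component}: empty element in {text!r}")
        m = _GAP_RE.match(tok)
        if m:
            lo = int(m.group(1)) if m.group(1) else 1
            hi = int(m.group(2)) if m.group(2) else lo
            if hi < lo:
                raise PatternError(f"{component}: bad gap bounds in {tok!r}")
            elements.append(("gap", lo, hi))
            continue
        m = _SET_RE.match(tok)
        if m:
            letters = frozenset(m.group(1))
        elif len(tok) == 1 and tok.isalpha() and tok.isupper():
            letters = frozenset(tok)
        else:
            raise PatternError(f"{component}: cannot parse element {tok!r}")
        if not letters <= AMINO_ACIDS:
            raise PatternError(
                f"{component}: residues outside the 20-letter alphabet in {tok!r}"
            )
        elements.append(("set", letters))
    return elements


def _expand_variants(elements: list, component: str):
    """Expand bounded gaps into all fixed-length regex variants.

    Each variant is wrapped in a lookahead capture so every start position is
    enumerated (overlapping matches included).  Residue sets translate to
    character classes over the 20 standard letters only, so the ambiguity
    letter X never satisfies a constrained position; wildcard positions match
    any alphabet letter, X included.
    """
    gap_choices = []
    for el in elements:
        if el[0] == "gap":
            gap_choices.append(range(el[1], el[2] + 1))
        else:
            gap_choices.append(None)
    spans = [c for c in gap_choices if c is not None]
    n_var = 1
    for c in spans:
        n_var *= len(c)
    if n_var > _MAX_VARIANTS:
        raise PatternError(f"{component}: pattern expands to {n_var} variants")
    variants = []
    for combo in itertools.product(*(c for c in spans)) if spans else [()]:
        it = iter(combo)
        parts = []
        for el in elements:
            if el[0] == "gap":
                parts.append("[A-Z]" * next(it))
            else:
                letters = "".join(sorted(el[1]))
                parts.append(letters if len(letters) == 1 else f"[{letters}]")
        variants.append(re.compile(f"(?=({''.join(parts)}))"))
    return tuple(variants)


# ---------------------------------------------------------------------------
# definition loading
# ---------------------------------------------------------------------------

def _default_config() -> dict:
    with resources.files("petscan.data").joinpath("motifs.yaml").open() as fh:
        return yaml.safe_load(fh)


def reference_sequence() -> ProteinSequence:
    """The bundled IsPETase reference (290-aa precursor)."""
    with resources.files("petscan.data").joinpath("ispetase.faa").open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return ProteinSequence(rec.id, str(rec.seq).upper(), rec.description)


def load_definitions(config=None):
    """Compile tier definitions from ``config`` (path, mapping, or None).

    ``None`` loads the bundled defaults, calibrated on the IsPETase
    reference with distance bounds widened by +/-10 residues per constraint.
    Returns ``(tiers, components)`` where ``tiers`` is the list of five
    cumulative :class:`MotifTierDefinition` and ``components`` maps component
    name to :class:`MotifComponent`.
    """
    if config is None:
        doc = _default_config()
    elif isinstance(config, Mapping):
        doc = config
    else:
        with open(config) as fh:
            doc = yaml.safe_load(fh)

    components: dict[str, MotifComponent] = {}
    for name, spec in doc["components"].items():
        components[name] = MotifComponent(
            name=name,
            pattern=spec["pattern"],
            anchor=int(spec.get("anchor", 0)),
            role=spec.get("role", ""),
        )

    tiers = []
    for tier_name in TIER_NAMES:
        if tier_name not in doc["tiers"]:
            raise DefinitionError(f"missing tier {tier_name}")
        spec = doc["tiers"][tier_name]
        req = frozenset(spec.get("components", []))
        unknown = req - set(components)
        if unknown:
            raise DefinitionError(f"{tier_name}: unknown components {sorted(unknown)}")
        cons = tuple(
            DistanceConstraint(c["from"], c["to"], int(c["min"]), int(c["max"]))
            for c in spec.get("constraints", []) or []
        )
        for c in cons:
            if c.from_component not in req or c.to_component not in req:
                raise DefinitionError(
                    f"{tier_name}: constraint references component outside the tier"
                )
        tiers.append(MotifTierDefinition(tier_name, req, cons))

    for lower, higher in zip(tiers, tiers[1:]):
        if not lower.required_components <= higher.required_components:
            raise DefinitionError(
                f"{higher.tier} does not include every component of {lower.tier}"
            )
        if not set(lower.constraints) <= set(higher.constraints):
            raise DefinitionError(
                f"{higher.tier} does not include every constraint of {lower.tier}"
            )
    return tiers, components


def definitions_to_dict(tiers, components) -> dict:
    """Serialize compiled definitions back to the config document form."""
    return {
        "components": {
            c.name: {"pattern": c.pattern, "anchor": c.anchor, "role": c.role}
            for c in components.values()
        },
        "tiers": {
            t.tier: {
                "components": sorted(t.required_components),
                "constraints": [
                    {
                        "from": c.from_component,
                        "to": c.to_component,
                        "min": c.min_sep,
                        "max": c.max_sep,
                    }
                    for c in t.constraints
                ],
            }
            for t in tiers
        },
    }


# ---------------------------------------------------------------------------
# scanning and classification
# ---------------------------------------------------------------------------

def scan_components(
    seq: ProteinSequence, components: Iterable[MotifComponent]
) -> list[MotifMatch]:
    """Every placement of every component, sorted by start then name."""
    seq.validate()
    residues = seq.residues.upper()
    out: list[MotifMatch] = []
    for comp in components:
        out.extend(comp.scan(residues))
    out.sort(key=lambda m: (m.start, m.component, m.end))
    return out


def _implicit_constraints(tier: MotifTierDefinition):
    """The Ser-Met component must share its serine with the elbow serine."""
    if {"ser_met", "nucleophile_elbow"} <= tier.required_components:
        shared = DistanceConstraint("nucleophile_elbow", "ser_met", 0, 0)
        if shared not in tier.constraints:
            return tier.constraints + (shared,)
    return tier.constraints


def _find_witness(tier, matches_by_comp, anchor_offsets):
    """Lexicographically smallest satisfying placement, or None.

    Components are considered in sorted name order; the witness minimizes the
    tuple of match start positions in that order.  Backtracking over anchor
    placements with constraint checks as soon as both endpoints are fixed.
    """
    names = sorted(tier.required_components)
    constraints = _implicit_constraints(tier)
    for n in names:
        if not matches_by_comp.get(n):
            return None
    # constraints applicable once component at index i is placed
    idx = {n: i for i, n in enumerate(names)}
    by_level: list[list] = [[] for _ in names]
    for c in constraints:
        by_level[max(idx[c.from_component], idx[c.to_component])].append(c)

    assignment: dict[str, int] = {}
    chosen: list[MotifMatch] = []

    def dfs(level: int):
        if level == len(names):
            return True
        name = names[level]
        for m in matches_by_comp[name]:
            assignment[name] = m.start + anchor_offsets[name]
            ok = all(
                c.satisfied(assignment[c.from_component], assignment[c.to_component])
                for c in by_level[level]
            )
            if ok:
                chosen.append(m)
                if dfs(level + 1):
                    return True
                chosen.pop()
        assignment.pop(name, None)
        return False

    if dfs(0):
        return tuple(chosen)
    return None


def classify_tier(
    seq: ProteinSequence, tiers, components=None
) -> TierClassification:
    """Award the highest tier some placement combination satisfies.

    Sequences shorter than any component span are M0, not errors.  The
    witness reported is the lexicographically smallest satisfying placement
    (components in sorted name order, compared by start position).
    """
    if components is None:
        _, components = load_definitions(None)
    seq.validate()

    needed = set().union(*(t.required_components for t in tiers))
    comp_objs = [components[n] for n in needed]
    anchor_offsets = {c.name: c.anchor for c in comp_objs}
    all_matches = scan_components(seq, comp_objs)
    matches_by_comp: dict[str, list[MotifMatch]] = {}
    for m in all_matches:
        matches_by_comp.setdefault(m.component, []).append(m)

    failed_at = None
    ordered = sorted(tiers, key=lambda t: t.rank, reverse=True)
    for tier in ordered:
        missing = [
            n for n in sorted(tier.required_components) if n not in matches_by_comp
        ]
        if missing:
            failed_at = f"{tier.tier}: component {missing[0]} has no match"
            continue
        witness = _find_witness(tier, matches_by_comp, anchor_offsets)
        if witness is not None:
            return TierClassification(seq.id, tier.tier, witness, failed_at)
        failed_at = f"{tier.tier}: no placement satisfies the distance constraints"
    return TierClassification(seq.id, "M0", (), failed_at)


# ---------------------------------------------------------------------------
# batch interface
# ---------------------------------------------------------------------------

def read_fasta(source) -> list[ProteinSequence]:
    """Read a multi-record FASTA (path, handle, or text) into sequences.

    Duplicate ids are suffix-deduplicated (``id_2``, ``id_3``, ...) with a
    warning.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new = f"{rid}_{seen[rid]}"
            warnings.warn(f"duplicate sequence id {rid!r}; renamed to {new!r}")
            rid = new
        else:
            seen[rid] = 1
        out.append(ProteinSequence(rid, str(rec.seq).upper(), rec.description))
    return out


def batch_classify(sequences, tiers=None, components=None):
    """Classify many sequences; returns ``(table, histogram)``.

    ``sequences`` may be a FASTA path/handle or an iterable of
    :class:`ProteinSequence`.  The table has one row per input record in
    input order; unreadable records are flagged in the ``error`` column and
    processing continues.  The histogram maps tier name (M0-M5) to count.
    """
    if tiers is None or components is None:
        tiers, components = load_definitions(None)
    if not isinstance(sequences, (list, tuple)):
        sequences = read_fasta(sequences)
    elif sequences and not isinstance(sequences[0], ProteinSequence):
        sequences = read_fasta(sequences)

    rows = []
    results = []
    for seq in sequences:
        try:
            cls = classify_tier(seq, tiers, components)
            err = ""
        except InputError as exc:
            cls = TierClassification(seq.id, "M0", (), str(exc))
            err = str(exc)
        results.append(cls)
        rows.append(
            {
                "sequence_id": cls.sequence_id,
                "tier": cls.tier,
                "n_placements": len(cls.placements),
                "failed_at": cls.failed_at or "",
                "error": err,
            }
        )
    table = pd.DataFrame(
        rows, columns=["sequence_id", "tier", "n_placements", "failed_at", "error"]
    )
    histogram = {f"M{k}": 0 for k in range(6)}
    for cls in results:
        histogram[cls.tier] += 1
    return table, histogram, results


def write_classification_tsv(results, path_or_handle) -> None:
    """Long-format placement table: one row per witness component match."""
    rows = []
    for cls in results:
        if not cls.placements:
            rows.append(
                {
                    "sequence_id": cls.sequence_id,
                    "tier": cls.tier,
                    "component": "",
                    "start_1based": "",
                    "end_1based": "",
                    "matched_text": "",
                }
            )
        for m in cls.placements:
            rows.append(
                {
                    "sequence_id": cls.sequence_id,
                    "tier": cls.tier,
                    "component": m.component,
                    "start_1based": m.start_1based,
                    "end_1based": m.end_1based,
                    "matched_text": m.matched_text,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "tier", "component",
            "start_1based", "end_1based", "matched_text",
        ],
    )
    df.to_csv(path_or_handle, sep="\t", index=False)
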