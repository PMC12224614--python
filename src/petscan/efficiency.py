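"""Reference-anchored theoretical PETase efficiency scoring.

Candidates are globally aligned to the IsPETase reference so that each
candidate residue acquires an IsPETase position number; a set of key-residue
rules then counts activity-enhancing substitutions (positive) minus
activity-inhibiting ones (negative), with a higher weight on the catalytic
triad and the PETase-specific disulfide cysteines and a penalty when a
critical residue is missing entirely.  The raw score is binned into
low / medium / high efficiency.

The score is a sequence-level heuristic: it reflects the expected *efficacy*
of PET turnover among enzymes that already look like PETases, not the
capability itself (that is what the M1-M5 motif tiers decide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .motif_engine import ProteinSequence, reference_sequence

logger = logging.getLogger("petscan")

#: alignment constants: BLOSUM62, affine gaps open 11 / extend 1 (needle-style)
GAP_OPEN = 11.0
GAP_EXTEND = 1.0

WEIGHT_CLASSES = ("standard", "catalytic_triad", "disulfide")
CRITICAL_CLASSES = ("catalytic_triad", "disulfide")

BINS = ("low", "medium", "high")


class SchemeError(ValueError):
    """Invalid scoring scheme configuration."""


@dataclass(frozen=True)
class KeyResidueRule:
    reference_position: int  # 1-based IsPETase numbering
    reference_residue: str
    positive_set: frozenset
    negative_set: frozenset
    weight_class: str = "standard"
    note: str = ""

    def __post_init__(self):
        if self.weight_class not in WEIGHT_CLASSES:
            raise SchemeError(f"unknown weight class {self.weight_class!r}")
        if self.positive_set & self.negative_set:
            raise SchemeError(
                f"rule at {self.reference_position}: positive and negative "
                "sets overlap"
            )

    @property
    def critical(self) -> bool:
        return self.weight_class in CRITICAL_CLASSES


@dataclass(frozen=True)
class ScoringScheme:
    rules: tuple
    weight_standard: float = 1.0
    weight_critical: float = 3.0
    absence_penalty_critical: float = -3.0
    medium_min: float = 4.0
    high_min: float = 9.0

    def __post_init__(self):
        if not self.weight_critical >= self.weight_standard > 0:
            raise SchemeError("need weight_critical >= weight_standard > 0")
        if not self.high_min > self.medium_min:
            raise SchemeError("bin thresholds must be ordered")

    def weight(self, rule: KeyResidueRule) -> float:
        return self.weight_critical if rule.critical else self.weight_standard


@dataclass(frozen=True)
class ReferenceAlignment:
    """Column-wise pairing of reference and candidate positions (1-based)."""

    candidate_id: str
    columns: tuple  # of (ref_pos or None, cand_pos or None)
    score: float

    def candidate_position(self, ref_pos: int):
        """Candidate position aligned to ``ref_pos``, or None at a gap."""
        for rp, cp in self.columns:
            if rp == ref_pos:
                return cp
        return None


@dataclass(frozen=True)
class EfficiencyScore:
    sequence_id: str
    raw: float
    n_positive: int
    n_negative: int
    per_rule: tuple  # of (rule, observed residue or None, contribution)
    bin: str


# ---------------------------------------------------------------------------
# scheme loading
# ---------------------------------------------------------------------------

def load_scheme(config=None, reference: ProteinSequence | None = None) -> ScoringScheme:
    """Load a scoring scheme from YAML (path/mapping) or the bundled default.

    When ``reference`` is given, every rule's stated reference residue is
    checked against it; a mismatch is a :class:`SchemeError` (it would mean
    the rule numbering does not fit the reference in use).
    """
    if config is None:
        with resources.files("petscan.data").joinpath("scoring.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(config, Mapping):
        doc = config
    else:
        with open(config) as fh:
            doc = yaml.safe_load(fh)

    weights = doc.get("weights", {})
    thresholds = doc.get("thresholds", {})
    rules = []
    for r in doc["rules"]:
        rules.append(
            KeyResidueRule(
                reference_position=int(r["position"]),
                reference_residue=str(r["reference_residue"]).upper(),
                positive_set=frozenset(str(a).upper() for a in r.get("positive", [])),
                negative_set=frozenset(str(a).upper() for a in r.get("negative", [])),
                weight_class=r.get("class", "standard"),
                note=r.get("note", ""),
            )
        )
    scheme = ScoringScheme(
        rules=tuple(rules),
        weight_standard=float(weights.get("standard", 1)),
        weight_critical=float(weights.get("critical", 3)),
        absence_penalty_critical=float(weights.get("absence_penalty_critical", -3)),
        medium_min=float(thresholds.get("medium_min", 4)),
        high_min=float(thresholds.get("high_min", 9)),
    )
    if reference is not None:
        for rule in scheme.rules:
            if rule.reference_position > len(reference.residues):
                raise SchemeError(
                    f"rule position {rule.reference_position} beyond reference length"
                )
            actual = reference.residues[rule.reference_position - 1]
            if actual != rule.reference_residue:
                raise SchemeError(
                    f"rule at {rule.reference_position}: reference residue "
                    f"{rule.reference_residue} but reference has {actual}"
                )
    return scheme


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def align_to_reference(
    candidate: ProteinSequence, reference: ProteinSequence | None = None
) -> ReferenceAlignment:
    """Global BLOSUM62 alignment of ``candidate`` against the reference.

    Traceback ties are resolved deterministically by taking the aligner's
    first (canonical) optimal alignment, which prefers aligned residue pairs
    over gaps and opens reference gaps before candidate gaps.
    """
    if reference is None:
        reference = reference_sequence()
    candidate.validate()
    reference.validate()
    aln = _aligner().align(reference.residues, candidate.residues)
    best = aln[0]
    columns = []
    ref_blocks, cand_blocks = best.aligned
    ref_cursor, cand_cursor = 0, 0
    for (rs, re_), (cs, ce) in zip(ref_blocks, cand_blocks):
        for p in range(ref_cursor, rs):
            columns.append((p + 1, None))
        for p in range(cand_cursor, cs):
            columns.append((None, p + 1))
        for i in range(re_ - rs):
            columns.append((rs + i + 1, cs + i + 1))
        ref_cursor, cand_cursor = re_, ce
    for p in range(ref_cursor, len(reference.residues)):
        columns.append((p + 1, None))
    for p in range(cand_cursor, len(candidate.residues)):
        columns.append((None, p + 1))
    return ReferenceAlignment(candidate.id, tuple(columns), float(best.score))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def extract_key_residues(
    alignment: ReferenceAlignment,
    candidate: ProteinSequence,
    scheme: ScoringScheme,
    reference: ProteinSequence | None = None,
):
    """Observed candidate residue (or None) at every rule position."""
    if reference is None:
        reference = reference_sequence()
    ref_to_cand = {rp: cp for rp, cp in alignment.columns if rp is not None}
    observed = []
    for rule in scheme.rules:
        if rule.reference_position > len(reference.residues):
            raise SchemeError(
                f"rule position {rule.reference_position} beyond reference length"
            )
        cp = ref_to_cand.get(rule.reference_position)
        residue = candidate.residues[cp - 1] if cp is not None else None
        observed.append((rule, residue))
    return observed


def score_efficiency(observed, scheme: ScoringScheme) -> EfficiencyScore:
    """Sum per-rule contributions and bin the raw score.

    Contribution: ``+weight`` when the observed residue is in the rule's
    positive set, ``-weight`` in the negative set, the critical absence
    penalty when a critical rule position is unaligned (gap), otherwise 0.
    The ambiguity residue X never counts for or against.
    """
    per_rule = []
    raw = 0.0
    n_pos = n_neg = 0
    for rule, residue in observed:
        w = scheme.weight(rule)
        if residue is None:
            contrib = scheme.absence_penalty_critical if rule.critical else 0.0
        elif residue in rule.positive_set:
            contrib = +w
            n_pos += 1
        elif residue in rule.negative_set:
            contrib = -w
            n_neg += 1
        else:
            contrib = 0.0
        raw += contrib
        per_rule.append((rule, residue, contrib))
    seq_id = ""
    return EfficiencyScore(
        sequence_id=seq_id,
        raw=raw,
        n_positive=n_pos,
        n_negative=n_neg,
        per_rule=tuple(per_rule),
        bin=bin_efficiency(raw, (scheme.medium_min, scheme.high_min)),
    )


def bin_efficiency(raw: float, thresholds=(4.0, 9.0)) -> str:
    """Piecewise-constant bin; a boundary value falls in the upper bin."""
    medium_min, high_min = thresholds
    if not high_min > medium_min:
        raise SchemeError("bin thresholds must be ordered (medium_min < high_min)")
    if raw >= high_min:
        return "high"
    if raw >= medium_min:
        return "medium"
    return "low"


def score_candidate(
    candidate: ProteinSequence,
    scheme: ScoringScheme | None = None,
    reference: ProteinSequence | None = None,
) -> EfficiencyScore:
    """Align, extract key residues, and score one candidate."""
    if reference is None:
        reference = reference_sequence()
    if scheme is None:
        scheme = load_scheme(None, reference)
    aln = align_to_reference(candidate, reference)
    observed = extract_key_residues(aln, candidate, scheme, reference)
    score = score_efficiency(observed, scheme)
    return EfficiencyScore(
        sequence_id=candidate.id,
        raw=score.raw,
        n_positive=score.n_positive,
        n_negative=score.n_negative,
        per_rule=score.per_rule,
        bin=score.bin,
    )


def score_table(
    candidates: Iterable[ProteinSequence],
    scheme: ScoringScheme | None = None,
    reference: ProteinSequence | None = None,
) -> pd.DataFrame:
    """Scored output table, one column per critical rule's observed residue."""
    if reference is None:
        reference = reference_sequence()
    if scheme is None:
        scheme = load_scheme(None, reference)
    critical_cols = [
        f"ref_{r.reference_residue}{r.reference_position}"
        for r in scheme.rules
        if r.critical
    ]
    rows = []
    for cand in candidates:
        s = score_candidate(cand, scheme, reference)
        row = {
            "sequence_id": s.sequence_id,
            "raw": s.raw,
            "n_positive": s.n_positive,
            "n_negative": s.n_negative,
            "bin": s.bin,
        }
        for (rule, residue, _), col in zip(
            ((r, o, c) for r, o, c in s.per_rule if r.critical), critical_cols
        ):
            row[col] = residue if residue is not None else "-"
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "raw", "n_positive", "n_negative", "bin"]
        + critical_cols,
    )
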