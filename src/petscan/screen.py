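"""Candidate screening: domain pre-filter, tier classification, efficiency
score, and signal-peptide annotation joined into one report.

The screen consumes the *outputs* of the standard external annotators rather
than running them: an hmmsearch per-domain table (``--domtblout``) supplies
the PF01738 dienelactone-hydrolase (DLH) domain pre-filter, and a SignalP 6
prediction table supplies secretion signal calls.  Sequence ids are matched
FASTA-style (description text after the first whitespace is ignored).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from . import efficiency, motif_engine

logger = logging.getLogger("petscan")

#: default independent e-value threshold for domain hits
DEFAULT_EVALUE = 1e-5
DLH_ACCESSION = "PF01738"


@dataclass(frozen=True)
class DomainHit:
    target_id: str
    query_accession: str
    independent_evalue: float
    env_from: int  # 1-based inclusive
    env_to: int


@dataclass(frozen=True)
class SignalPeptideCall:
    sequence_id: str
    has_signal: bool
    cleavage_site: int | None = None
    probability: float = 0.0

    def __post_init__(self):
        if not self.has_signal and self.cleavage_site is not None:
            raise ValueError("cleavage_site present without a signal call")


def _strip_id(raw: str) -> str:
    return raw.split()[0] if raw else raw


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_domtbl(source) -> list[DomainHit]:
    """Parse an hmmsearch per-domain tabular file (``--domtblout``).

    Comment lines (``#``) are skipped; malformed rows are skipped with a
    warning naming the line number.  Fields follow the standard 23-column
    layout; the independent (per-domain) e-value is column 13 and the
    envelope span columns 20-21.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    hits = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        try:
            if len(fields) < 22:
                raise ValueError(f"{len(fields)} fields, expected >= 22")
            hits.append(
                DomainHit(
                    target_id=_strip_id(fields[0]),
                    query_accession=fields[4],
                    independent_evalue=float(fields[12]),
                    env_from=int(fields[19]),
                    env_to=int(fields[20]),
                )
            )
        except (ValueError, IndexError) as exc:
            logger.warning("domtbl line %d malformed, skipped: %s", lineno, exc)
    return hits


def filter_hits(
    hits, accession: str | None = DLH_ACCESSION, evalue: float = DEFAULT_EVALUE
) -> list[DomainHit]:
    """Hits matching ``accession`` (version suffix ignored) under ``evalue``."""
    out = []
    for h in hits:
        if accession is not None and h.query_accession.split(".")[0] != accession:
            continue
        if h.independent_evalue > evalue:
            continue
        out.append(h)
    return out


_CS_RE = re.compile(r"CS pos:\s*(\d+)-(\d+)")


def parse_signalp(source) -> list[SignalPeptideCall]:
    """Parse a SignalP 6 tabular prediction file.

    One call per sequence; the ``OTHER`` label (and, with a warning, any
    unknown label) means no signal.  The cleavage site is read from the
    ``CS pos: a-b`` annotation (position ``a``, the last signal residue).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    calls = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            fields = line.split()
        seq_id = _strip_id(fields[0])
        label = fields[1].strip()
        if label == "OTHER":
            has_signal = False
        elif label.startswith("SP") or label in {"LIPO", "TAT", "TATLIPO", "PILIN"}:
            has_signal = True
        else:
            logger.warning("unknown SignalP label %r for %s; treated as no signal",
                           label, seq_id)
            has_signal = False
        cs = None
        prob = 0.0
        m = _CS_RE.search(line)
        if has_signal and m:
            cs = int(m.group(1))
        for f in fields[2:]:
            try:
                prob = max(prob, float(f.split()[0]))
            except (ValueError, IndexError):
                continue
        calls.append(SignalPeptideCall(seq_id, has_signal, cs, min(prob, 1.0)))
    return calls


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def screen_fasta(
    fasta,
    tiers=None,
    components=None,
    scheme=None,
    domtbl=None,
    signalp=None,
    evalue: float = DEFAULT_EVALUE,
    reference=None,
) -> tuple[pd.DataFrame, dict]:
    """Screen all sequences in ``fasta``; returns ``(report, tier_histogram)``.

    The report has one row per input sequence regardless of annotation
    coverage; annotations whose ids are absent from the FASTA are warned
    about and ignored.  When ``domtbl`` is given, a boolean ``dlh_prefilter``
    column records PF01738 presence under the e-value threshold.
    """
    sequences = motif_engine.read_fasta(fasta)
    if not sequences:
        logger.warning("no sequences in input FASTA")
    if tiers is None or components is None:
        tiers, components = motif_engine.load_definitions(None)
    if reference is None:
        reference = motif_engine.reference_sequence()
    if scheme is None:
        scheme = efficiency.load_scheme(None, reference)

    table, histogram, _ = motif_engine.batch_classify(sequences, tiers, components)
    scores = efficiency.score_table(sequences, scheme, reference)
    report = table.merge(
        scores[["sequence_id", "raw", "n_positive", "n_negative", "bin"]],
        on="sequence_id",
        how="left",
    ).rename(columns={"raw": "efficiency_raw", "bin": "efficiency_bin"})

    known_ids = set(report["sequence_id"])

    if domtbl is not None:
        hits = parse_domtbl(domtbl) if not isinstance(domtbl, list) else domtbl
        passing = {h.target_id for h in filter_hits(hits, DLH_ACCESSION, evalue)}
        for h in hits:
            if h.target_id not in known_ids:
                logger.warning("domtbl id %r not in FASTA; ignored", h.target_id)
        report["dlh_prefilter"] = report["sequence_id"].isin(passing)

    if signalp is not None:
        calls = parse_signalp(signalp) if not isinstance(signalp, list) else signalp
        by_id = {}
        for c in calls:
            if c.sequence_id not in known_ids:
                logger.warning("signalp id %r not in FASTA; ignored", c.sequence_id)
                continue
            by_id[c.sequence_id] = c
        report["has_signal_peptide"] = report["sequence_id"].map(
            lambda i: by_id[i].has_signal if i in by_id else pd.NA
        )
        report["signal_cleavage_site"] = report["sequence_id"].map(
            lambda i: by_id[i].cleavage_site if i in by_id else pd.NA
        )

    logger.info(
        "tier histogram: %s",
        " ".join(f"{k}:{v}" for k, v in histogram.items()),
    )
    return report, histogram
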