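"""Ground-truthed synthetic inputs: planted-motif protein sets and simulated
ocean surveys with a known plastic effect.

Sequence generation plants the M1-M5 motif components, at offsets measured
on the IsPETase reference (so every distance constraint is satisfied by
construction), into a random backbone.  Backbones are rejection-sampled:
any component match outside a planted site triggers regeneration, which
makes the truth tier labels exact rather than merely probable.  Decoys copy
the full M5 layout but violate exactly one named requirement.

Survey generation emulates the study conditions of the plastic-association
analysis: stations on a coarse global grid, each with a surface sample and a
co-located plastic tow; plastic-positive stations draw normalized PETase
abundance from ``effect × baseline`` where the baseline is log-normal.  The
generator emits the plastic, station, and per-gene count tables the other
modules consume, plus the truth parameters for recovery tests.  All
randomness flows from the single seed in the spec; no global RNG state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motif_engine
from .motif_engine import AMINO_ACIDS, ProteinSequence

logger = logging.getLogger("petscan")


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# planted-motif sequences
# ---------------------------------------------------------------------------

# 0-based plant offsets within the reference frame (IsPETase coordinates)
_PLANTS = {
    "pg_g_yf": (84, "PGY"),
    "elbow_quad": (157, None),  # text depends on the Ser+1 residue
    "aromatic_clamp_1": (184, "WDSS"),
    "catalytic_asp": (203, "ENDSI"),
    "catalytic_his": (233, "GGSHS"),
    "dxdxr_block": (262, "DNDTRYSTFAC"),
    "disulfide_cys": (285, "TANC"),
}
#: components planted for each intended tier
_TIER_PLANTS = {
    "M0": (),
    "M1": ("elbow",),
    "M2": ("elbow_quad", "aromatic_clamp_1", "catalytic_asp"),
    "M3": ("elbow_quad", "aromatic_clamp_1", "catalytic_asp", "catalytic_his"),
    "M4": ("elbow_quad", "aromatic_clamp_1", "catalytic_asp", "catalytic_his",
           "pg_g_yf"),
    "M5": ("elbow_quad", "aromatic_clamp_1", "catalytic_asp", "catalytic_his",
           "pg_g_yf", "dxdxr_block", "disulfide_cys"),
}
#: single-violation decoy modes and the tier the decoy must classify as
DECOY_MODES = {
    "ser_met": "M4",            # Ser followed by Leu instead of Met
    "missing_disulfide": "M4",  # disulfide cysteine block absent
    "asp_distance": "M2",       # catalytic Asp shifted past the max distance
}
#: minimal backbone length able to host the full reference-frame layout
_MIN_SPAN = 290


@dataclass(frozen=True)
class SequenceGenSpec:
    """What to generate: counts per tier, backbone model, decoys, seed."""

    n_per_tier: dict = field(default_factory=dict)  # e.g. {"M5": 10, "M0": 5}
    n_decoys: dict = field(default_factory=dict)    # e.g. {"ser_met": 5}
    length_range: tuple = (295, 330)
    background: str = "uniform"  # or "reference" (IsPETase composition)
    seed: int = 0

    def __post_init__(self):
        for tier, n in self.n_per_tier.items():
            if tier not in _TIER_PLANTS:
                raise SpecError(f"unknown tier {tier!r}")
            if n < 0:
                raise SpecError("counts must be >= 0")
        for mode in self.n_decoys:
            if mode not in DECOY_MODES:
                raise SpecError(f"unknown decoy mode {mode!r}")
        lo, hi = self.length_range
        if hi < lo:
            raise SpecError("bad length range")
        planted = [t for t, n in self.n_per_tier.items() if t != "M0" and n > 0]
        if (planted or any(self.n_decoys.values())) and lo < _MIN_SPAN:
            raise SpecError(
                f"length range {self.length_range} too short for planted tiers "
                f"(need >= {_MIN_SPAN})"
            )


def _background_probs(background: str) -> tuple:
    letters = sorted(AMINO_ACIDS)
    if background == "uniform":
        probs = np.full(len(letters), 1 / len(letters))
    elif background == "reference":
        ref = motif_engine.reference_sequence().residues
        counts = np.array([ref.count(a) for a in letters], dtype=float)
        probs = counts / counts.sum()
    else:
        raise SpecError(f"unknown background {background!r}")
    return letters, probs


def _plant_layout(kind: str, decoy: str | None):
    """(component plants, expected spans per engine component) for one record."""
    plants = []  # (offset, text)
    if kind == "M1":
        plants.append((157, "GWSLG"))
    else:
        for name in _TIER_PLANTS[kind]:
            if name == "elbow_quad":
                ser1 = "M" if (kind == "M5" and decoy != "ser_met") else "L"
                plants.append((157, f"GWS{ser1}GGGG"))
            else:
                off, text = _PLANTS[name]
                if decoy == "missing_disulfide" and name == "disulfide_cys":
                    continue
                if decoy == "asp_distance" and name == "catalytic_asp":
                    off = off + 15  # past the +10 slack of the distance bounds
                plants.append((off, text))
    # expected engine-level match spans, per component name
    expected: dict[str, set] = {}

    def expect(comp, start, length):
        expected.setdefault(comp, set()).add((start, start + length))

    for off, text in plants:
        if text.startswith("GWS"):
            expect("nucleophile_elbow", off, 5)
            if "GGGG" in text:
                expect("glycine_quad", off + 4, 4)
            if text[3] == "M":
                expect("ser_met", off + 2, 2)
        elif text == "PGY":
            expect("pg_g_yf", off, 3)
        elif text == "WDSS":
            expect("aromatic_clamp_1", off, 4)
        elif text == "ENDSI":
            expect("catalytic_asp", off, 5)
        elif text == "GGSHS":
            expect("catalytic_his", off, 5)
        elif text == "DNDTRYSTFAC":
            expect("dxdxr_block", off, 11)
        elif text == "TANC":
            expect("disulfide_cys", off, 4)
    return plants, expected


def gen_sequences(spec: SequenceGenSpec, out_fasta=None):
    """Generate planted-motif sequences; returns ``(sequences, truth)``.

    ``truth`` is a DataFrame with ``sequence_id``, ``true_tier`` and
    ``decoy_mode`` columns.  Records are reproducible per seed; the FASTA
    written to ``out_fasta`` (when given) is byte-identical across reruns.
    """
    rng = np.random.default_rng(spec.seed)
    letters, probs = _background_probs(spec.background)
    _, components = motif_engine.load_definitions(None)
    comp_objs = list(components.values())

    jobs = []
    for tier in ("M0", "M1", "M2", "M3", "M4", "M5"):
        for _ in range(spec.n_per_tier.get(tier, 0)):
            jobs.append((tier, None))
    for mode in sorted(spec.n_decoys):
        for _ in range(spec.n_decoys[mode]):
            jobs.append((DECOY_MODES[mode], mode))

    sequences, rows = [], []
    for i, (tier, decoy) in enumerate(jobs):
        kind = "M5" if decoy else tier
        if decoy == "asp_distance":
            kind = "M5"
        seq = _gen_one(rng, kind if not decoy else "M5", decoy, spec, letters,
                       probs, comp_objs)
        name = f"synth_{i:04d}_{tier}" + (f"_{decoy}" if decoy else "")
        sequences.append(ProteinSequence(name, seq, f"planted tier {tier}"))
        rows.append({"sequence_id": name, "true_tier": tier,
                     "decoy_mode": decoy or ""})
    truth = pd.DataFrame(rows, columns=["sequence_id", "true_tier", "decoy_mode"])

    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for s in sequences:
                fh.write(f">{s.id} {s.description}\n")
                for j in range(0, len(s.residues), 60):
                    fh.write(s.residues[j : j + 60] + "\n")
    return sequences, truth


def _gen_one(rng, kind, decoy, spec, letters, probs, comp_objs, max_tries=2000):
    plants, expected = _plant_layout(kind, decoy) if kind != "M0" else ([], {})
    lo, hi = spec.length_range
    for _ in range(max_tries):
        length = int(rng.integers(lo, hi + 1))
        backbone = rng.choice(letters, size=length, p=probs)
        for off, text in plants:
            backbone[off : off + len(text)] = list(text)
        seq = "".join(backbone)
        if _only_planted(seq, expected, comp_objs):
            return seq
    raise SpecError(f"could not generate a clean {kind} backbone in {max_tries} tries")


def _only_planted(seq, expected, comp_objs) -> bool:
    """True when every component match is exactly a planted site."""
    p = ProteinSequence("_", seq)
    for comp in comp_objs:
        spans = {(m.start, m.end) for m in comp.scan(seq)}
        if spans != expected.get(comp.name, set()):
            return False
    return True


# ---------------------------------------------------------------------------
# simulated ocean survey
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyGenSpec:
    """Study conditions of the simulated plastic-association survey.

    Defaults mirror the printed contrast: 816 matched surface records of
    which about 65% are plastic-positive, a 10-fold multiplicative abundance
    effect at plastic-positive stations, a log-normal baseline with median
    0.002 (dimensionless recA-normalized units), and log-sd 1.0.
    """

    n_stations: int = 816
    fraction_positive: float = 533 / 816
    effect: float = 10.0
    sigma: float = 1.0
    baseline_median: float = 0.002
    concentration_median: float = 1000.0  # g/km2 at positive stations
    depth_m: float = 5.0
    n_variant_genes: int = 3
    marker_fragments: int = 100_000
    total_mapped: int = 100_000_000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fraction_positive <= 1:
            raise SpecError("fraction_positive must be in [0,1]")
        if self.effect < 1:
            raise SpecError("effect must be >= 1")


def gen_survey(spec: SurveyGenSpec, out_dir=None):
    """Simulate a matched plastic/metagenome surface survey.

    Returns ``(plastic, stations, counts, truth)``: the plastic-record and
    station-sample tables, a per-sample per-gene fragment count table
    (variant genes plus the recA marker) whose recA-normalized sums
    reproduce the station abundances up to count quantization, and the truth
    parameters.  Stations sit on a 2-degree grid so each plastic tow is
    nearest to exactly its own station.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_stations
    n_pos = int(round(spec.fraction_positive * n))
    positive = np.zeros(n, dtype=bool)
    positive[rng.choice(n, size=n_pos, replace=False)] = True

    # 2-degree station grid between 60S and 60N, clear of the antimeridian
    # so the plastic-tow jitter never leaves the coordinate range
    lats = np.arange(-60, 61, 2.0)
    lons = np.arange(-178, 179, 2.0)
    grid = [(la, lo) for la in lats for lo in lons]
    if n > len(grid):
        raise SpecError(f"n_stations {n} exceeds grid capacity {len(grid)}")
    idx = rng.choice(len(grid), size=n, replace=False)
    coords = np.array([grid[i] for i in idx])

    mu = np.log(spec.baseline_median)
    abundance = np.exp(rng.normal(mu, spec.sigma, size=n))
    abundance[positive] *= spec.effect

    concentration = np.zeros(n)
    concentration[positive] = np.exp(
        rng.normal(np.log(spec.concentration_median), 1.0, size=n_pos)
    )

    # plastic tow within ~0.3 degrees of its station
    jitter = rng.uniform(-0.3, 0.3, size=(n, 2))
    plastic = pd.DataFrame(
        {
            "record_id": [f"plastic_{i:04d}" for i in range(n)],
            "latitude": coords[:, 0] + jitter[:, 0],
            "longitude": coords[:, 1] + jitter[:, 1],
            "concentration": concentration,
        }
    )
    stations = pd.DataFrame(
        {
            "sample_id": [f"sample_{i:04d}" for i in range(n)],
            "latitude": coords[:, 0],
            "longitude": coords[:, 1],
            "depth": np.full(n, spec.depth_m),
            "normalized_abundance": abundance,
        }
    )

    counts = _counts_from_abundance(stations, spec, rng)
    truth = {
        "effect": spec.effect,
        "sigma": spec.sigma,
        "baseline_median": spec.baseline_median,
        "n_positive": int(n_pos),
        "n_negative": int(n - n_pos),
        "seed": spec.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plastic.to_csv(out / "plastic.tsv", sep="\t", index=False)
        stations.to_csv(out / "stations.tsv", sep="\t", index=False)
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        pd.Series(truth).to_json(out / "truth.json")
    return plastic, stations, counts, truth


def _counts_from_abundance(stations, spec, rng):
    """Per-gene fragment counts whose recA ratio reproduces the abundances."""
    rows = []
    variant_ids = [f"petase_var_{k}" for k in range(spec.n_variant_genes)]
    for rec in stations.itertuples(index=False):
        target = rec.normalized_abundance * spec.marker_fragments
        split = rng.dirichlet(np.ones(spec.n_variant_genes))
        frags = np.round(split * target).astype(int)
        for gid, f in zip(variant_ids, frags):
            rows.append(
                {"sample_id": rec.sample_id, "gene_id": gid, "fragments": int(f),
                 "gene_length": 1000,
                 "total_mapped_fragments": spec.total_mapped}
            )
        rows.append(
            {"sample_id": rec.sample_id, "gene_id": "recA",
             "fragments": spec.marker_fragments, "gene_length": 1000,
             "total_mapped_fragments": spec.total_mapped}
        )
    return pd.DataFrame(rows, columns=list(
        ("sample_id", "gene_id", "fragments", "gene_length",
         "total_mapped_fragments")
    ))


def variant_gene_ids(spec: SurveyGenSpec) -> list[str]:
    return [f"petase_var_{k}" for k in range(spec.n_variant_genes)]


# ---------------------------------------------------------------------------
# depth profiles (for the depth-trend model)
# ---------------------------------------------------------------------------

def gen_depth_profiles(
    n_stations: int = 11,
    depths_m=(50, 300, 750, 1500, 2500, 3500),
    slope: float = 0.4,
    intercept: float = -2.0,
    station_sd: float = 0.3,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Vertical profiles with a planted linear depth effect.

    The response is on the (log-abundance-like) model scale:
    ``value = intercept + slope * depth_km + station_intercept + noise``;
    depth enters in kilometers.  Returns ``(table, truth)`` where the table
    has ``station, depth, value`` columns (depth in km).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_stations):
        b0 = rng.normal(0.0, station_sd)
        for d in depths_m:
            depth_km = d / 1000.0
            value = intercept + slope * depth_km + b0 + rng.normal(0.0, noise_sd)
            rows.append({"station": f"st_{s:02d}", "depth": depth_km, "value": value})
    truth = {"slope": slope, "intercept": intercept, "station_sd": station_sd,
             "noise_sd": noise_sd, "seed": seed}
    return pd.DataFrame(rows), truth
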