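# Methods

## Motif model

The M1–M5 tiers encode what distinguishes a functional PETase from the
generic dienelactone-hydrolase (DLH) fold, as cumulative sequence filters.
Each tier is a set of *components* — PROSITE-style patterns with an anchor
residue — plus pairwise distance constraints between anchors; tier Mk's
components and constraints are supersets of Mk−1's, and the loader rejects
non-cumulative custom definitions. Classification uses existential
semantics: a sequence is awarded the highest tier for which *some*
combination of component placements satisfies every constraint, found by
backtracking over all placements (an exhaustive-enumeration oracle in the
test suite checks this on sequences ≤ 300 aa). The reported witness is the
lexicographically smallest satisfying placement with components ordered by
name. The Ser-Met component (oxyanion-hole methionine) must share its
serine with the nucleophile-elbow serine; this is enforced as an implicit
zero-separation constraint between the two anchors.

The bundled definitions are calibrated on the 290-aa *Is*PETase precursor
shipped with the package. Component patterns were transcribed from the
residue neighborhoods of the canonical functional residues — the
`G-x-S-x-G` elbow at 158–162 (catalytic S160), `GGGG` at 162–165, the W185
aromatic clamp, the catalytic D206 and H237, `[PG]-G-[YF]` at 85–87, the
`DxDxR(Y)xxFxC` block at 263–273 and the C-terminal disulfide cysteine
C289. Distance bounds are the reference anchor separations widened by ±10
residues per constraint, so the reference passes M5 by construction and
moderate indel drift is tolerated; tighter empirical bounds can be dropped
into the YAML without code changes. Presence-only checks apply at M1–M2;
distance constraints begin at M3, where the complete catalytic triad first
appears. Two conventions worth knowing: the ambiguity residue X never
satisfies a constrained position (conservative — prevents spurious M5
calls) but does match pure wildcards, and the aromatic `(Y)` inside
`DxDxR(Y)xxFxC` is optional by default (the block's wildcard gap spans 2 or
3 positions); requiring it is a one-line YAML edit.

## Efficiency score

The score ranks sequences that already look like PETases by expected
efficacy. A candidate is globally aligned to *Is*PETase with BLOSUM62 and
affine gap penalties (open 11, extend 1 — the classic needle defaults for
proteins); the first optimal traceback of the aligner is used, which is
deterministic. Each key-residue rule then reads the candidate residue at
one *Is*PETase position: +w if it is a known activity-enhancing
substitution, −w if inhibiting, a −3 penalty if a catalytic-triad or
disulfide position is aligned to a gap, else 0. Standard rules carry w = 1,
critical ones w = 3. Raw scores bin into low (< 4), medium (4–8) and high
(≥ 9), boundaries inclusive on the upper bin. The bundled rule table
anchors the back-wall residues A89/W159 (acidic/His substitutions there
impair activity), the triad S160/D206/H237, the active-site disulfide
C203/C239, and nine enhancing substitutions from the *Is*PETase engineering
literature at positions verified against the bundled reference (S121E,
T140D, I168R, A180I, S214H, R224Q, N233K, S238F, R280A); a fully optimized
variant therefore scores 9 under the defaults. Ranking is robust to the
critical-weight choice (Spearman ≥ 0.8 across w ∈ {2, 3, 4} on a synthetic
panel, asserted in the tests). The table deliberately avoids residues
probed by the motif filters, and ships as editable YAML so a different
substitution catalog can be dropped in.

## Abundance and depth structure

FPKM = fragments / ((gene length / 10³) × (total mapped fragments / 10⁶)).
Per sample, the summed FPKM of the functional-variant genes is divided by
the summed FPKM of the single-copy marker recA (multiple recA copies in a
catalog are summed; the ratio is then "variant copies per genome").
Samples without marker signal get a missing value, never a zero. Detection
is strictly ratio > 0. Because the marker ratio cancels units, length-
normalized transcript counts can be fed through the same machinery
unchanged. Depth summaries use six half-open layers (0–100, 100–500,
500–1000, 1000–2000, 2000–3000, > 3000 m); detection fractions are over all
samples in a layer, means ± SE (sd/√n) only over detected samples. The
depth trend is a linear mixed model (`value ~ depth`, per-station random
intercept, REML via statsmodels); depth units and any response transform
are the caller's choice — the generator and tests use depth in km on a
log-abundance-like scale. A single station degenerates to OLS with a
warning.

## Plastic association

Plastic tow records carry g/km² at a surface position. Each record is
matched to the nearest sequencing-sample location within 5° of arc,
computed as a great-circle (haversine) distance with threshold
5°·R⊕ ≈ 556 km (a flat lat/lon degree metric is available behind a flag for
sensitivity checks). Only samples ≤ 10 m deep are eligible, because the
plastic data are surface tows. "Same location" means coordinates equal
after rounding to 4 decimals (~11 m); all samples at the matched location
join the record, one sample may serve many records, and records with no
in-radius sample are discarded. Presence (concentration > 0) vs absence of
plastic is contrasted with a two-sided Mann–Whitney U — exact enumeration
when n₁·n₂ ≤ 400 without ties, tie-corrected normal approximation
otherwise — and the linear relation is an untransformed OLS fit reporting
slope, intercept, R² and the slope's two-sided p.

## Synthetic data

The sequence generator plants component texts taken from the reference
(`PGY`, `GWS[M|L]GGGG`, `WDSS`, `ENDSI`, `GGSHS`, `DNDTRYSTFAC`, `TANC`) at
the reference offsets inside a random backbone (uniform or
reference-composition residues, length 295–330 by default), so all distance
constraints hold by construction. Backbones are rejection-sampled until no
component matches anywhere except the planted sites, which makes truth
labels exact rather than probable — the closed-loop property
(classify(generate(tier)) == tier) is asserted over many seeds. Decoys copy
the full M5 layout and violate exactly one requirement: Leu instead of Met
after the catalytic serine (→ M4), a missing disulfide block (→ M4), or the
catalytic Asp shifted 15 residues — past the ±10 slack (→ M2).

The survey generator emulates the matched surface survey: stations on a 2°
grid (60°S–60°N, clear of the antimeridian), one ≤ 10 m sample and one
co-located plastic tow each, so nearest-neighbor matching is unambiguous
and yields exactly one association per station. Defaults are 816 stations
with 533/816 plastic-positive, mirroring the published group sizes; the
normalized-abundance baseline is log-normal with median 0.002 and log-sd
1.0, and plastic-positive stations are scaled by the effect ratio (default
10). Positive stations draw concentrations log-normally around 1000 g/km².
The generator also emits a per-gene fragment-count table (three variant
genes split by a Dirichlet draw, plus a recA marker at 10⁵ fragments) whose
recA-normalized sums reproduce the station abundances up to count
quantization (~10⁻⁵), so the abundance module can be exercised end to end.
What the simulation does *not* emulate: phylogenetic covariance between
variants, spatial autocorrelation of pollution, ocean circulation, or
many-to-many station geometry — passing tests show the statistics and
plumbing are correct under the stated model, not that field data meet the
model. All randomness flows from the spec's single seed; no global RNG
state is touched.

## Problem sizes and numerics

The test suite and the acceptance script run on generated data at the sizes
stated in-line: 500+ planted sequences for recovery, a 200-case corpus for
the placement-enumeration oracle, 100 survey seeds for power at α = 0.001
and 200 for the null at α = 0.05, and 11 stations × 6 depths for slope
recovery — sizes chosen so each check is statistically meaningful while the
whole suite stays fast. Scale invariances of FPKM are asserted to within
one floating-point ulp; Mann–Whitney exactness is checked against full
permutation enumeration at small n. Known limitations: the bundled motif
patterns and scoring rules are a reference-calibrated transcription, not a
fitted model — on real candidate catalogs they should be reviewed against
curated alignments before quantitative use; the efficiency score is a
sequence heuristic with no structural or thermodynamic term; and the
5°-radius matching treats plastic concentration as static at the tow
position.
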