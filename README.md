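# petscan

Motif-tier classification, efficiency scoring, and ocean-survey statistics
for PET hydrolase (PETase) candidate sequences.

## The problem

PET hydrolases — cutinase-like serine hydrolases that depolymerize
polyethylene terephthalate — share their dienelactone-hydrolase (DLH,
Pfam PF01738) α/β fold with a crowd of enzymes that cannot touch PET.
Screening environmental sequence collections (e.g. ocean metagenome gene
catalogs) for *functional* PETases therefore needs more than a domain hit:
it needs the specific constellation of residues that makes the fold a
PETase, and a way to rank how efficient a hit is likely to be.

`petscan` is a desk-scale toolkit for that screen, aimed at microbial
ecologists and enzyme hunters working from protein FASTA plus standard
annotation outputs:

- **Motif tiers M1–M5** (`petscan.motif_engine`). Five cumulative filters of
  increasing stringency, expressed as PROSITE-style patterns with pairwise
  distance constraints. M1 asks only for the promiscuous nucleophile-elbow
  motif `G-x-S-x-G` that carries the catalytic serine; M2 adds the `GGGG`
  core-packing run, an aromatic clamp and the catalytic aspartate; M3
  completes the catalytic triad (His) and turns on the distance constraints;
  M4 adds the `[PG]-G-[YF]` clamp/oxyanion motif; M5 demands a methionine
  directly after the catalytic serine, the conserved `DxDxR(Y)xxFxC` block
  and the stabilizing disulfide cysteine. A sequence gets the highest tier
  for which *some* placement of components satisfies every constraint; only
  complete M5 marks a functional PETase. Defaults are calibrated on the
  bundled *Is*PETase reference (the catalytic serine is S160 in its
  numbering) and every bound is editable YAML.
- **Efficiency score** (`petscan.efficiency`). Candidates are globally
  aligned to *Is*PETase (BLOSUM62, affine gaps 11/1) and scored as the
  weighted count of known activity-enhancing substitutions minus inhibiting
  ones; the catalytic triad and the PETase-specific disulfide carry weight 3
  and a −3 absence penalty. Raw scores bin into low (<4), medium (4–8) and
  high (≥9).
- **Screening** (`petscan.screen`). Joins tier calls and efficiency scores
  with a PF01738 pre-filter parsed from `hmmsearch --domtblout` output and
  secretion-signal calls parsed from SignalP 6 tables.
- **Abundance** (`petscan.abundance`). FPKM from fragment counts,
  normalization by the single-copy marker *recA* (Σ variant FPKM / recA
  FPKM per sample), six-depth-layer detection summaries, a mixed-model
  depth trend, and PETase/MHETase co-occurrence counts.
- **Plastic association** (`petscan.plastic_assoc`). Matches surface plastic
  survey records (g/km²) to sequencing samples within a 5° great-circle
  radius (samples ≤ 10 m deep), then contrasts normalized PETase abundance
  by plastic presence (Mann–Whitney U) and fits the linear
  concentration–abundance relation (OLS, R²).
- **Synthetic data** (`petscan.synthetic_data`). Ground-truthed generators:
  planted-motif protein sets with single-violation decoys, and simulated
  surveys with a known multiplicative plastic effect (default 10×).

## Worked example

Generate a small ground-truthed sequence set and classify it:

```sh
$ petscan simulate sequences --seed 42 --n-per-tier "M0:2,M3:2,M5:2" --out demo
$ petscan classify --fasta demo/sequences.faa --out demo/cls.tsv
INFO petscan: tier histogram: M0:2 M1:0 M2:0 M3:2 M4:0 M5:2
$ cat demo/cls.tsv
# petscan 0.1.0
# fasta = demo/sequences.faa
# definitions = bundled
sequence_id	tier	n_placements	failed_at	error
synth_0000_M0	M0	0	M1: component nucleophile_elbow has no match
synth_0001_M0	M0	0	M1: component nucleophile_elbow has no match
synth_0002_M3	M3	5	M4: component pg_g_yf has no match
synth_0003_M3	M3	5	M4: component pg_g_yf has no match
synth_0004_M5	M5	9
synth_0005_M5	M5	9
```

Each row reports the awarded tier, the number of witness component
placements backing it, and the first requirement that blocked the next tier
up: the two M3 records carry the full catalytic triad at valid distances (5
placements) but lack the `[PG]-G-[YF]` motif required for M4, while the two
M5 records satisfy all nine components. A companion
`demo/cls.placements.tsv` lists every witness match with 1-based
coordinates. The same library calls are available in Python
(`petscan.batch_classify`, `petscan.score_candidate`, ...), and
`petscan screen/abundance/assoc/score` cover the other pipeline stages.

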