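# Default key-residue scoring scheme for theoretical PETase efficiency,
# expressed in 1-based IsPETase (290-aa precursor) numbering.
#
# Each rule names a reference position, the IsPETase wild-type residue, the
# substitutions counted as activity-enhancing (positive) or inhibiting
# (negative), and a weight class.  catalytic_triad and disulfide rules carry
# the critical weight and the critical absence penalty; standard rules carry
# unit weight.  Positive sets at standard rules are drawn from substitutions
# reported to enhance IsPETase activity or stability in the enzyme-engineering
# literature; the set is editable and deliberately non-overlapping with the
# residues probed by the M1-M5 motif filters.
weights:
  standard: 1
  critical: 3
  absence_penalty_critical: -3
thresholds:
  medium_min: 4
  high_min: 9
rules:
  - {position: 89,  reference_residue: A, positive: [], negative: [E, D, H],
     class: standard, note: ligand-binding back wall; acidic/His back wall impairs activity}
  - {position: 121, reference_residue: S, positive: [E], negative: [],
     class: standard, note: surface stabilization}
  - {position: 140, reference_residue: T, positive: [D], negative: [],
     class: standard, note: surface salt-bridge stabilization}
  - {position: 159, reference_residue: W, positive: [], negative: [H, E],
     class: standard, note: ligand-binding back wall tryptophan}
  - {position: 160, reference_residue: S, positive: [], negative: [A, G, T],
     class: catalytic_triad, note: catalytic nucleophile serine (S160A is inactive)}
  - {position: 168, reference_residue: I, positive: [R], negative: [],
     class: standard, note: binding-cleft polar substitution}
  - {position: 180, reference_residue: A, positive: [I], negative: [],
     class: standard, note: hydrophobic core packing}
  - {position: 203, reference_residue: C, positive: [], negative: [A, S],
     class: disulfide, note: PETase-specific disulfide partner near the active site}
  - {position: 206, reference_residue: D, positive: [], negative: [A, N],
     class: catalytic_triad, note: catalytic aspartate}
  - {position: 214, reference_residue: S, positive: [H], negative: [],
     class: standard, note: active-site second shell}
  - {position: 224, reference_residue: R, positive: [Q], negative: [],
     class: standard, note: reduces steric hindrance near the cleft}
  - {position: 233, reference_residue: N, positive: [K], negative: [],
     class: standard, note: stabilizing salt bridge}
  - {position: 237, reference_residue: H, positive: [], negative: [A, F],
     class: catalytic_triad, note: catalytic histidine}
  - {position: 238, reference_residue: S, positive: [F], negative: [],
     class: standard, note: deepens the substrate-binding cleft}
  - {position: 239, reference_residue: C, positive: [], negative: [A, S],
     class: disulfide, note: PETase-specific disulfide partner near the active site}
  - {position: 280, reference_residue: R, positive: [A], negative: [],
     class: standard, note: relieves steric hindrance at the cleft entrance}
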