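# Default M1-M5 motif tier definitions for PET hydrolase (PETase) screening.
#
# Patterns are PROSITE-style: residue alternatives in brackets, `x` an
# unconstrained position, `x(n,m)` a bounded wildcard gap.  Each component
# carries an `anchor` offset (0-based, within the fixed-length prefix of the
# pattern) marking the functionally defining residue; distance constraints are
# measured between anchors.  All patterns and distance bounds are calibrated
# on the bundled IsPETase reference (1-based numbering of the 290-aa
# precursor): the catalytic serine S160 sits in the G-x-S-x-G nucleophile
# elbow at 158-162, GGGG at 162-165, the [PG]-G-[YF] clamp/oxyanion motif at
# 85-87, the aromatic clamp tryptophan at W185, the catalytic D206 and H237,
# the DxDxR(Y)xxFxC block at 263-273 and the C-terminal disulfide cysteine
# C289.  Distance bounds are the reference separations widened by +/-10
# residues; edit this file to drop in tighter (or looser) bounds.
components:
  nucleophile_elbow:
    pattern: G-x-S-x-G
    anchor: 2
    role: helix-4 nucleophile elbow carrying the catalytic serine (S160)
  glycine_quad:
    pattern: G-G-G-G
    anchor: 0
    role: conserved four-glycine motif embedding helix-4 into the core
  aromatic_clamp_1:
    pattern: "[WY]-[DN]-S-[ST]"
    anchor: 0
    role: aromatic clamp sandwiching the PET aromatic ring (W185)
  catalytic_asp:
    pattern: "[ED]-[NS]-D-[ST]-[ILVMF]"
    anchor: 2
    role: catalytic aspartate of the charge-relay triad (D206)
  catalytic_his:
    pattern: "G-G-[SAT]-H-[SA]"
    anchor: 3
    role: catalytic histidine completing the triad (H237)
  pg_g_yf:
    pattern: "[PG]-G-[YF]"
    anchor: 0
    role: additional aromatic clamp and oxyanion hole upstream of the triad
  ser_met:
    pattern: S-M
    anchor: 0
    role: methionine directly after the catalytic serine (oxyanion hole)
  dxdxr_block:
    pattern: D-x-D-x-R-x(2,3)-F-x-C
    anchor: 0
    role: >
      conserved DxDxR(Y)xxFxC block packing the final helix to the core; the
      aromatic (Y) position is optional by default (gap 2 or 3), tighten to
      D-x-D-x-R-Y-x-x-F-x-C to require it
  disulfide_cys:
    pattern: T-x-N-C
    anchor: 3
    role: C-terminal cysteine of the stabilizing internal disulfide (C289)

tiers:
  M1:
    components: [nucleophile_elbow]
    constraints: []
  M2:
    components: [nucleophile_elbow, glycine_quad, aromatic_clamp_1, catalytic_asp]
    constraints: []
  M3:
    components: [nucleophile_elbow, glycine_quad, aromatic_clamp_1, catalytic_asp,
                 catalytic_his]
    constraints:
      - {from: nucleophile_elbow, to: glycine_quad, min: 0, max: 12}
      - {from: glycine_quad, to: aromatic_clamp_1, min: 13, max: 33}
      - {from: nucleophile_elbow, to: catalytic_asp, min: 36, max: 56}
      - {from: catalytic_asp, to: catalytic_his, min: 21, max: 41}
  M4:
    components: [nucleophile_elbow, glycine_quad, aromatic_clamp_1, catalytic_asp,
                 catalytic_his, pg_g_yf]
    constraints:
      - {from: nucleophile_elbow, to: glycine_quad, min: 0, max: 12}
      - {from: glycine_quad, to: aromatic_clamp_1, min: 13, max: 33}
      - {from: nucleophile_elbow, to: catalytic_asp, min: 36, max: 56}
      - {from: catalytic_asp, to: catalytic_his, min: 21, max: 41}
      - {from: pg_g_yf, to: nucleophile_elbow, min: 65, max: 85}
  M5:
    components: [nucleophile_elbow, glycine_quad, aromatic_clamp_1, catalytic_asp,
                 catalytic_his, pg_g_yf, ser_met, dxdxr_block, disulfide_cys]
    constraints:
      - {from: nucleophile_elbow, to: glycine_quad, min: 0, max: 12}
      - {from: glycine_quad, to: aromatic_clamp_1, min: 13, max: 33}
      - {from: nucleophile_elbow, to: catalytic_asp, min: 36, max: 56}
      - {from: catalytic_asp, to: catalytic_his, min: 21, max: 41}
      - {from: pg_g_yf, to: nucleophile_elbow, min: 65, max: 85}
      - {from: nucleophile_elbow, to: ser_met, min: 0, max: 0}
      - {from: catalytic_his, to: dxdxr_block, min: 16, max: 36}
      - {from: dxdxr_block, to: disulfide_cys, min: 16, max: 36}
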