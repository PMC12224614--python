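"""Motif scanning and tier classification."""

import io

import pytest

from petscan import motif_engine as me
from petscan.synthetic_data import SequenceGenSpec, gen_sequences

from conftest import naive_scan, oracle_classify


class TestPatternSyntax:
    @pytest.mark.parametrize("bad", ["", "Z1-G", "[", "[ABJ]", "x(3,2)", "G--S"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(me.PatternError):
            me.parse_pattern(bad, component="c")

    def test_bounded_gap_expansion(self):
        comp = me.MotifComponent("d", "D-x(1,2)-R", anchor=0)
        spans = {(m.start, m.end) for m in comp.scan("DAARDAR")}
        # DAAR (gap 2) at 0 and DAR (gap 1) at 4
        assert spans == {(0, 4), (4, 7)}

    def test_anchor_must_sit_in_fixed_prefix(self):
        with pytest.raises(me.PatternError):
            me.MotifComponent("d", "D-x(1,2)-R", anchor=3)


class TestScanComponents:
    def test_single_literal_occurrence(self, defaults):
        _, comps = defaults
        seq = me.ProteinSequence("t", "AAGGGGAA")
        (m,) = me.scan_components(seq, [comps["glycine_quad"]])
        assert (m.start_1based, m.end_1based, m.matched_text) == (3, 6, "GGGG")

    def test_overlap_enumeration(self, defaults):
        _, comps = defaults
        seq = me.ProteinSequence("t", "GGGGG")
        spans = [(m.start_1based, m.end_1based)
                 for m in me.scan_components(seq, [comps["glycine_quad"]])]
        assert spans == [(1, 4), (2, 5)]

    def test_matches_equal_naive_position_oracle(self, defaults, random_proteins):
        _, comps = defaults
        for seq in random_proteins[:30]:
            for comp in comps.values():
                got = {(m.start, m.end) for m in comp.scan(seq.residues)}
                assert got == naive_scan(seq.residues, comp.pattern), comp.name

    def test_ambiguity_x_never_satisfies_a_residue_set(self, defaults):
        _, comps = defaults
        seq = me.ProteinSequence("t", "GGGX" + "AGGGGA")
        spans = {(m.start, m.end) for m in comps["glycine_quad"].scan(seq.residues)}
        assert spans == {(5, 9)}


class TestDefinitions:
    def test_defaults_have_five_cumulative_tiers(self, defaults):
        tiers, comps = defaults
        assert [t.tier for t in tiers] == ["M1", "M2", "M3", "M4", "M5"]
        assert tiers[-1].required_components == set(me.COMPONENT_NAMES)
        for lo, hi in zip(tiers, tiers[1:]):
            assert lo.required_components <= hi.required_components
            assert set(lo.constraints) <= set(hi.constraints)

    def test_round_trip_serialization(self, defaults):
        tiers, comps = defaults
        doc = me.definitions_to_dict(tiers, comps)
        tiers2, comps2 = me.load_definitions(doc)
        assert tiers2 == tiers
        assert comps2 == comps

    def test_non_cumulative_config_rejected(self, defaults):
        tiers, comps = defaults
        doc = me.definitions_to_dict(tiers, comps)
        doc["tiers"]["M2"]["components"].remove("nucleophile_elbow")
        with pytest.raises(me.DefinitionError):
            me.load_definitions(doc)

    def test_constraint_outside_tier_rejected(self, defaults):
        tiers, comps = defaults
        doc = me.definitions_to_dict(tiers, comps)
        doc["tiers"]["M1"]["constraints"] = [
            {"from": "nucleophile_elbow", "to": "catalytic_his", "min": 0, "max": 99}
        ]
        with pytest.raises(me.DefinitionError):
            me.load_definitions(doc)


class TestClassifyTier:
    def test_reference_is_m5(self, defaults, reference):
        tiers, comps = defaults
        cls = me.classify_tier(reference, tiers, comps)
        assert cls.tier == "M5"
        by_comp = {m.component: m for m in cls.placements}
        # catalytic serine anchored at IsPETase S160
        elbow = by_comp["nucleophile_elbow"]
        assert elbow.start + comps["nucleophile_elbow"].anchor + 1 == 160
        assert by_comp["ser_met"].start_1based == 160

    def test_polyalanine_is_m0(self, defaults):
        tiers, comps = defaults
        cls = me.classify_tier(me.ProteinSequence("ala", "A" * 300), tiers, comps)
        assert cls.tier == "M0"
        assert cls.placements == ()

    def test_short_sequence_is_m0_not_error(self, defaults):
        tiers, comps = defaults
        assert me.classify_tier(me.ProteinSequence("s", "GWSMG"), tiers, comps).tier == "M1"
        assert me.classify_tier(me.ProteinSequence("s", "AC"), tiers, comps).tier == "M0"

    def test_invalid_residues_raise(self, defaults):
        tiers, comps = defaults
        with pytest.raises(me.InputError):
            me.classify_tier(me.ProteinSequence("bad", "ACDEB"), tiers, comps)

    def test_ser_leu_decoy_drops_to_m4(self, defaults):
        tiers, comps = defaults
        spec = SequenceGenSpec(n_decoys={"ser_met": 3}, seed=7)
        seqs, truth = gen_sequences(spec)
        for seq in seqs:
            assert me.classify_tier(seq, tiers, comps).tier == "M4"

    def test_agrees_with_exhaustive_placement_oracle(self, defaults, random_proteins):
        tiers, comps = defaults
        spec = SequenceGenSpec(
            n_per_tier={"M0": 5, "M1": 5, "M2": 5, "M3": 5, "M4": 5, "M5": 5},
            n_decoys={"ser_met": 3, "missing_disulfide": 3, "asp_distance": 3},
            seed=11,
        )
        planted, _ = gen_sequences(spec)
        for seq in planted + random_proteins[:30]:
            got = me.classify_tier(seq, tiers, comps).tier
            assert got == oracle_classify(seq, tiers, comps), seq.id

    def test_cumulativity_of_awarded_tiers(self, defaults):
        """Awarded tier Mk implies every lower tier is satisfiable alone."""
        tiers, comps = defaults
        spec = SequenceGenSpec(
            n_per_tier={"M1": 10, "M2": 10, "M3": 10, "M4": 10, "M5": 10}, seed=5
        )
        seqs, _ = gen_sequences(spec)
        for seq in seqs:
            cls = me.classify_tier(seq, tiers, comps)
            k = cls.rank
            for lower in tiers[: max(k - 1, 0)]:
                sub = me.classify_tier(seq, [lower], comps)
                assert sub.rank >= lower.rank, (seq.id, lower.tier)

    def test_flank_stability(self, defaults):
        """Flanking runs of a residue absent from all patterns keep the tier."""
        tiers, comps = defaults
        spec = SequenceGenSpec(n_per_tier={"M3": 3, "M5": 3}, seed=9)
        seqs, truth = gen_sequences(spec)
        for seq, want in zip(seqs, truth["true_tier"]):
            padded = me.ProteinSequence(seq.id, "K" * 25 + seq.residues + "K" * 25)
            assert me.classify_tier(padded, tiers, comps).tier == want


class TestBatch:
    def test_empty_fasta(self, defaults):
        tiers, comps = defaults
        table, hist, _ = me.batch_classify(io.StringIO(""), tiers, comps)
        assert len(table) == 0
        assert all(v == 0 for v in hist.values())

    def test_duplicate_ids_deduplicated_with_warning(self):
        fasta = ">a\nGWSMG\n>a\nACDE\n"
        with pytest.warns(UserWarning, match="duplicate"):
            seqs = me.read_fasta(io.StringIO(fasta))
        assert [s.id for s in seqs] == ["a", "a_2"]

    def test_planted_set_fully_recovered(self, defaults):
        tiers, comps = defaults
        spec = SequenceGenSpec(
            n_per_tier={"M0": 10, "M2": 10, "M5": 10}, seed=13
        )
        seqs, truth = gen_sequences(spec)
        table, hist, _ = me.batch_classify(seqs, tiers, comps)
        assert list(table["tier"]) == list(truth["true_tier"])
        assert hist["M0"] == hist["M2"] == hist["M5"] == 10

    def test_output_table_is_deterministic(self, defaults):
        tiers, comps = defaults
        spec = SequenceGenSpec(n_per_tier={"M4": 5}, seed=3)
        seqs, _ = gen_sequences(spec)
        bufs = []
        for _ in range(2):
            _, _, results = me.batch_classify(seqs, tiers, comps)
            buf = io.StringIO()
            me.write_classification_tsv(results, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]
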