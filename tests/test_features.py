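"""The 46-feature protein encoder against independent oracles."""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings, strategies as st

from sielunet.features import (
    AMINO_ACIDS,
    FEATURE_NAMES,
    DEFAULT_SCHEMA,
    ProteinFeaturizer,
    ProteinRecord,
    aliphatic_index,
    atom_counts,
    charge_counts,
    coiled_coil_score,
    composition,
    extract_features,
    extract_feature_table,
    gravy,
    instability_index,
    molecular_weight,
    net_charge,
    ptm_motif_counts,
    sanitize_sequence,
    theoretical_pi,
)

protein_seq = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


class TestSanitize:
    @pytest.mark.parametrize(
        "raw, policy, expected",
        [
            ("acdE", "strict", "ACDE"),
            ("AXC", "drop", "AC"),
            ("ABZ", "impute", "ANQ"),
            ("AUX", "impute", "AC"),
        ],
    )
    def test_policies(self, raw, policy, expected):
        assert sanitize_sequence(raw, policy) == expected

    def test_strict_rejects_ambiguous(self):
        with pytest.raises(ValueError, match="non-standard"):
            sanitize_sequence("AXB", "strict")

    def test_empty_after_sanitization(self):
        with pytest.raises(ValueError, match="empty"):
            sanitize_sequence("XXX", "drop")


class TestComposition:
    def test_homopolymer(self):
        comp = composition("AAAA")
        assert comp[AMINO_ACIDS.index("A")] == 1.0
        assert comp.sum() == pytest.approx(1.0)

    def test_equal_quarters(self):
        comp = composition("ARND")
        for aa in "ARND":
            assert comp[AMINO_ACIDS.index(aa)] == 0.25

    @given(protein_seq)
    @settings(deadline=None)
    def test_fractions_sum_to_one(self, seq):
        assert composition(seq).sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_unsanitized(self):
        with pytest.raises(ValueError, match="sanitize"):
            composition("AXC")


class TestSimpleCounts:
    @pytest.mark.parametrize(
        "seq, expected",
        [("DDEE", (4, 0)), ("KKRR", (0, 4)), ("GGGG", (0, 0)), ("HHHH", (0, 0))],
    )
    def test_charge_counts(self, seq, expected):
        assert charge_counts(seq) == expected

    def test_glycine_formula(self):
        assert atom_counts("G") == (2, 5, 1, 2, 0)

    def test_cysteine_has_sulphur(self):
        assert atom_counts("C")[4] == 1

    @given(protein_seq, protein_seq)
    @settings(deadline=None, max_examples=25)
    def test_atoms_concat_loses_one_water(self, a, b):
        joined = np.array(atom_counts(a + b))
        parts = np.array(atom_counts(a)) + np.array(atom_counts(b))
        np.testing.assert_array_equal(parts - joined, [0, 2, 0, 1, 0])


class TestMolecularWeight:
    def test_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_peptide_bond_identity(self):
        assert molecular_weight("GG") == pytest.approx(
            2 * molecular_weight("G") - 18.0153, abs=1e-4
        )

    @given(protein_seq)
    @settings(deadline=None, max_examples=25)
    def test_matches_biopython_oracle(self, seq):
        assert molecular_weight(seq) == pytest.approx(
            ProteinAnalysis(seq).molecular_weight(), rel=1e-6
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            molecular_weight("")


class TestIsoelectricPoint:
    @given(protein_seq)
    @settings(deadline=None, max_examples=25)
    def test_net_charge_vanishes_at_pi(self, seq):
        pi = theoretical_pi(seq)
        assert 0 < pi < 14
        assert abs(net_charge(seq, pi)) < 1e-4

    def test_acidic_below_basic(self):
        assert theoretical_pi("DDDDDDDD") < theoretical_pi("KKKKKKKK")

    def test_alanine_regression(self):
        # frozen from the EMBOSS pKa set at first run (Nterm 8.6 / Cterm 3.6)
        assert theoretical_pi("A") == pytest.approx(6.1, abs=0.01)

    @given(protein_seq)
    @settings(deadline=None, max_examples=15)
    def test_close_to_biopython_scale(self, seq):
        # different pKa sets (EMBOSS vs Bjellqvist): loose sanity band only
        assert theoretical_pi(seq) == pytest.approx(
            ProteinAnalysis(seq).isoelectric_point(), abs=1.5
        )


class TestStabilityAndHydropathy:
    def test_dipeptide_closed_form(self):
        from Bio.SeqUtils import ProtParamData

        assert instability_index("GG") == pytest.approx(
            5 * ProtParamData.DIWV["G"]["G"]
        )

    def test_homopolymer_closed_form(self):
        from Bio.SeqUtils import ProtParamData

        n = 12
        assert instability_index("W" * n) == pytest.approx(
            10 * (n - 1) / n * ProtParamData.DIWV["W"]["W"]
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_biopython_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        assert instability_index(seq) == pytest.approx(
            ProteinAnalysis(seq).instability_index(), abs=1e-6
        )

    def test_length_one_errors(self):
        with pytest.raises(ValueError, match="length"):
            instability_index("A")

    @pytest.mark.parametrize(
        "seq, expected", [("AAAA", 100.0), ("VVVV", 290.0), ("GGGG", 0.0)]
    )
    def test_aliphatic_index(self, seq, expected):
        assert aliphatic_index(seq) == pytest.approx(expected)

    def test_gravy_table_values(self):
        assert gravy("A") == pytest.approx(1.8)
        assert gravy("AILV") == pytest.approx((1.8 + 4.5 + 3.8 + 4.2) / 4)

    @given(protein_seq)
    @settings(deadline=None, max_examples=25)
    def test_gravy_bounded_and_matches_biopython(self, seq):
        g = gravy(seq)
        assert -4.5 <= g <= 4.5
        assert g == pytest.approx(ProteinAnalysis(seq).gravy(), abs=1e-9)


class TestMotifCounters:
    def test_no_centers_all_zero(self):
        counts = ptm_motif_counts("GGGAGGLG")
        assert all(v == 0 for v in counts.values())

    def test_planted_sumo1_counted_once(self):
        seq = "GGGG" + "LKHE" + "GGGG"  # psi-K-x-E on a motif-free background
        counts = ptm_motif_counts(seq)
        assert counts["sumoylation_1"] == 1
        assert counts["sumoylation_2"] == 0
        assert counts["sumoylation_total"] == 1

    @given(protein_seq)
    @settings(deadline=None, max_examples=30)
    def test_totals_are_subcount_sums(self, seq):
        c = ptm_motif_counts(seq)
        assert c["nitrosylation_total"] == c["nitrosylation_a"] + c["nitrosylation_b"] + c["nitrosylation_c"]
        assert c["nitrotyrosine_total"] == c["nitrotyrosine_a"] + c["nitrotyrosine_b"] + c["nitrotyrosine_c"]
        assert c["sumoylation_total"] == c["sumoylation_1"] + c["sumoylation_2"] + c["sumoylation_3"]

    def test_context_classes(self):
        # C flanked by acidic only
        c = ptm_motif_counts("DDDCDDD")
        assert (c["nitrosylation_a"], c["nitrosylation_b"], c["nitrosylation_c"]) == (1, 0, 0)


class TestCoiledCoil:
    def test_short_sequence_scores_zero(self):
        assert coiled_coil_score("LEALEGK" * 3) == 0  # len 21 < window 28

    def test_ideal_heptad_scores_positive(self):
        assert coiled_coil_score("LEALEGK" * 8) > 0

    def test_polyglycine_scores_zero(self):
        assert coiled_coil_score("G" * 60) == 0


class TestExtraction:
    def test_vector_has_46_named_values(self, small_dataset):
        assert len(FEATURE_NAMES) == 46
        vec = extract_features(small_dataset.records[0])
        assert vec.shape == (46,)

    def test_deterministic(self, small_dataset):
        r = small_dataset.records[0]
        np.testing.assert_array_equal(extract_features(r), extract_features(r))

    def test_composition_block_sums_to_one(self, small_dataset):
        vec = extract_features(small_dataset.records[1])
        assert vec[:20].sum() == pytest.approx(1.0, abs=1e-12)

    @given(protein_seq.filter(lambda s: len(s) >= 4))
    @settings(deadline=None, max_examples=10)
    def test_permutation_sensitivity_split(self, seq):
        """Composition-type features are permutation-invariant; the
        order-sensitive block (instability, PTM, coiled-coil) need not be."""
        rng = np.random.default_rng(1)
        perm = "".join(rng.permutation(list(seq)))
        v1, v2 = extract_features(seq), extract_features(perm)
        invariant = (
            list(range(20))  # composition
            + [FEATURE_NAMES.index(n) for n in (
                "length", "n_negative", "n_positive", "molecular_weight",
                "theoretical_pi", "n_carbon", "n_hydrogen", "n_nitrogen",
                "n_oxygen", "n_sulphur", "aliphatic_index", "gravy",
            )]
        )
        np.testing.assert_allclose(v1[invariant], v2[invariant], atol=1e-9)

    def test_order_sensitive_features_can_change(self):
        # same composition, different dipeptides and motifs
        a = "LKHE" + "W" * 10
        b = "EHKL" + "W" * 10
        ii = FEATURE_NAMES.index("instability_index")
        s1 = FEATURE_NAMES.index("sumoylation_1")
        va, vb = extract_features(a), extract_features(b)
        assert va[s1] != vb[s1]
        assert va[ii] != vb[ii]

    def test_table_and_featurizer_agree(self, small_dataset):
        recs = small_dataset.records[:5]
        table = extract_feature_table(recs)
        assert table.shape == (5, 46)
        ft = ProteinFeaturizer(policy="strict").fit(recs)
        np.testing.assert_allclose(ft.transform(recs), table.values)
        assert list(ft.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_schema_hash_changes_with_config(self):
        from sielunet.features import FeatureSchema, CoiledCoilConfig

        other = FeatureSchema(coiled_coil=CoiledCoilConfig(min_fraction=1.0))
        assert other.schema_hash() != DEFAULT_SCHEMA.schema_hash()
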