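"""Markov model estimation, entropy, repertoire similarity, composition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from braycall import (
    COARSE_ALPHABET,
    VARIANT_ALPHABET,
    ProbabilityVector,
    Repertoire,
    TransitionMatrix,
    build_repertoire,
    composition,
    composition_from_counts,
    element_probabilities,
    emission_rate,
    estimate_fomm,
    generate_fomm_chain,
    load_survey_inventory,
    repertoire_from_sequences,
    shannon_entropy,
    sorensen_dice,
)

from conftest import make_seq


class TestFomm:
    def test_single_self_transition_sequence(self):
        tm = estimate_fomm([["GU", "GU", "GU"]], alphabet=("GU", "GR", "SQ"))
        assert tm.probability("GU", "GU") == 1.0

    def test_symmetric_counts_split_evenly(self):
        tm = estimate_fomm([["GU", "GR"], ["GU", "SQ"]],
                           alphabet=("GU", "GR", "SQ"))
        assert tm.probability("GU", "GR") == pytest.approx(0.5)
        assert tm.probability("GU", "SQ") == pytest.approx(0.5)

    def test_no_transition_across_sequence_boundaries(self):
        # GR ends sequence 1 and GU starts sequence 2: no GR->GU count
        tm = estimate_fomm([["GU", "GR"], ["GU", "SQ"]],
                           alphabet=("GU", "GR", "SQ"))
        assert tm.counts.sum() == 2

    def test_rows_with_observations_are_stochastic(self):
        seqs = [["GU", "GR", "GU", "SQ"], ["SQ", "SQ", "GU"]]
        tm = estimate_fomm(seqs, alphabet=("GU", "GR", "SQ"))
        sums = tm.probabilities[tm.defined_rows].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_undefined_rows_flagged_not_nan(self):
        tm = estimate_fomm([["GU", "GU"]], alphabet=("GU", "GR", "SQ"))
        assert not tm.defined_rows[1]
        assert not np.isnan(tm.probabilities).any()
        with pytest.raises(ValueError, match="no observed transitions"):
            tm.probability("GR", "GU")

    def test_pseudocount_smoothing_defines_every_row(self):
        tm = estimate_fomm([["GU", "GU"]], alphabet=("GU", "GR", "SQ"),
                           pseudocount=1.0)
        assert tm.defined_rows.all()
        assert tm.probability("GU", "GU") == pytest.approx(2 / 4)

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            estimate_fomm([["GU", "XX"]], alphabet=("GU", "GR"))

    def test_bray_sequences_symbolised_at_both_levels(self):
        seq = make_seq(["GU3", "GU1", "GU3", "GU1"])
        coarse = estimate_fomm([seq], alphabet=COARSE_ALPHABET, level="coarse")
        assert coarse.probability("GU", "GU") == 1.0
        variant = estimate_fomm([seq], alphabet=VARIANT_ALPHABET,
                                level="variant")
        assert variant.probability("GU3", "GU1") == 1.0
        assert variant.probability("GU1", "GU3") == 1.0

    def test_long_chain_recovers_generating_matrix(self):
        # both states are visited often, so every row is well estimated
        truth = TransitionMatrix(
            states=("GU", "SQ"),
            counts=np.array([[70, 30], [40, 60]]),
        )
        chain = generate_fomm_chain(truth, n_steps=50_001, initial="GU",
                                    seed=123)
        est = estimate_fomm([chain], alphabet=truth.states)
        assert np.abs(est.probabilities - truth.probabilities).max() < 0.01

    def test_edge_list_export(self):
        tm = estimate_fomm([["GU", "GR", "GU"]], alphabet=("GU", "GR"))
        edges = tm.to_edge_list()
        assert set(zip(edges["source"], edges["target"])) == {
            ("GU", "GR"), ("GR", "GU"),
        }
        assert (edges["probability"] == 1.0).all()


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [((0.5, 0.5), 1.0), ((1.0,), 0.0), ((0.5, 0.25, 0.25), 1.5)],
    )
    def test_closed_form_cases(self, p, expected):
        pv = ProbabilityVector(labels=tuple(f"s{i}" for i in range(len(p))), p=p)
        assert shannon_entropy(pv) == pytest.approx(expected)

    def test_non_normalised_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ProbabilityVector(labels=("a", "b"), p=(0.7, 0.7))

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    def test_entropy_within_bounds(self, weights):
        total = sum(weights)
        p = tuple(w / total for w in weights)
        pv = ProbabilityVector(labels=tuple(map(str, range(len(p)))), p=p)
        h = shannon_entropy(pv)
        assert -1e-9 <= h <= math.log2(len(p)) + 1e-9

    def test_element_probabilities_from_sequences(self):
        seqs = [make_seq(["GU1", "GU1", "SQ", "GU1"])]
        pv = element_probabilities(seqs, level="coarse")
        assert pv.labels == ("GU", "SQ")
        assert pv.p == (0.75, 0.25)
        assert shannon_entropy(pv) == pytest.approx(0.811278, abs=1e-5)


class TestSorensenDice:
    def test_identical_repertoires_give_one(self):
        rep = build_repertoire("a", {1, 2, 10}, {"GU1", "SQ"})
        assert sorensen_dice(rep, rep) == 1.0

    def test_disjoint_repertoires_give_zero(self):
        a = build_repertoire("a", {1}, {"GU1"})
        b = build_repertoire("b", {10}, {"SQ"})
        assert sorensen_dice(a, b) == 0.0

    def test_two_site_survey_value_convention_a(self):
        """Variant-level enumeration: 2*(2+2)/(23+4)."""
        inv = load_survey_inventory()
        tyr, sic = inv["sites"]["tyrrhenian"], inv["sites"]["sicily"]
        rep_t = build_repertoire("tyrrhenian", tyr["typologies_present"],
                                 tyr["element_classes_present"])
        rep_s = build_repertoire("sicily", sic["typologies_present"],
                                 sic["element_classes_present"])
        assert rep_t.size == 23
        assert rep_s.size == 4
        assert sorensen_dice(rep_t, rep_s) == pytest.approx(0.296, abs=5e-4)

    def test_two_site_survey_value_convention_b(self):
        """Coarse+variant enumeration for the variant-resolved site: 8/29."""
        inv = load_survey_inventory()
        tyr, sic = inv["sites"]["tyrrhenian"], inv["sites"]["sicily"]
        rep_t = build_repertoire("tyrrhenian", tyr["typologies_present"],
                                 tyr["element_classes_present"],
                                 element_level="both")
        rep_s = build_repertoire("sicily", sic["typologies_present"],
                                 sic["element_classes_present"],
                                 element_level="coarse")
        assert rep_t.size == 25
        assert rep_s.size == 4
        assert sorensen_dice(rep_t, rep_s) == pytest.approx(0.276, abs=5e-4)

    def test_empty_pair_is_undefined(self):
        empty = Repertoire("x", frozenset(), frozenset())
        with pytest.raises(ValueError, match="undefined|empty"):
            sorensen_dice(empty, empty)

    @given(
        st.sets(st.integers(1, 13)), st.sets(st.integers(1, 13)),
        st.sets(st.sampled_from(VARIANT_ALPHABET)),
        st.sets(st.sampled_from(VARIANT_ALPHABET)),
    )
    def test_symmetry_and_range(self, ta, tb, ea, eb):
        a = build_repertoire("a", ta, ea)
        b = build_repertoire("b", tb, eb)
        if a.size + b.size == 0:
            return
        s = sorensen_dice(a, b)
        assert s == sorensen_dice(b, a)
        assert 0.0 <= s <= 1.0

    def test_repertoire_from_sequences(self, patterns):
        from braycall import assign_typology

        seqs = [make_seq(["GU1"] * 4), make_seq(["SQ"] * 3, begin=500.0)]
        for s in seqs:
            assign_typology(s, patterns)
        rep = repertoire_from_sequences(seqs, site="x")
        assert rep.sequence_typologies == frozenset({1, 10})
        assert rep.element_classes == frozenset({"GU1", "SQ"})


class TestComposition:
    def test_single_class_sequence(self):
        df = composition([make_seq(["GU1"] * 3)], level="coarse_type")
        assert df.loc[0, "label"] == "GU"
        assert df.loc[0, "proportion"] == 1.0

    def test_survey_element_counts_give_published_gulp_share(self):
        inv = load_survey_inventory()
        totals: dict[str, int] = {}
        for counts in inv["element_counts"].values():
            for cls, n in counts.items():
                key = "GU" if cls.startswith("GU") else (
                    "GR" if cls.startswith("GR") else cls)
                totals[key] = totals.get(key, 0) + n
        df = composition_from_counts(totals)
        gu = df.set_index("label").loc["GU"]
        assert gu["count"] == 3217
        assert df["count"].sum() == 4031
        assert gu["proportion"] == pytest.approx(3217 / 4031)
        assert round(100 * gu["proportion"]) == 80

    def test_typology_shares_match_published_tyrrhenian_counts(self):
        df = composition_from_counts({1: 340, 2: 78, "rest": 637 - 340 - 78})
        shares = df.set_index("label")["proportion"]
        assert shares[1] == pytest.approx(0.534, abs=5e-4)
        assert shares[2] == pytest.approx(0.122, abs=5e-4)

    def test_proportions_sum_to_one_at_every_level(self, patterns):
        from braycall import assign_typology

        seqs = [make_seq(["GU3", "GU1"] * 2), make_seq(["SQ"] * 3, begin=500.0)]
        for s in seqs:
            assign_typology(s, patterns)
        for level in ("coarse_type", "element_class", "typology"):
            assert composition(seqs, level=level)["proportion"].sum() == \
                pytest.approx(1.0)


class TestEmissionRate:
    def test_published_site_rates(self):
        assert round(emission_rate(637, 115.3 * 60), 2) == 0.09
        assert round(emission_rate(7, 3.8 * 60), 2) == 0.03

    def test_zero_sequences(self):
        assert emission_rate(0, 100.0) == 0.0

    def test_nonpositive_minutes_rejected(self):
        with pytest.raises(ValueError):
            emission_rate(5, 0.0)
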