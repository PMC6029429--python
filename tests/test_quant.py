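"""Probabilistic engine: top-event probability, importance, mitigation."""

import numpy as np
import pytest

import foodfta as f
from foodfta.fixtures import generate_random_tree, random_probabilities
from foodfta.quant import RepeatedEventsError, has_repeated_events
from tests.conftest import brute_top_probability


@pytest.fixture
def half():
    return f.ProbabilityAssignment({"a": 0.5, "b": 0.5})


class TestTopEventProbability:
    def test_or_closed_form(self, minimal_or, half):
        res = f.top_event_probability(minimal_or, half, method="bottom_up")
        assert res.estimate == pytest.approx(0.75)

    def test_and_closed_form(self, and_only, half):
        res = f.top_event_probability(and_only, half, method="bottom_up")
        assert res.estimate == pytest.approx(0.25)

    def test_repeated_event_needs_enumeration(self, shared_tree):
        """A shared basic feeding both branches of an AND: exact answer is
        p(s) when the other basics are certain, where the tree closed form
        would wrongly square it."""
        probs = f.ProbabilityAssignment({"s": 0.5, "x": 0.0, "y": 0.0})
        exact = f.top_event_probability(shared_tree, probs, method="enumeration")
        assert exact.estimate == pytest.approx(0.5)
        with pytest.raises(RepeatedEventsError):
            f.top_event_probability(shared_tree, probs, method="bottom_up")
        auto = f.top_event_probability(shared_tree, probs, method="auto")
        assert auto.method == "enumeration"
        assert auto.estimate == pytest.approx(0.5)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(f.FaultTreeError):
            f.ProbabilityAssignment({"a": 1.2})

    def test_missing_probability_rejected(self, minimal_or):
        with pytest.raises(f.FaultTreeError):
            f.top_event_probability(minimal_or, f.ProbabilityAssignment({"a": 0.5}))

    @pytest.mark.parametrize("seed", range(25))
    def test_methods_agree_and_match_oracle(self, seed):
        """bottom_up (when valid) and enumeration agree to 1e-12 and both
        match the independent truth-table-weighted oracle."""
        tree = generate_random_tree(n_basic=2 + seed % 7, max_depth=3, seed=seed)
        probs = random_probabilities(tree, seed=seed)
        pa = f.ProbabilityAssignment(probs)
        enum = f.top_event_probability(tree, pa, method="enumeration").estimate
        oracle = brute_top_probability(tree, probs)
        assert enum == pytest.approx(oracle, abs=1e-12)
        if not has_repeated_events(tree):
            bu = f.top_event_probability(tree, pa, method="bottom_up").estimate
            assert bu == pytest.approx(enum, abs=1e-12)

    def test_monte_carlo_reproducible_and_close(self, textbook):
        pa = f.ProbabilityAssignment({"a": 0.3, "b": 0.6, "c": 0.5})
        mc1 = f.top_event_probability(textbook, pa, method="monte_carlo",
                                      n_samples=50_000, seed=11)
        mc2 = f.top_event_probability(textbook, pa, method="monte_carlo",
                                      n_samples=50_000, seed=11)
        assert mc1.estimate == mc2.estimate
        exact = f.top_event_probability(textbook, pa, method="enumeration").estimate
        assert abs(mc1.estimate - exact) < 4 * mc1.stderr

    def test_degenerate_probs_reduce_to_state_evaluation(self, food_tree):
        rng = np.random.default_rng(5)
        basics = sorted(e.id for e in food_tree.basic_events())
        states = {b: bool(rng.integers(2)) for b in basics}
        pa = f.ProbabilityAssignment({b: float(v) for b, v in states.items()})
        expected = f.evaluate_states(food_tree, f.StateAssignment(states)).top_failed
        # degenerate probabilities make even Monte Carlo exact
        res = f.top_event_probability(food_tree, pa, method="monte_carlo",
                                      n_samples=64, seed=0)
        assert res.estimate == pytest.approx(float(expected), abs=1e-12)

    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_coherence_bounds(self, seed):
        """max single-cut probability <= P(top) <= sum of cut probabilities."""
        tree = generate_random_tree(n_basic=6, max_depth=3, seed=seed)
        probs = random_probabilities(tree, seed=seed)
        pa = f.ProbabilityAssignment(probs)
        p_top = f.top_event_probability(tree, pa, method="enumeration").estimate
        cut_probs = [np.prod([probs[b] for b in c.events])
                     for c in f.minimal_cut_sets(tree)]
        assert max(cut_probs) <= p_top + 1e-12
        assert p_top <= sum(cut_probs) + 1e-12


class TestBirnbaum:
    def test_or_closed_form(self, minimal_or, half):
        df = f.birnbaum_importance(minimal_or, half).set_index("event_id")
        assert df.loc["a", "birnbaum"] == pytest.approx(0.5)
        assert df.loc["b", "birnbaum"] == pytest.approx(0.5)

    def test_and_closed_form(self, and_only, half):
        df = f.birnbaum_importance(and_only, half).set_index("event_id")
        assert df.loc["a", "birnbaum"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_difference_on_oracle(self, seed):
        tree = generate_random_tree(n_basic=2 + seed % 6, max_depth=3, seed=seed)
        probs = random_probabilities(tree, seed=seed)
        df = f.birnbaum_importance(
            tree, f.ProbabilityAssignment(probs), method="enumeration"
        ).set_index("event_id")
        for b in probs:
            hi = brute_top_probability(tree, {**probs, b: 1.0})
            lo = brute_top_probability(tree, {**probs, b: 0.0})
            assert df.loc[b, "birnbaum"] == pytest.approx(hi - lo, abs=1e-10)
            assert -1e-12 <= df.loc[b, "birnbaum"] <= 1 + 1e-12  # monotone tree

    def test_sorted_descending_with_id_tiebreak(self, minimal_or, half):
        df = f.birnbaum_importance(minimal_or, half)
        assert list(df.event_id) == ["a", "b"]  # equal importance, id order
        assert list(df["rank"]) == [1, 2]


class TestFussellVesely:
    def test_or_closed_form(self, minimal_or, half):
        df = f.fussell_vesely_importance(minimal_or, half).set_index("event_id")
        assert df.loc["a", "fussell_vesely"] == pytest.approx(0.5 / 0.75)

    def test_single_basic_tree_is_one(self):
        tree = f.parse_tree("""
id: single
subtrees: [{id: main, top_event: top}]
events:
  - {id: top, label: T, kind: top, subtree: main, gate: {type: or, inputs: [a]}}
  - {id: a, label: A, kind: basic, subtree: main}
""")
        df = f.fussell_vesely_importance(tree, f.ProbabilityAssignment({"a": 0.37}))
        assert df.fussell_vesely.iloc[0] == pytest.approx(1.0)

    def test_zero_top_probability_is_undefined(self, minimal_or):
        df = f.fussell_vesely_importance(
            minimal_or, f.ProbabilityAssignment({"a": 0.0, "b": 0.0}))
        assert df.fussell_vesely.isna().all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        """FV equals P(union of cut sets containing b all fail)/P(top),
        computed independently from the truth table."""
        tree = generate_random_tree(n_basic=2 + seed % 6, max_depth=3, seed=seed)
        probs = random_probabilities(tree, seed=seed)
        cuts = [set(c.events) for c in f.minimal_cut_sets(tree)]
        p_top = brute_top_probability(tree, probs)
        df = f.fussell_vesely_importance(
            tree, f.ProbabilityAssignment(probs), method="enumeration"
        ).set_index("event_id")
        from itertools import product

        basics = sorted(probs)
        for b in probs:
            mine = [c for c in cuts if b in c]
            num = 0.0
            for bits in product([False, True], repeat=len(basics)):
                states = dict(zip(basics, bits))
                if any(all(states[x] for x in c) for c in mine):
                    w = 1.0
                    for x, bit in states.items():
                        w *= probs[x] if bit else 1.0 - probs[x]
                    num += w
            expected = num / p_top if p_top > 0 else float("nan")
            got = df.loc[b, "fussell_vesely"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)
                assert 0.0 <= got <= 1.0


class TestMitigation:
    def test_identity_intervention_is_zero_delta(self, textbook):
        pa = f.ProbabilityAssignment({"a": 0.2, "b": 0.4, "c": 0.6})
        res = f.mitigation_delta(textbook, pa, {"a": 0.2})
        assert res["delta"] == pytest.approx(0.0)

    def test_removing_an_or_input(self, minimal_or, half):
        res = f.mitigation_delta(minimal_or, half, {"a": 0.0})
        assert res["baseline"] == pytest.approx(0.75)
        assert res["mitigated"] == pytest.approx(0.5)
        assert res["delta"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_lowering_any_probability_never_hurts(self, seed):
        tree = generate_random_tree(n_basic=2 + seed % 6, max_depth=3, seed=seed)
        probs = random_probabilities(tree, seed=seed)
        pa = f.ProbabilityAssignment(probs)
        rng = np.random.default_rng(seed)
        target = rng.choice(sorted(probs))
        res = f.mitigation_delta(tree, pa, {target: probs[target] * 0.5},
                                 method="enumeration")
        assert res["delta"] >= -1e-12
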