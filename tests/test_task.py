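"""Transitive-inference protocol: pair construction, scheduling, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sotmr import synthetic as syn
from sotmr.task import (
    ExitState,
    Hierarchy,
    PairTrial,
    build_late_test_pairs,
    build_premise_pairs,
    build_sound_image_test,
    degree_of_separation,
    schedule_learning_block,
    schedule_test_block,
    score_behaviour,
    update_exit_criterion,
)


@pytest.fixture
def h():
    return Hierarchy("Up", "faces", tuple("ABCDEF"))


class TestPairs:
    def test_premise_pairs_are_the_five_adjacent_pairs(self, h):
        assert build_premise_pairs(h) == [("A", "B"), ("B", "C"), ("C", "D"),
                                          ("D", "E"), ("E", "F")]

    def test_premise_pairs_follow_given_order_not_lexical(self):
        rev = Hierarchy("Up", "faces", tuple("FEDCBA"))
        assert build_premise_pairs(rev)[0] == ("F", "E")

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError):
            Hierarchy("Up", "faces", tuple("ABCDE"))
        with pytest.raises(ValueError):
            Hierarchy("Up", "faces", tuple("AABCDE"))

    @pytest.mark.parametrize("pair,expected", [
        (("B", "D"), 1),
        (("B", "E"), 2),
        (("A", "B"), 0),
        (("A", "F"), 4),
        (("D", "B"), 1),          # symmetric in order
    ])
    def test_degree_of_separation(self, h, pair, expected):
        assert degree_of_separation(pair, h) == expected

    def test_degree_unknown_item_rejected(self, h):
        with pytest.raises(KeyError):
            degree_of_separation(("A", "Z"), h)

    def test_late_test_composition(self, h):
        trials = build_late_test_pairs(h)
        assert len(trials) == 9
        by_class = {}
        for t in trials:
            by_class.setdefault(t.pair_class, []).append(t.pair)
        assert set(by_class["inference_deg1"]) == {("B", "D"), ("C", "E")}
        assert by_class["inference_deg2"] == [("B", "E")]
        assert by_class["anchor"] == [("A", "F")]
        # forced counts for a 6-item hierarchy: deg2 instances are half of deg1
        assert len(by_class["premise"]) == 5
        assert len(by_class["inference_deg2"]) * 2 == len(by_class["inference_deg1"])

    def test_late_test_premise_subset_matches_premise_builder(self, h):
        late_premise = [t.pair for t in build_late_test_pairs(h) if t.pair_class == "premise"]
        assert late_premise == build_premise_pairs(h)

    def test_correct_item_is_higher_ranked(self, h):
        for t in build_late_test_pairs(h):
            assert h.rank(t.correct) < h.rank(t.pair[0] if t.correct != t.pair[0] else t.pair[1])


class TestLearningBlock:
    @pytest.mark.parametrize("seed", range(8))
    def test_block_structure(self, hierarchies, seed):
        block = schedule_learning_block(hierarchies, np.random.default_rng(seed))
        assert len(block) == 30
        for hier in hierarchies:
            sub = [t for t in block if t.hierarchy == hier.category]
            assert len(sub) == 10
            # each premise pair exactly twice, both orientations
            counts = {}
            for t in sub:
                counts[t.pair] = counts.get(t.pair, 0) + 1
                assert t.position_order in (t.pair, t.pair[::-1])
            assert all(v == 2 for v in counts.values())
            orientations = {(t.pair, t.position_order) for t in sub}
            assert len(orientations) == 10
            # no consecutive pairs share an item within the sub-block
            for a, b in zip(sub, sub[1:]):
                assert not (set(a.pair) & set(b.pair))

    def test_hierarchies_are_contiguous_in_category_order(self, hierarchies):
        order = ["objects", "faces", "scenes"]
        block = schedule_learning_block(hierarchies, np.random.default_rng(0),
                                        category_order=order)
        cats = [t.hierarchy for t in block]
        assert cats == ["objects"] * 10 + ["faces"] * 10 + ["scenes"] * 10

    def test_determinism(self, hierarchies):
        b1 = schedule_learning_block(hierarchies, np.random.default_rng(5))
        b2 = schedule_learning_block(hierarchies, np.random.default_rng(5))
        assert b1 == b2

    @pytest.mark.parametrize("seed", range(6))
    def test_late_test_block_respects_constraint(self, hierarchies, seed):
        block = schedule_test_block(hierarchies, np.random.default_rng(seed), phase="late")
        for hier in hierarchies:
            sub = [t for t in block if t.hierarchy == hier.category]
            for a, b in zip(sub, sub[1:]):
                assert not (set(a.pair) & set(b.pair))


class TestExitCriterion:
    def run_blocks(self, accuracies, **kwargs):
        state = ExitState(categories=("faces",), **kwargs)
        for acc in accuracies:
            state = update_exit_criterion(state, {"faces": acc})
        return state

    def test_criterion_met_after_three_good_blocks(self):
        state = self.run_blocks([70, 70, 70])
        assert state.feedback_on["faces"] is False
        assert state.done

    def test_one_of_last_three_not_enough(self):
        state = self.run_blocks([70, 60, 60])
        assert state.feedback_on["faces"] is True

    def test_strictly_over_threshold(self):
        # exactly 66% never counts under the strict reading
        state = self.run_blocks([66.0, 66.0, 66.0])
        assert state.feedback_on["faces"] is True

    def test_no_evaluation_before_minimum_blocks(self):
        state = self.run_blocks([90, 90])
        assert state.feedback_on["faces"] is True
        assert not state.done

    def test_never_learning_agent_stops_at_ten_blocks(self):
        state = ExitState(categories=("faces",))
        n = 0
        while not state.done:
            state = update_exit_criterion(state, {"faces": 50.0})
            n += 1
        assert n == 10
        with pytest.raises(ValueError):
            update_exit_criterion(state, {"faces": 50.0})

    def test_feedback_never_turns_back_on(self):
        state = self.run_blocks([70, 70, 70, 10, 10, 10])
        assert state.feedback_on["faces"] is False

    def test_inconsistent_state_rejected(self):
        state = ExitState(categories=("faces",))
        state.history["faces"] = [50.0]     # out of sync with blocks_completed
        with pytest.raises(ValueError):
            update_exit_criterion(state, {"faces": 70.0})

    def test_out_of_range_accuracy_rejected(self):
        state = ExitState(categories=("faces",))
        with pytest.raises(ValueError):
            update_exit_criterion(state, {"faces": 120.0})


class TestSoundImageTest:
    def test_lure_and_count_structure(self, hierarchies, rng):
        trials = build_sound_image_test(hierarchies, rng)
        category_of = {item: h.category for h in hierarchies for item in h.items}
        assert len(trials) == 2 * 18 * 3
        per_block_sound = {}
        for t in trials:
            assert t.target in t.images
            distractors = [x for x in t.images if x != t.target]
            assert len(distractors) == 2
            assert any(category_of[d] == category_of[t.target] for d in distractors)
            per_block_sound[(t.block, t.sound)] = per_block_sound.get((t.block, t.sound), 0) + 1
        assert set(per_block_sound.values()) == {3}

    def test_determinism(self, hierarchies):
        t1 = build_sound_image_test(hierarchies, np.random.default_rng(3))
        t2 = build_sound_image_test(hierarchies, np.random.default_rng(3))
        assert t1 == t2


class TestScoreBehaviour:
    def table(self, corrects, pair_class="premise"):
        return pd.DataFrame({
            "subject": 0, "condition": "Up", "session": 1,
            "pair_class": pair_class, "correct": corrects,
        })

    def test_all_correct_gives_100(self):
        out = score_behaviour(self.table([1, 1, 1, 1]))
        assert out["accuracy"].iloc[0] == 100.0
        assert out["n"].iloc[0] == 4

    def test_alternating_gives_50(self):
        out = score_behaviour(self.table([1, 0, 1, 0]))
        assert out["accuracy"].iloc[0] == 50.0

    def test_empty_cells_absent_not_zero(self):
        out = score_behaviour(self.table([1, 1]))
        assert len(out[out["pair_class"] == "deg2"]) == 0

    def test_inference_rollup(self):
        df = pd.concat([self.table([1, 1], "deg1"), self.table([0, 0], "deg2")])
        out = score_behaviour(df)
        roll = out[out["pair_class"] == "inference"]
        assert len(roll) == 1
        assert roll["accuracy"].iloc[0] == 50.0
        assert roll["n"].iloc[0] == 4

    def test_unknown_pair_rejected(self):
        df = self.table([1]).assign(pair=[("A", "Z")], hierarchy="faces")
        with pytest.raises(ValueError, match="unknown pair"):
            score_behaviour(df, valid_pairs={"faces": {("A", "B")}})

    def test_round_trip_with_generator(self):
        acc = {("Up", 2, "deg2"): 0.7, ("Control", 2, "deg2"): 0.55}
        config = syn.BehaviourSimConfig(n_subjects=60, true_accuracy=acc,
                                        subject_effect_sd=0.2, trials_per_cell=20, seed=4)
        out = score_behaviour(syn.generate_behaviour(config))
        cell = out.groupby("condition")["accuracy"].mean()
        assert cell["Up"] == pytest.approx(70.0, abs=4.0)
        assert cell["Control"] == pytest.approx(55.0, abs=4.0)


class TestPairTrialInvariants:
    def test_confidence_only_in_late_test(self):
        with pytest.raises(ValueError):
            PairTrial(pair=("A", "B"), correct="A", pair_class="premise",
                      phase="learning", hierarchy="faces", confidence=1)

    def test_feedback_only_in_learning(self):
        with pytest.raises(ValueError):
            PairTrial(pair=("A", "B"), correct="A", pair_class="premise",
                      phase="late", hierarchy="faces", feedback=True)

    def test_correct_must_be_member(self):
        with pytest.raises(ValueError):
            PairTrial(pair=("A", "B"), correct="C", pair_class="premise",
                      phase="learning", hierarchy="faces")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.permutations(list("ABCDEF")))
def test_degree_plus_two_is_rank_distance_for_any_ordering(items):
    h = Hierarchy("Up", "faces", tuple(items))
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            pair = (h.items[i], h.items[j])
            assert degree_of_separation(pair, h) == abs(i - j) - 1
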