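"""Per-fish weights, side probabilities and sequence likelihoods."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import patchhop as ph
from patchhop.eventlog import flip_lr
from patchhop.models import DecisionState, list_models, get_model

from conftest import random_valid_trial


STATE_SPLIT = DecisionState(1, 3)  # delta for a left fish: 3 - 0 = 3
STATE_LAST_L2R = DecisionState(2, 2, "L2R")


class TestPerFishWeight:
    @pytest.mark.parametrize(
        "model,params,side,state,expected",
        [
            ("M0", {}, "L", STATE_SPLIT, 1.0),
            ("M0", {}, "R", STATE_LAST_L2R, 1.0),
            ("S1", {"gamma": 3.0}, "L", STATE_SPLIT, 3.0),
            ("S1", {"gamma": 3.0}, "R", STATE_SPLIT, 1.0 / 3.0),
            ("S1", {"gamma": 3.0}, "L", DecisionState(3, 2), 1.0),  # delta 0
            ("S2", {"beta": 0.5}, "L", STATE_SPLIT, 2.5),
            ("S3", {"g": 2.0}, "L", STATE_SPLIT, 8.0),
            ("D1", {"alpha": 2.0}, "L", STATE_LAST_L2R, 2.0),
            ("D1", {"alpha": 2.0}, "R", STATE_LAST_L2R, 1.0),
            ("C1", {"gamma": 3.0, "alpha": 2.0}, "L", DecisionState(1, 3, "L2R"), 6.0),
        ],
    )
    def test_hand_evaluations(self, model, params, side, state, expected):
        w = ph.per_fish_weight(model, params, side, state)
        assert w == pytest.approx(expected, rel=1e-12)

    def test_s4_saturates_for_steep_quorum(self):
        # 1 / (1 + a s^-delta) -> 1 as s -> inf when delta > 0
        w = ph.per_fish_weight("S4", {"a": 1.0, "s": 1e6}, "L", STATE_SPLIT)
        assert w == pytest.approx(1.0, abs=1e-5)

    def test_s2_floor_keeps_weight_positive(self):
        w = ph.per_fish_weight("S2", {"beta": -5.0}, "L", STATE_SPLIT)
        assert w == pytest.approx(1e-9)

    def test_d2_counts_net_recent_moves(self):
        state = DecisionState(
            2, 2, "L2R", recent_moves=(("L2R", 1.0), ("L2R", 2.0), ("R2L", 3.0))
        )
        assert ph.per_fish_weight("D2", {"alpha": 2.0}, "L", state) == pytest.approx(2.0)
        assert ph.per_fish_weight("D2", {"alpha": 2.0}, "R", state) == pytest.approx(0.5)
        # moves older than the window are ignored
        stale = DecisionState(2, 2, "L2R", recent_moves=(("L2R", 5.0),))
        assert ph.per_fish_weight("D2", {"alpha": 2.0}, "L", stale) == 1.0

    def test_refuge_bias_multiplies_left_side_only(self):
        wl = ph.per_fish_weight("M0", {"b": 3.0}, "L", STATE_LAST_L2R,
                                environment_mode="asymmetric")
        wr = ph.per_fish_weight("M0", {"b": 3.0}, "R", STATE_LAST_L2R,
                                environment_mode="asymmetric")
        assert (wl, wr) == (3.0, 1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ph.per_fish_weight("S1", {"gamma": -1.0}, "L", STATE_SPLIT)
        with pytest.raises(ValueError, match="missing"):
            ph.per_fish_weight("D1", {}, "L", STATE_SPLIT)


class TestSideProbability:
    def test_null_model_is_proportional_to_occupancy(self):
        assert ph.side_probability("M0", {}, DecisionState(2, 1)) == pytest.approx(2 / 3)

    def test_follow_weight_balances_minority_side(self):
        p = ph.side_probability("D1", {"alpha": 2.0}, DecisionState(1, 2, "L2R"))
        assert p == pytest.approx(0.5)

    def test_empty_side_has_zero_probability(self):
        assert ph.side_probability("S1", {"gamma": 2.0}, DecisionState(0, 3)) == 0.0
        assert ph.side_probability("S1", {"gamma": 2.0}, DecisionState(3, 0)) == 1.0

    @pytest.mark.parametrize("model,params", [
        ("S1", {"gamma": 7.3}),
        ("S2", {"beta": -2.1}),
        ("S3", {"g": 0.2}),
        ("S4", {"a": 2.0, "s": 1.4}),
        ("D1", {"alpha": 11.0}),
        ("D2", {"alpha": 0.3}),
        ("C1", {"gamma": 2.0, "alpha": 5.0}),
    ])
    def test_left_and_right_probabilities_are_complementary(self, model, params):
        rng = np.random.default_rng(0)
        for _ in range(25):
            g = int(rng.integers(2, 7))
            nl = int(rng.integers(1, g))
            last = [None, "L2R", "R2L"][int(rng.integers(3))]
            recent = tuple(
                ("L2R" if rng.random() < 0.5 else "R2L", float(rng.uniform(0, 3)))
                for _ in range(int(rng.integers(0, 4)))
            )
            state = DecisionState(nl, g - nl, last, recent)
            p_l = ph.side_probability(model, params, state)
            mirror = DecisionState(
                g - nl,
                nl,
                None if last is None else ("R2L" if last == "L2R" else "L2R"),
                tuple(("R2L" if d == "L2R" else "L2R", a) for d, a in recent),
            )
            # the mirrored state's left probability is the original P(R)
            p_r = ph.side_probability(model, params, mirror)
            assert p_l + p_r == pytest.approx(1.0, abs=1e-12)

    def test_probability_monotone_in_alpha_and_gamma(self):
        alphas = np.linspace(0.5, 8.0, 12)
        probs = [
            ph.side_probability("D1", {"alpha": a}, DecisionState(1, 3, "L2R"))
            for a in alphas
        ]
        assert np.all(np.diff(probs) >= 0)
        gammas = np.linspace(0.5, 8.0, 12)  # L is the minority side
        probs = [
            ph.side_probability("S1", {"gamma": g}, DecisionState(1, 3))
            for g in gammas
        ]
        assert np.all(np.diff(probs) >= 0)


class TestLogLikelihood:
    def test_hand_product_of_two_null_decisions(self, hand_trial):
        ll = ph.log_likelihood("M0", {}, hand_trial)
        assert ll == pytest.approx(np.log2(2 / 3) + np.log2(2 / 3))

    def test_empty_dataset_has_zero_loglik(self):
        assert ph.log_likelihood("M0", {}, ph.Dataset()) == 0.0

    @pytest.mark.parametrize("model,params", [
        ("S1", {"gamma": 1.0}),
        ("S2", {"beta": 0.0}),
        ("S3", {"g": 1.0}),
        ("D1", {"alpha": 1.0}),
        ("D2", {"alpha": 1.0}),
        ("C1", {"gamma": 1.0, "alpha": 1.0}),
    ])
    def test_unit_parameters_reduce_to_null_model(self, model, params, d1_dataset):
        assert ph.log_likelihood(model, params, d1_dataset) == ph.log_likelihood(
            "M0", {}, d1_dataset
        )

    @pytest.mark.parametrize("model,params", [
        ("M0", {}),
        ("S1", {"gamma": 3.0}),
        ("S2", {"beta": 0.7}),
        ("S4", {"a": 1.5, "s": 1.3}),
        ("D1", {"alpha": 4.0}),
        ("D2", {"alpha": 2.0}),
    ])
    def test_mirror_symmetry_of_the_likelihood(self, model, params, d1_dataset):
        ll = ph.log_likelihood(model, params, d1_dataset)
        ll_flip = ph.log_likelihood(model, params, flip_lr(d1_dataset))
        assert ll_flip == pytest.approx(ll, abs=1e-9)

    def test_uninformative_points_contribute_nothing(self):
        meta = ph.TrialMetadata("u", 3, frozenset({"a", "b"}))
        events = (
            ph.CrossingEvent("u", 1.0, "c", "R2L"),  # (2,1) -> informative
            ph.CrossingEvent("u", 2.0, "a", "L2R"),  # (3,0) -> uninformative
        )
        trial = ph.Trial(meta, events)
        assert ph.log_likelihood("M0", {}, trial) == pytest.approx(np.log2(1 / 3))

    def test_natural_log_base_rescales(self, hand_trial):
        ll2 = ph.log_likelihood("M0", {}, hand_trial, base=2)
        lle = ph.log_likelihood("M0", {}, hand_trial, base=np.e)
        assert lle == pytest.approx(ll2 * np.log(2))


class TestRegistry:
    def test_seven_core_models(self):
        core = list_models()
        assert [m.name for m in core] == ["M0", "S1", "S2", "S3", "S4", "D1", "D2"]

    def test_extension_and_param_counts(self):
        assert [m.name for m in list_models(True)][-1] == "C1"
        counts = {m.name: m.n_params for m in list_models(True)}
        assert counts == {
            "M0": 0, "S1": 1, "S2": 1, "S3": 1, "S4": 2, "D1": 1, "D2": 1, "C1": 2,
        }
        assert get_model("C1").param_names == ("gamma", "alpha")


class TestQuorumLinearity:
    @pytest.mark.parametrize("s", [1.1, 1.3, 1.5])
    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    def test_s4_close_to_linear_for_small_count_differences(self, s, a):
        """For shallow quorum steepness the S4 side probability is within
        0.05 of the best-fitting linear (S2) probability over states with
        count differences in -2..2."""
        states = [
            DecisionState(nl, g - nl)
            for g in (4, 5)
            for nl in range(1, g)
            if abs((g - nl) - (nl - 1)) <= 2
        ]
        p4 = np.array(
            [ph.side_probability("S4", {"a": a, "s": s}, st) for st in states]
        )

        def loss(beta):
            p2 = np.array(
                [ph.side_probability("S2", {"beta": beta}, st) for st in states]
            )
            return np.sum((p2 - p4) ** 2)

        beta = minimize_scalar(loss, bounds=(-5, 5), method="bounded").x
        p2 = np.array(
            [ph.side_probability("S2", {"beta": beta}, st) for st in states]
        )
        assert np.max(np.abs(p2 - p4)) < 0.05
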