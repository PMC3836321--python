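"""Occupancy, crossing groups, sign tests, leadership and hierarchy."""

import itertools

import numpy as np
import pytest

import patchhop as ph
from patchhop.eventlog import CrossingEvent, Dataset, Trial, TrialMetadata
from patchhop.patterns import (
    circular_triads_score_form,
    coral_association_test,
    crossing_groups,
    direction_interval_analysis,
    fisher_omnibus,
    follow_matrix,
    hierarchy_test,
    kendall_linearity,
    leadership_scores,
    linearity_mc_test,
    occupancy_distribution,
    pool_group_matrix,
)
from patchhop.simulate import SimulationDesign, simulate_trial


def make_trial(tid, g, left_ids, moves, duration=600.0):
    meta = TrialMetadata(tid, g, frozenset(left_ids), duration_s=duration)
    events = tuple(CrossingEvent(tid, t, f, d) for t, f, d in moves)
    return Trial(meta, events)


class TestOccupancy:
    def test_two_fish_hand_computation(self):
        trial = make_trial("o", 2, {"a"}, [(2.0, "a", "L2R")], duration=10.0)
        occ = occupancy_distribution(trial)
        assert occ.proportions == pytest.approx([0.8, 0.2, 0.0])

    def test_no_events_puts_all_mass_on_the_initial_split(self):
        trial = make_trial("o", 4, {"a", "b"}, [])
        occ = occupancy_distribution(trial)
        assert occ.proportions[2] == 1.0

    def test_proportions_sum_to_one(self, d1_dataset):
        for trial in d1_dataset:
            occ = occupancy_distribution(trial)
            assert occ.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_duration_rejected(self):
        meta = TrialMetadata("z", 2, frozenset({"a"}), duration_s=0.0)
        with pytest.raises(ValueError, match="duration"):
            occupancy_distribution(Trial(meta))


class TestCrossingGroups:
    def test_direction_runs_are_split_correctly(self):
        moves = [
            (1.0, "a", "L2R"), (2.0, "b", "L2R"),
            (3.0, "a", "R2L"), (4.0, "b", "L2R"),
        ]
        trial = make_trial("g", 4, {"a", "b", "c"}, moves)
        sizes = [grp.size for grp in crossing_groups(trial)]
        assert sizes == [2, 1, 1]

    def test_pool_is_origin_occupancy_at_group_start(self):
        moves = [(1.0, "a", "L2R"), (2.0, "b", "L2R"), (3.0, "c", "L2R")]
        trial = make_trial("g", 5, {"a", "b", "c", "d"}, moves)
        (grp,) = crossing_groups(trial)
        assert (grp.size, grp.pool) == (3, 4)

    def test_empty_trial_has_no_groups(self):
        assert crossing_groups(make_trial("g", 3, {"a"}, [])) == []

    def test_group_count_is_direction_changes_plus_one(self, d1_dataset):
        for trial in d1_dataset:
            if not trial.events:
                continue
            changes = sum(
                a.direction != b.direction
                for a, b in itertools.pairwise(trial.events)
            )
            assert len(crossing_groups(trial)) == changes + 1

    def test_single_group_matrix_row(self):
        moves = [(1.0, "a", "L2R"), (2.0, "b", "L2R")]
        trial = make_trial("g", 5, {"a", "b", "c"}, moves)
        mat = pool_group_matrix(trial)
        assert mat.loc[3, 2] == 1.0
        assert mat.loc[3].drop(2).eq(0).all()

    def test_matrix_rows_sum_to_one(self, d1_dataset):
        mat = pool_group_matrix(d1_dataset)
        assert mat.sum(axis=1).to_numpy() == pytest.approx(
            np.ones(len(mat)), abs=1e-9
        )


class TestDirectionInterval:
    def test_hand_classification_around_the_threshold(self):
        moves = [(1.0, "a", "L2R"), (2.0, "b", "L2R"), (10.0, "a", "R2L")]
        trial = make_trial("d", 3, {"a", "b"}, moves)
        res = direction_interval_analysis(trial)
        assert res.n_pairs == 2
        assert res.table["p_same"].tolist() == [1.0, 0.0]
        assert res.overall_p_same == pytest.approx(0.5)

    def test_single_event_gives_empty_table(self):
        trial = make_trial("d", 3, {"a"}, [(1.0, "b", "R2L")])
        res = direction_interval_analysis(trial)
        assert res.n_pairs == 0 and res.table.empty

    def test_strong_following_makes_same_direction_dominant(self):
        trial = simulate_trial(
            SimulationDesign(group_size=5, initial_left=2, model="D1",
                             params={"alpha": 20.0}, duration_s=None,
                             n_events=4000, seed=0)
        )
        res = direction_interval_analysis(trial)
        assert res.overall_p_same > 0.5


class TestCoralAssociation:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (14, 11, 0.0287),   # rounds to the reported 0.029
            (11, 11, 2.0**-11),
            (2, 1, 0.75),
        ],
    )
    def test_exact_tail_probabilities(self, n, k, expected):
        assert coral_association_test(n, k) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("n,k", [(5, 3), (9, 7), (12, 6), (12, 12)])
    def test_agrees_with_brute_force_enumeration(self, n, k):
        count = sum(
            1
            for outcome in itertools.product((0, 1), repeat=n)
            if sum(outcome) >= k
        )
        assert coral_association_test(n, k) == pytest.approx(count / 2**n)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            coral_association_test(5, 6)
        with pytest.raises(ValueError):
            coral_association_test(5, -1)


class TestLeadership:
    def test_hand_counts_identify_the_leader(self):
        moves = [
            (0.5, "c", "R2L"),                      # solo c (joins the left)
            (1.0, "a", "L2R"), (2.0, "b", "L2R"),   # a initiates, b follows
            (5.0, "a", "R2L"),                      # solo a
            (9.0, "a", "L2R"), (9.5, "c", "L2R"),   # a initiates again
            (20.0, "a", "R2L"),                     # solo a
        ]
        trial = make_trial("l", 3, {"a", "b"}, moves)
        summary = leadership_scores(trial)
        per = summary.per_fish.set_index("fish_id")
        assert per.loc["a", "solo"] == 2 and per.loc["a", "initiations"] == 2
        assert per.loc["b", "follows"] == 1 and per.loc["c", "follows"] == 1
        assert per["initiations"].idxmax() == "a"
        assert per["solo"].idxmax() == "a"

    def test_degenerate_counts_flagged_not_crashed(self):
        trial = make_trial("l", 3, {"a"}, [])
        summary = leadership_scores(trial)
        assert np.isnan(summary.solo_initiation_r)
        assert any("undefined" in f for f in summary.flags)

    def test_lengths_feed_the_size_correlation(self):
        moves = [(1.0, "a", "L2R"), (2.0, "b", "L2R"), (4.0, "c", "R2L"),
                 (6.0, "a", "R2L"), (7.0, "b", "R2L")]
        meta = TrialMetadata("l", 3, frozenset({"a", "b"}))
        roster = (ph.FishRecord("a", 40.0), ph.FishRecord("b", 30.0),
                  ph.FishRecord("c", 35.0))
        trial = Trial(meta, tuple(CrossingEvent("l", *m) for m in moves), roster)
        summary = leadership_scores(trial)
        assert np.isfinite(summary.length_initiation_r)


def tournament(n, edges):
    f = np.zeros((n, n), dtype=int)
    for i, j in edges:
        f[i, j] = 1
    return f


class TestHierarchy:
    def test_transitive_triple_is_perfectly_linear(self):
        f = tournament(3, [(0, 1), (0, 2), (1, 2)])
        k, d, d_max = kendall_linearity(f)
        assert (k, d, d_max) == (1.0, 0, 1.0)

    def test_circular_triple_has_zero_linearity(self):
        f = tournament(3, [(0, 1), (1, 2), (2, 0)])
        k, d, _ = kendall_linearity(f)
        assert (k, d) == (0.0, 1)

    def test_tied_dyads_shrink_the_triad_baseline(self):
        # one undecided dyad in a 4-fish group: the two triads containing
        # it are skipped and the baseline scales by the decided share
        f = tournament(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        k, d, d_max = kendall_linearity(f)
        assert d_max == pytest.approx(2.0 * 2 / 4)  # max(4) * decided share
        assert k == 1.0 and d == 0

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_triad_count_matches_score_variance_identity(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            wins = rng.integers(0, 2, size=(n, n))
            f = np.triu(wins, 1) + np.triu(1 - wins, 1).T  # complete tournament
            _, d, _ = kendall_linearity(f)
            assert d == circular_triads_score_form(f)

    def test_fisher_omnibus_hand_value(self):
        chi2, df, p = fisher_omnibus([0.5, 0.5])
        assert chi2 == pytest.approx(-2 * 2 * np.log(0.5), abs=1e-4)
        assert chi2 == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        assert 0 < p < 1

    def test_fisher_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            fisher_omnibus([0.5, 0.0])

    def test_mc_pvalue_detects_a_strict_hierarchy(self):
        # six fish: a fully transitive tournament is rare enough under the
        # fair-coin null (720 of 2^15 tournaments) for clear significance
        n = 6
        f = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                f[i, j] = 7  # i always leads j; odd counts cannot tie
                             # under the fair-coin null
        test = linearity_mc_test(f, n_mc=2000, rng=1)
        assert test.k == 1.0
        assert test.p < 0.05

    def test_follow_matrix_counts_within_group_successions(self):
        moves = [(0.5, "c", "R2L"),
                 (1.0, "a", "L2R"), (2.0, "b", "L2R"), (3.0, "c", "L2R"),
                 (9.0, "a", "R2L")]
        meta = TrialMetadata("h", 3, frozenset({"a", "b"}))
        roster = tuple(ph.FishRecord(x) for x in "abc")
        trial = Trial(meta, tuple(CrossingEvent("h", *m) for m in moves), roster)
        fish, f = follow_matrix(trial)
        assert fish == ["a", "b", "c"]
        assert f[0, 1] == 1 and f[1, 2] == 1 and f.sum() == 2

    def test_hierarchy_test_combines_trials_and_reports_exclusions(self):
        moves = [
            (0.5, "c", "R2L"),                                        # solo
            (1.0, "a", "L2R"), (2.0, "b", "L2R"), (3.0, "c", "L2R"),  # a>b, b>c
            (5.0, "a", "R2L"), (6.0, "b", "R2L"), (7.0, "c", "R2L"),  # a>b, b>c
            (9.0, "a", "L2R"), (10.0, "c", "L2R"),                    # a>c
        ]
        t1 = make_trial("h1", 3, {"a", "b"}, moves)
        meta2 = TrialMetadata("h2", 2, frozenset({"x"}))
        t2 = Trial(meta2)  # fewer than 3 fish -> excluded
        res = hierarchy_test(Dataset((t1, t2)), n_mc=500, seed=0)
        assert len(res.trials) == 1
        assert res.df == 2
        assert ("h2", "fewer than 3 fish") in res.excluded
        assert np.isfinite(res.fisher_chi2)
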