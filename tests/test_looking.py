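"""Unit and property tests for the per-trial looking measures."""

import numpy as np
import pytest

from gazecog.gaze_io import TaskConfig
from gazecog import looking

from conftest import (
    make_trial, random_trials,
    oracle_first_look, oracle_cp, oracle_shift_rate, oracle_lw1,
)


class TestFirstLook:
    def test_onscreen_at_change_onset_classifies_directly(self, task_cfg):
        tr = make_trial([(0, "left")], change_side="left")
        assert looking.classify_first_look(tr, task_cfg) == "change"
        tr = make_trial([(0, "left")], change_side="right")
        assert looking.classify_first_look(tr, task_cfg) == "no_change"

    def test_fallback_uses_first_onscreen_sample(self, task_cfg):
        # missing over [1000, 1500); first on-screen sample at 1500 is right
        tr = make_trial([(0, "left"), (1000, "missing"), (1500, "right")],
                        change_side="left")
        assert looking.classify_first_look(tr, task_cfg) == "no_change"

    def test_away_at_onset_triggers_fallback(self, task_cfg):
        tr = make_trial([(0, "away"), (1200, "left")], change_side="left")
        assert looking.classify_first_look(tr, task_cfg) == "change"

    def test_no_onscreen_window_unclassified(self, task_cfg):
        tr = make_trial([(0, "left"), (900, "away"), (2600, "right")],
                        change_side="left")
        assert looking.classify_first_look(tr, task_cfg) == "unclassified"

    def test_fallback_boundary_inclusive_at_end(self, task_cfg):
        at_2500 = make_trial([(0, "missing"), (2500, "right")], change_side="left")
        assert looking.classify_first_look(at_2500, task_cfg) == "no_change"
        at_2501 = make_trial([(0, "missing"), (2501, "right")], change_side="left")
        assert looking.classify_first_look(at_2501, task_cfg) == "unclassified"

    def test_truncation_after_fallback_window_is_irrelevant(self, task_cfg):
        rng = np.random.default_rng(7)
        for tr in random_trials(50, seed=11):
            full = looking.classify_first_look(tr, task_cfg)
            keep = tr.t_ms <= task_cfg.firstlook_fallback_end_ms
            trunc = make_trial(
                list(zip(tr.t_ms[keep], tr.aoi[keep])) or [(0, "missing")],
                change_side=tr.change_side)
            assert looking.classify_first_look(trunc, task_cfg) == full


class TestChangePreference:
    def test_hand_computed_interval_sum(self, task_cfg):
        # inside [1750, 6750): 3000 ms change side, 2000 ms no-change side
        tr = make_trial(
            [(0, "away"), (1750, "left"), (4750, "right"), (6750, "away")],
            change_side="left")
        assert looking.change_preference(tr, task_cfg) == pytest.approx(0.6)

    def test_all_looking_on_change_side(self, task_cfg):
        tr = make_trial([(0, "left")], change_side="left")
        assert looking.change_preference(tr, task_cfg) == 1.0

    def test_away_above_threshold_excluded(self, task_cfg):
        # 80% of the trial away -> excluded
        tr = make_trial([(0, "away"), (8000, "left")], change_side="left")
        assert looking.away_fraction(tr, task_cfg) == pytest.approx(0.8)
        assert looking.change_preference(tr, task_cfg) is None

    def test_away_boundary_is_strict(self, task_cfg):
        # exactly 75% away is retained; 76% is excluded
        retained = make_trial(
            [(0, "away"), (1750, "left"), (4250, "away")], change_side="left")
        assert looking.away_fraction(retained, task_cfg) == pytest.approx(0.75)
        assert looking.change_preference(retained, task_cfg) is not None
        excluded = make_trial(
            [(0, "away"), (1750, "left"), (4150, "away")], change_side="left")
        assert looking.away_fraction(excluded, task_cfg) == pytest.approx(0.76)
        assert looking.change_preference(excluded, task_cfg) is None

    def test_no_onscreen_time_in_window_undefined(self, task_cfg):
        tr = make_trial([(0, "left"), (1500, "away"), (7000, "left")],
                        change_side="left")
        assert looking.change_preference(tr, task_cfg) is None


class TestShiftRate:
    def test_hand_counted_runs(self, task_cfg):
        # L(2s) R(2s) L(1s) away(5s): 2 switches / 5 s looking
        tr = make_trial([(0, "left"), (2000, "right"), (4000, "left"),
                        (5000, "away")])
        assert looking.shift_rate(tr, task_cfg) == pytest.approx(0.4)

    def test_single_side_is_zero(self, task_cfg):
        tr = make_trial([(0, "right")])
        assert looking.shift_rate(tr, task_cfg) == 0.0

    def test_away_gap_neither_breaks_switch_nor_counts(self, task_cfg):
        tr = make_trial([(0, "left"), (2000, "away"), (4000, "right"),
                        (6000, "missing")])
        assert looking.shift_rate(tr, task_cfg) == pytest.approx(0.25)

    def test_no_looking_undefined(self, task_cfg):
        tr = make_trial([(0, "away")])
        assert looking.shift_rate(tr, task_cfg) is None


class TestLookingWindow1:
    def test_hand_computed_fraction(self, task_cfg):
        # window [0, 750): 600 ms left then 150 ms right -> 600/750
        tr = make_trial([(0, "left"), (600, "right"), (750, "away")])
        assert looking.looking_window1(tr, task_cfg) == pytest.approx(0.8)

    def test_single_side_is_one(self, task_cfg):
        tr = make_trial([(0, "right")])
        assert looking.looking_window1(tr, task_cfg) == 1.0

    def test_no_onscreen_looking_undefined(self, task_cfg):
        tr = make_trial([(0, "away"), (800, "left")])
        assert looking.looking_window1(tr, task_cfg) is None


class TestKappa:
    def test_identical_codings(self):
        a = ["left", "right", "away", "left"]
        assert looking.cohens_kappa(a, a) == pytest.approx(1.0)

    def test_constant_versus_split_is_zero(self):
        a = ["left"] * 10
        b = ["left"] * 5 + ["right"] * 5
        assert looking.cohens_kappa(a, b) == pytest.approx(0.0)

    def test_closed_form_two_by_two(self):
        # 45/45 agreement, 5/5 disagreement: p_o=0.9, p_e=0.5 -> kappa 0.8
        a = ["left"] * 50 + ["right"] * 50
        b = ["left"] * 45 + ["right"] * 5 + ["right"] * 45 + ["left"] * 5
        assert looking.cohens_kappa(a, b) == pytest.approx(0.8)

    def test_both_constant_equal_degenerate(self):
        assert looking.cohens_kappa(["left"] * 5, ["left"] * 5) == 1.0


def mirror(trial):
    swap = {"left": "right", "right": "left", "away": "away", "missing": "missing"}
    return make_trial(
        [(t, swap[str(a)]) for t, a in zip(trial.t_ms, trial.aoi)],
        change_side=swap[trial.change_side],
        load=trial.load, load_level=trial.load_level,
    )


def test_mirror_symmetry_of_all_measures(task_cfg):
    """Relabeling left<->right in samples and change side leaves every
    looking measure unchanged."""
    for tr in random_trials(60, seed=5):
        mirrored = mirror(tr)
        assert looking.classify_first_look(tr, task_cfg) == \
            looking.classify_first_look(mirrored, task_cfg)
        for fn in (looking.change_preference, looking.shift_rate,
                   looking.looking_window1):
            a, b = fn(tr, task_cfg), fn(mirrored, task_cfg)
            if a is None:
                assert b is None
            else:
                assert a == pytest.approx(b)


def test_interval_scorer_matches_bruteforce_oracle(task_cfg):
    """Interval-based measures agree with the straight-loop per-ms scorer."""
    for tr in random_trials(120, seed=21):
        assert looking.classify_first_look(tr, task_cfg) == \
            oracle_first_look(tr, task_cfg)
        for fast, slow in [(looking.change_preference, oracle_cp),
                           (looking.shift_rate, oracle_shift_rate),
                           (looking.looking_window1, oracle_lw1)]:
            a, b = fast(tr, task_cfg), slow(tr, task_cfg)
            if a is None or b is None:
                assert a is None and b is None
            else:
                assert a == pytest.approx(b, abs=1e-9)


def test_measure_ranges_when_defined(task_cfg):
    for tr in random_trials(80, seed=9):
        cp = looking.change_preference(tr, task_cfg)
        if cp is not None:
            assert 0.0 <= cp <= 1.0
        sr = looking.shift_rate(tr, task_cfg)
        if sr is not None:
            assert sr >= 0.0


def test_score_dataset_single_trial_aggregate(task_cfg):
    tr = make_trial([(0, "left"), (3000, "right"), (6000, "left")],
                    change_side="left", load=1, load_level="low")
    scores, agg, excl = looking.score_dataset([tr], task_cfg)
    assert len(scores) == 1 and len(agg) == 1
    assert agg["cp_mean"].iloc[0] == pytest.approx(
        scores["change_preference"].iloc[0])
    assert agg["shift_rate_mean"].iloc[0] == pytest.approx(
        scores["shift_rate"].iloc[0])
    assert excl["cp_invalid_total"] == 0


def test_score_dataset_exclusion_tallies(task_cfg):
    """Fixture violating each filter once: counts must match hand tallies."""
    good = make_trial([(0, "left"), (4000, "right")], change_side="left",
                      trial_index=0)
    # classified at onset but 80% away -> fails only the away filter
    away_heavy = make_trial([(0, "left"), (2000, "away")], change_side="left",
                            trial_index=1)
    unclassifiable = make_trial([(0, "away")], change_side="left", trial_index=2)
    scores, _, excl = looking.score_dataset(
        [good, away_heavy, unclassifiable], task_cfg)
    assert excl["n_trials"] == 3
    assert excl["away_excluded"] == 2  # away_heavy and the all-away trial
    assert excl["firstlook_unclassified"] == 1
    assert excl["cp_invalid_total"] == 2


def test_cp_decreases_with_load_on_synthetic_trials(task_cfg):
    """With capacity below the top load, mean CP on first-look no-change
    trials falls as load rises (the memory-load signature)."""
    rng = np.random.default_rng(42)
    from gazecog import synth
    means = {}
    for load in (1, 2, 3):
        vals = []
        for _ in range(400):
            side = "left" if rng.random() < 0.5 else "right"
            segs = synth.simulate_trial_segments(
                rng, side, load, capacity=1.8, look_mean_ms=1200.0)
            tr = make_trial(segs, change_side=side)
            if looking.classify_first_look(tr, task_cfg) != "no_change":
                continue
            cp = looking.change_preference(tr, task_cfg)
            if cp is not None:
                vals.append(cp)
        means[load] = np.mean(vals)
    assert means[1] > means[2] > means[3]
    assert means[1] > 0.5
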