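"""Ensemble categorization, arm scores, peri-event activity, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pagstates.behavior import ZoneLabels
from pagstates.core import AssayKind, BehaviorIntervals, TraceMatrix
from pagstates.ensembles import (
    categorization_split,
    categorize_arm_cells,
    compute_arm_scores,
    epm_score,
    open_arm_preference_score,
    peri_event_analysis,
    activity_correlations,
    spatial_activity_map,
)


def _brute_force_auc(open_vals, closed_vals):
    """Mann-Whitney AUC by enumerating every (open, closed) pair."""
    wins = ties = 0
    for o in open_vals:
        for c in closed_vals:
            if o > c:
                wins += 1
            elif o == c:
                ties += 1
    return (wins + 0.5 * ties) / (len(open_vals) * len(closed_vals))


class TestPreferenceScore:
    def test_strict_separation_gives_plus_one(self):
        act = np.array([2.0, 3.0, 4.0, 0.0, 0.5, 1.0])
        open_mask = np.array([1, 1, 1, 0, 0, 0], bool)
        score, auc = open_arm_preference_score(act, open_mask, ~open_mask)
        assert auc == 1.0 and score == 1.0

    def test_identical_distributions_give_zero(self):
        act = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        open_mask = np.array([1, 1, 1, 0, 0, 0], bool)
        score, auc = open_arm_preference_score(act, open_mask, ~open_mask)
        assert auc == pytest.approx(0.5)
        assert score == pytest.approx(0.0)

    def test_hand_example_with_interleaved_values(self):
        # open {1, 3}, closed {2}: pairs (1,2) lose, (3,2) win -> AUC 0.5
        act = np.array([1.0, 3.0, 2.0])
        open_mask = np.array([1, 1, 0], bool)
        score, auc = open_arm_preference_score(act, open_mask, ~open_mask)
        assert auc == pytest.approx(_brute_force_auc([1, 3], [2])) == pytest.approx(0.5)
        assert score == pytest.approx(0.0)

    def test_one_class_empty_raises(self):
        act = np.arange(5.0)
        with pytest.raises(ValueError, match="both arm types"):
            open_arm_preference_score(act, np.zeros(5, bool), np.ones(5, bool))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_pair_counting(self, data):
        """AUC equals the all-pairs Mann-Whitney oracle on small inputs,
        including ties."""
        n_open = data.draw(st.integers(1, 25))
        n_closed = data.draw(st.integers(1, 25))
        vals = data.draw(st.lists(st.integers(-3, 3), min_size=n_open + n_closed,
                                  max_size=n_open + n_closed))
        act = np.array(vals, dtype=float)
        open_mask = np.zeros(len(act), bool)
        open_mask[:n_open] = True
        score, auc = open_arm_preference_score(act, open_mask, ~open_mask)
        oracle = _brute_force_auc(act[open_mask], act[~open_mask])
        assert auc == pytest.approx(oracle, abs=1e-12)
        assert score == pytest.approx(2 * oracle - 1, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_label_swap_antisymmetry(self, data):
        """Swapping open/closed labels negates the preference score."""
        n = data.draw(st.integers(4, 30))
        act = np.array(data.draw(st.lists(st.floats(-5, 5, allow_nan=False),
                                          min_size=n, max_size=n)))
        k = data.draw(st.integers(1, n - 1))
        open_mask = np.zeros(n, bool)
        open_mask[:k] = True
        s1, _ = open_arm_preference_score(act, open_mask, ~open_mask)
        s2, _ = open_arm_preference_score(act, ~open_mask, open_mask)
        assert s1 == pytest.approx(-s2, abs=1e-12)


class TestEPMScore:
    def test_same_type_identical_across_type_different_is_one(self):
        # F_O1 = F_O2 = 1, F_C1 = F_C2 = 0: A = 1, B = 0 -> score 1.0
        assert epm_score(1.0, 1.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_hand_arithmetic_mixed_case(self):
        # F_O1 = F_C1 = 1, F_O2 = F_C2 = 0: A = 0.5, B = 1 -> -1/3
        assert epm_score(1.0, 0.0, 1.0, 0.0) == pytest.approx(-1.0 / 3.0)

    def test_all_equal_defined_as_zero(self):
        assert epm_score(0.7, 0.7, 0.7, 0.7) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=4, max_size=4))
    def test_bounded_whenever_defined(self, means):
        s = epm_score(*means)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12


def _zone_labels(labels):
    return ZoneLabels(np.asarray(labels), AssayKind.EPM)


class TestCategorization:
    def _session_zones(self, n_per_arm=80, rng=None):
        labels = (["open1"] * n_per_arm + ["open2"] * n_per_arm
                  + ["closed1"] * n_per_arm + ["closed2"] * n_per_arm
                  + ["center"] * 20)
        rng = rng or np.random.default_rng(0)
        labels = np.array(labels)
        rng.shuffle(labels)
        return _zone_labels(labels)

    def test_planted_categories_recovered(self, epm_prepared, epm_session):
        """At snr 5 the categorizer recovers the planted open/closed/neither
        labels with balanced accuracy > 0.9."""
        from sklearn.metrics import balanced_accuracy_score

        labels = categorize_arm_cells(epm_prepared.traces, epm_prepared.zones_neural)
        truth = epm_session.truth.cell_category
        y_true = [truth[c] for c in labels.table.index]
        y_pred = list(labels.categories)
        assert balanced_accuracy_score(y_true, y_pred) > 0.9

    def test_cell_elevated_in_single_open_arm_is_neither(self):
        """The rule requires *each individual* open arm to beat pooled closed
        activity; tuning to only one open arm is not enough."""
        zones = self._session_zones()
        rng = np.random.default_rng(1)
        act = rng.standard_normal(len(zones.labels)) * 0.1
        act[zones.labels == "open1"] += 3.0  # open1 only
        tm = TraceMatrix(act[None, :], 7.5, ["solo"], is_zscored=True)
        labels = categorize_arm_cells(tm, zones)
        assert labels.categories["solo"] == "neither"

    def test_constant_cell_is_neither(self):
        zones = self._session_zones()
        tm = TraceMatrix(np.full((1, len(zones.labels)), 2.0), 7.5, ["flat"],
                         is_zscored=True)
        labels = categorize_arm_cells(tm, zones)
        assert labels.categories["flat"] == "neither"

    def test_unvisited_arm_warns_and_labels_neither(self):
        labels_arr = np.array(["open1"] * 50 + ["closed1"] * 50 + ["closed2"] * 50)
        zones = _zone_labels(labels_arr)
        rng = np.random.default_rng(0)
        tm = TraceMatrix(rng.standard_normal((3, 150)), 7.5, is_zscored=True)
        with pytest.warns(UserWarning, match="never visited"):
            out = categorize_arm_cells(tm, zones)
        assert (out.categories == "neither").all()

    def test_split_40_60_masks(self):
        cat, held = categorization_split(1000, 7.5)
        assert cat.sum() == 400
        gap = int(round(10 * 7.5))
        assert not held[:400 + gap].any()
        assert held[400 + gap:].all()
        assert not (cat & held).any()


class TestPeriEvent:
    def _step_traces(self, onset_s=40.0, n=750, fs=7.5):
        vals = np.zeros((1, n))
        vals[0, int(onset_s * fs):] = 1.0
        return TraceMatrix(vals, fs, ["step"], is_zscored=True)

    def test_unit_step_gives_unit_delta(self):
        tm = self._step_traces()
        iv = BehaviorIntervals.from_records([("escape", 40.0, 42.0)])
        res = peri_event_analysis(tm, iv, "escape")
        assert res.delta[0] == pytest.approx(1.0)
        assert res.n_events == 1

    def test_event_too_close_to_edge_dropped(self):
        tm = self._step_traces()
        iv = BehaviorIntervals.from_records([("escape", 1.0, 2.0)])
        with pytest.raises(ValueError, match="no usable"):
            peri_event_analysis(tm, iv, "escape")

    def test_freeze_within_10s_of_escape_excluded(self):
        tm = self._step_traces()
        iv = BehaviorIntervals.from_records(
            [("escape", 30.0, 32.0), ("freeze", 35.0, 36.0), ("freeze", 60.0, 61.0)])
        res = peri_event_analysis(tm, iv, "freeze", exclude_after="escape")
        assert res.n_events == 1  # the 35 s freeze (5 s after escape) is dropped
        res_all = peri_event_analysis(tm, iv, "freeze")
        assert res_all.n_events == 2

    def test_head_dip_uses_early_before_window(self):
        fs = 7.5
        n = 750
        vals = np.zeros((1, n))
        # activity ramps between -2.5 s and 0 s before the dip at t = 40 s
        onset = int(40 * fs)
        vals[0, onset - int(2.5 * fs):onset] = 0.5
        vals[0, onset:] = 1.0
        tm = TraceMatrix(vals, fs, ["ramp"], is_zscored=True)
        iv = BehaviorIntervals.from_records([("head_dip", 40.0, 41.0)])
        res = peri_event_analysis(tm, iv, "head_dip")
        # before window [-5, -2.5] sees 0, after [0, 2.5] sees 1
        assert res.delta[0] == pytest.approx(1.0)

    def test_window_time_axis_centered_on_onset(self):
        tm = self._step_traces()
        iv = BehaviorIntervals.from_records([("escape", 40.0, 42.0)])
        res = peri_event_analysis(tm, iv, "escape")
        assert res.time_s[0] == pytest.approx(-5.0, abs=1 / 7.5)
        assert res.time_s[-1] == pytest.approx(5.0, abs=1 / 7.5)
        onset_col = np.searchsorted(res.time_s, 0)
        assert res.aligned[0, onset_col - 1] == 0.0
        assert res.aligned[0, onset_col] == 1.0


class TestCorrelationsAndMaps:
    def test_cell_equal_to_speed_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        speed = rng.random(500) * 10
        tm = TraceMatrix(np.vstack([speed, rng.standard_normal(500)]), 7.5,
                         ["speedcell", "noise"], is_zscored=True)
        table = activity_correlations(tm, speed=speed)
        assert table.loc["speedcell", "r_speed"] == pytest.approx(1.0)
        assert abs(table.loc["noise", "r_speed"]) < 0.2

    def test_null_correlations_concentrate_near_zero(self):
        """Independent noise cells at n = 1000 samples: 95% of |r| < 0.1."""
        rng = np.random.default_rng(1)
        n_cells, n = 60, 1000
        tm = TraceMatrix(rng.standard_normal((n_cells, n)), 7.5, is_zscored=True)
        speed = rng.random(n)
        table = activity_correlations(tm, speed=speed)
        frac_small = (table["r_speed"].abs() < 0.1).mean()
        assert frac_small >= 0.93

    def test_zero_variance_regressor_reported_missing(self):
        tm = TraceMatrix(np.random.default_rng(0).standard_normal((2, 100)), 7.5,
                         is_zscored=True)
        table = activity_correlations(tm, speed=np.ones(100))
        assert table["r_speed"].isna().all()

    def test_anti_symmetric_tuning_negative_open_closed_correlation(self, epm_prepared):
        """Planted open vs closed ensembles: per-cell open-arm means
        anticorrelate with closed-arm means across cells."""
        table = activity_correlations(epm_prepared.traces, zones=epm_prepared.zones_neural)
        assert table.attrs["r_open_closed"] < -0.3
        assert table.attrs["r_open1_open2"] > 0.3

    def test_spatial_map_flat_for_uniform_activity(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 50, (2000, 2))
        tm = TraceMatrix(np.full((1, 2000), 1.5), 7.5, is_zscored=True)
        maps, _, _ = spatial_activity_map(tm, xy, bin_cm=10.0)
        assert np.ma.allclose(maps[0][~maps[0].mask], 1.5)

    def test_unvisited_bins_masked(self):
        xy = np.tile([5.0, 5.0], (500, 1))
        tm = TraceMatrix(np.random.default_rng(0).standard_normal((1, 500)), 7.5,
                         is_zscored=True)
        maps, xe, ye = spatial_activity_map(tm, xy, bin_cm=2.0,
                                            extent=(0, 20, 0, 20))
        assert maps[0].mask.sum() >= maps[0].size - 1

    def test_threat_tuned_cell_peaks_in_threat_zone(self, rat_prepared):
        """A planted approach-tuned (open-category) cell's spatial map peaks
        inside the threatening zone of the rat arena."""
        sess = rat_prepared.session
        truth = sess.truth.cell_category
        open_cells = [c for c in rat_prepared.traces.cell_ids if truth[c] == "open"]
        ratio = sess.config.downsample_ratio
        n = rat_prepared.traces.n_timepoints
        xy = sess.pose.centroid()[: n * ratio].reshape(n, ratio, 2).mean(axis=1)
        idx = rat_prepared.traces.cell_ids.index(open_cells[0])
        sub = TraceMatrix(rat_prepared.traces.values[[idx]], 7.5, is_zscored=True)
        maps, xe, ye = spatial_activity_map(sub, xy, bin_cm=7.0, min_occupancy=5)
        m = maps[0]
        peak = np.unravel_index(np.ma.argmax(m), m.shape)
        x_peak = (xe[peak[0]] + xe[peak[0] + 1]) / 2
        y_peak = (ye[peak[1]] + ye[peak[1] + 1]) / 2
        rat_xy = sess.geometry.rat_tether_xy
        assert np.hypot(x_peak - rat_xy[0], y_peak - rat_xy[1]) < 25.0


class TestArmScores:
    def test_compute_arm_scores_on_planted_session(self, epm_prepared, epm_session):
        scores = compute_arm_scores(epm_prepared.traces, epm_prepared.zones_neural)
        truth = epm_session.truth.cell_category
        open_pref = [scores.table.loc[c, "preference_score"]
                     for c in scores.table.index if truth[c] == "open"]
        closed_pref = [scores.table.loc[c, "preference_score"]
                       for c in scores.table.index if truth[c] == "closed"]
        assert np.mean(open_pref) > 0.5
        assert np.mean(closed_pref) < -0.5
        # planted ensembles fire alike in both same-type arms: high EPM score
        tuned = [c for c in scores.table.index if truth[c] != "neither"]
        assert scores.table.loc[tuned, "epm_score"].mean() > 0.5
        assert scores.table["preference_score"].between(-1, 1).all()
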