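import numpy as np
import pandas as pd
import pytest

from racestop.fmri_glm import (
    EVENT_TYPES,
    EventClassificationError,
    build_design_matrix,
    contrast_spec,
    events_from_trials,
    fit_and_contrast,
    flexible_factorial,
    roi_mean_signal,
    sphere_roi,
)
from racestop.group_stats import RankDeficientError


def events_df(onsets, types):
    return pd.DataFrame(
        {"onset": onsets, "duration": 0.0, "trial_type": types}
    )


def zero_motion(n):
    return np.zeros((n, 6))


class TestEventsFromTrials:
    def test_eight_way_classification(self, food_log):
        ev = events_from_trials(food_log)
        assert len(ev) == 200
        assert set(ev["trial_type"]) <= {t for t in EVENT_TYPES if t.startswith("food")}
        # partition: four food types cover the whole run
        assert ev["trial_type"].value_counts().sum() == 200
        assert (ev["duration"] == 0).all()
        assert ev["onset"].is_monotonic_increasing

    def test_correct_go_and_failed_stop_mapping(self, food_log):
        ev = events_from_trials(food_log)
        go_correct = ((food_log["trial_type"] == "go") & food_log["responded"]
                      & food_log["correct"]).sum()
        stop_failed = ((food_log["trial_type"] == "stop")
                       & food_log["responded"]).sum()
        counts = ev["trial_type"].value_counts()
        assert counts.get("food_gocor", 0) == go_correct
        assert counts.get("food_stopincor", 0) == stop_failed

    def test_missing_timing_column_errors(self, food_log):
        with pytest.raises(EventClassificationError, match="onset_ms"):
            events_from_trials(food_log.drop(columns=["onset_ms"]))


class TestDesignMatrix:
    def test_column_layout_is_23_wide(self):
        ev = events_df([4.0, 30.0], ["food_gocor", "food_stopcor"])
        with pytest.warns(UserWarning):
            bundle = build_design_matrix(ev, zero_motion(40), tr=2.0)
        assert bundle.matrix.shape == (40, 23)
        assert bundle.columns[-1] == "intercept"
        assert sum(c.startswith("motion_") for c in bundle.columns) == 6
        assert sum(c.endswith("_derivative") for c in bundle.columns) == 8

    def test_canonical_hrf_peaks_near_five_seconds(self):
        ev = events_df([0.0], ["food_stopcor"])
        with pytest.warns(UserWarning):
            bundle = build_design_matrix(ev, zero_motion(64), tr=0.5)
        col = bundle.matrix["food_stopcor"].to_numpy()
        peak_t = np.argmax(col) * 0.5
        assert 4.0 <= peak_t <= 6.0
        # undershoot after the peak
        assert col[int(14 / 0.5)] < 0

    def test_no_events_leaves_zero_task_columns(self):
        ev = events_df([], [])
        with pytest.warns(UserWarning):
            bundle = build_design_matrix(ev, zero_motion(20), tr=2.0)
        task_cols = [c for c in bundle.columns
                     if not c.startswith(("motion_", "intercept"))]
        assert not bundle.matrix[task_cols].to_numpy().any()
        assert (bundle.matrix["intercept"] == 1).all()

    def test_shifting_onsets_by_one_tr_shifts_columns_one_sample(self):
        tr, n = 2.0, 60
        e1 = events_df([10.0], ["food_gocor"])
        e2 = events_df([12.0], ["food_gocor"])
        with pytest.warns(UserWarning):
            b1 = build_design_matrix(e1, zero_motion(n), tr=tr)
            b2 = build_design_matrix(e2, zero_motion(n), tr=tr)
        np.testing.assert_allclose(
            b1.matrix["food_gocor"].to_numpy()[:-1],
            b2.matrix["food_gocor"].to_numpy()[1:],
            atol=1e-10,
        )

    def test_derivative_nearly_orthogonal_to_hrf_for_isolated_event(self):
        ev = events_df([20.0], ["food_gocor"])
        with pytest.warns(UserWarning):
            bundle = build_design_matrix(ev, zero_motion(100), tr=1.0)
        h = bundle.matrix["food_gocor"]
        d = bundle.matrix["food_gocor_derivative"]
        r = np.corrcoef(h, d)[0, 1]
        assert abs(r) < 0.3

    def test_late_event_rejected(self):
        ev = events_df([100.0], ["food_gocor"])
        with pytest.raises(ValueError, match="beyond"):
            build_design_matrix(ev, zero_motion(20), tr=2.0)


def full_run_bundle(seed=0, n_scans=240):
    """A run containing all eight event types plus smooth motion columns."""
    rng = np.random.default_rng(seed)
    onsets = np.sort(rng.uniform(5, n_scans * 2.0 - 40, size=48))
    types = [EVENT_TYPES[i % 8] for i in range(48)]
    motion = rng.normal(0, 0.05, size=(n_scans, 6)).cumsum(axis=0) * 0.1
    ev = events_df(onsets, types)
    return build_design_matrix(ev, motion, tr=2.0, n_scans=n_scans)


class TestFitAndContrast:
    def test_noiseless_recovery_is_exact(self):
        bundle = full_run_bundle()
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 2, size=bundle.matrix.shape[1])
        y = bundle.matrix.to_numpy() @ beta
        for name in ("stopcor_gt_gocor", "stopcor_gt_baseline", "stopincor_gt_gocor"):
            c = contrast_spec(name, bundle)
            est = fit_and_contrast(y, bundle, c)
            assert est.value == pytest.approx(float(c.weights.to_numpy() @ beta),
                                              abs=1e-8)

    def test_equal_betas_null_the_between_condition_contrast(self):
        bundle = full_run_bundle(seed=2)
        beta = np.zeros(bundle.matrix.shape[1])
        cols = list(bundle.columns)
        for c in ("food_stopcor", "food_gocor", "neutral_stopcor", "neutral_gocor"):
            beta[cols.index(c)] = 1.7
        y = bundle.matrix.to_numpy() @ beta
        est = fit_and_contrast(y, bundle, contrast_spec("stopcor_gt_gocor", bundle))
        assert est.value == pytest.approx(0.0, abs=1e-10)

    def test_stopcor_gt_baseline_equals_the_stopcor_beta(self):
        bundle = full_run_bundle(seed=3)
        rng = np.random.default_rng(4)
        beta = rng.normal(size=bundle.matrix.shape[1])
        y = bundle.matrix.to_numpy() @ beta
        est = fit_and_contrast(
            y, bundle, contrast_spec("stopcor_gt_baseline", bundle, condition="food")
        )
        assert est.value == pytest.approx(
            beta[list(bundle.columns).index("food_stopcor")], abs=1e-8
        )

    def test_weights_sum_to_zero_for_between_condition_contrasts(self):
        bundle = full_run_bundle(seed=5)
        for name in ("stopcor_gt_gocor", "stopincor_gt_gocor"):
            w = contrast_spec(name, bundle).weights
            assert w.sum() == pytest.approx(0.0)
            assert (w[[c for c in bundle.columns
                       if c.endswith("_derivative") or c.startswith("motion_")]] == 0).all()

    def test_rank_deficiency_names_collinear_columns(self):
        bundle = full_run_bundle(seed=6)
        bundle.matrix["motion_2"] = bundle.matrix["motion_1"]
        y = np.zeros(bundle.n_scans)
        with pytest.raises(RankDeficientError, match="motion"):
            fit_and_contrast(y, bundle, contrast_spec("stopcor_gt_gocor", bundle))


class TestFlexibleFactorial:
    def test_crossover_interaction_detected_with_correct_simple_effects(self):
        rng = np.random.default_rng(10)
        rows, parts = [], []
        for g_idx, group in enumerate(["RPG", "IAG"]):
            for i in range(25):
                pid = f"{group}-{i}"
                parts.append({"participant_id": pid, "group": group,
                              "age": float(rng.normal(21, 3)),
                              "sex": rng.choice(["male", "female"]),
                              "bmi": float(rng.normal(29, 5)),
                              "bdi_ii": float(rng.normal(8, 5)),
                              "composite_appetite": float(rng.normal(57, 17))})
                for cond in ["food", "neutral"]:
                    mu = 1.0 if (group == "RPG") == (cond == "food") else -1.0
                    rows.append({"participant_id": pid, "condition": cond,
                                 "value": mu + rng.normal(0, 0.8)})
        results, simple = flexible_factorial(pd.DataFrame(rows), pd.DataFrame(parts))
        inter = next(r for r in results if r.effect == "group:condition")
        assert inter.p < 0.05
        by_level = simple[simple["kind"] == "group_within_stimulus"].set_index("level")
        assert (by_level["comparison"] == "RPG - IAG").all()
        assert by_level.loc["food", "mean_diff"] > 0   # IAG below RPG under food
        assert by_level.loc["neutral", "mean_diff"] < 0
        within = simple[simple["kind"] == "stimulus_within_group"].set_index("level")
        assert (within["comparison"] == "neutral - food").all()
        assert within.loc["RPG", "mean_diff"] < 0      # neutral below food in RPG
        assert within.loc["IAG", "mean_diff"] > 0

    def test_null_betas_keep_interaction_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 120
        for _ in range(reps):
            rows, parts = [], []
            for group, n in [("RPG", 12), ("IAG", 12)]:
                for i in range(n):
                    pid = f"{group}-{i}"
                    parts.append({"participant_id": pid, "group": group})
                    for cond in ["food", "neutral"]:
                        rows.append({"participant_id": pid, "condition": cond,
                                     "value": float(rng.normal())})
            results, _ = flexible_factorial(
                pd.DataFrame(rows), pd.DataFrame(parts), covariates=[]
            )
            inter = next(r for r in results if r.effect == "group:condition")
            rejections += inter.p < 0.05
        assert 0.01 <= rejections / reps <= 0.11


class TestSphereRoi:
    def brute_force_count(self, center, radius, voxel):
        center = np.round(np.asarray(center) / voxel) * voxel
        lo = center - radius - 2 * voxel
        hi = center + radius + 2 * voxel
        count = 0
        grids = [np.arange(np.floor(l / voxel), np.ceil(h / voxel) + 1) * voxel
                 for l, h in zip(lo, hi)]
        for x in grids[0]:
            for y in grids[1]:
                for z in grids[2]:
                    if np.sum((np.array([x, y, z]) - center) ** 2) <= radius**2 + 1e-9:
                        count += 1
        return count

    def test_canonical_ifg_sphere_has_81_voxels(self):
        roi = sphere_roi((51, 16, 18), radius=8.0, voxel_size=3.0)
        assert roi.n_voxels == 81
        assert roi.n_voxels == self.brute_force_count((51, 16, 18), 8.0, 3.0)

    @pytest.mark.parametrize("radius", [4.0, 6.0, 10.0])
    def test_matches_brute_force_enumeration(self, radius):
        roi = sphere_roi((0, 0, 0), radius=radius, voxel_size=3.0)
        assert roi.n_voxels == self.brute_force_count((0, 0, 0), radius, 3.0)

    def test_tiny_radius_keeps_only_the_center(self):
        roi = sphere_roi((0, 0, 0), radius=1.4, voxel_size=3.0)
        assert roi.n_voxels == 1

    def test_membership_symmetric_under_reflection(self):
        roi = sphere_roi((51, 16, 18), radius=8.0, voxel_size=3.0)
        center = np.asarray(roi.center_mm)
        members = {tuple(v) for v in np.round(roi.voxels, 6)}
        reflected = {tuple(np.round(2 * center - v, 6)) for v in roi.voxels}
        assert members == reflected

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_roi((0, 0, 0), radius=0.0)

    def test_mean_signal_extraction(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        np.testing.assert_allclose(roi_mean_signal(vals), vals.mean(axis=1))
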