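"""Features, fold assignment, two-step training, HPO, and gated prediction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import babylength as bl
from babylength.card import CardDetection
from babylength.landmarks import LandmarkSet, SegmentLengths
from babylength.model import (
    FEATURE_NAMES,
    ModelConfig,
    SearchSpace,
    assign_folds,
    build_features,
    cross_validate,
    fit_two_step,
    hpo_search,
    validate_folds,
)
from babylength.synthetic import SEGMENTS, GeneratorConfig, generate_cohort


def _detection(ppm=10.0):
    return CardDetection(
        success=True, quad_px=np.zeros((4, 2)), scale_w=ppm, scale_h=ppm,
        pixel_per_metric=ppm, mask_quad_iou=1.0,
    )


def _feature_frame(n_rows: int, seed: int, outlier_mm: float | None = None):
    """Synthetic feature table with total_mm informative of measured_mm."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(450.0, 850.0, size=n_rows)
    frame = pd.DataFrame({name: rng.normal(0, 1, n_rows) for name in FEATURE_NAMES})
    frame["total_mm"] = y + rng.normal(0, 2.0, n_rows)
    frame["measured_mm"] = y
    if outlier_mm is not None:
        frame.loc[0, "measured_mm"] += outlier_mm
    return frame


class TestBuildFeatures:
    def _segments(self, each=1000.0):
        lengths = {s: each for s in SEGMENTS}
        return SegmentLengths(lengths_px=lengths, total_px=sum(lengths.values()))

    def _lms(self):
        pts = {n: (np.zeros(2), 0.9) for n in
               ("crown", "left_shoulder", "right_shoulder", "left_hip",
                "right_hip", "left_knee", "right_knee", "left_ankle",
                "right_ankle", "left_heel", "right_heel")}
        return LandmarkSet(points=pts, source="synthetic_truth", success=True)

    def test_mm_conversion(self):
        fv = build_features(self._segments(), _detection(10.0), self._lms(), (1280, 960))
        assert fv["total_mm"] == pytest.approx(500.0)
        assert fv["ppm"] == pytest.approx(10.0)
        assert fv["scale_ratio"] == pytest.approx(1.0)

    def test_nonpositive_ppm_rejected(self):
        with pytest.raises(ValueError):
            build_features(self._segments(), _detection(0.0), self._lms(), (10, 10))

    def test_resolution_independence(self):
        """Doubling focal length and image size leaves mm features unchanged."""
        base = GeneratorConfig()
        hi = GeneratorConfig(focal_px=2 * base.focal_px,
                             image_size_px=(2 * base.image_size_px[0],
                                            2 * base.image_size_px[1]))
        rows = []
        for cfg in (base, hi):
            scene = bl.generate_cohort(1, 1, seed=55, config=cfg)[0]
            row, reason = bl.model.extract_image_row(
                scene, bl.SyntheticLandmarkProvider(0.0)
            )
            assert reason is None
            rows.append(row)
        assert rows[1]["total_mm"] == pytest.approx(rows[0]["total_mm"], rel=0.01)
        assert rows[1]["ppm"] == pytest.approx(2 * rows[0]["ppm"], rel=0.01)

    def test_clean_scene_chain_near_true_length(self, clean_records, clean_cohort):
        truth = {s.truth.image_id: s.truth.participant.true_length_mm
                 for s in clean_cohort}
        for row in clean_records.itertuples():
            assert row.total_mm == pytest.approx(truth[row.image_id], rel=0.02)


class TestFoldAssignment:
    def test_equal_participants_split_evenly(self):
        parts = [(f"P{i}", 500.0 + i, 6) for i in range(10)]
        fa = assign_folds(parts, k=5, seed=0)
        counts = np.bincount(list(fa.folds.values()), minlength=5)
        assert (counts == 2).all()

    def test_study_scale_cohort_meets_invariants(self):
        rng = np.random.default_rng(11)
        parts = [(f"P{i:03d}", float(rng.uniform(450, 850)), 6) for i in range(215)]
        fa = assign_folds(parts, k=5, seed=1)
        stats = validate_folds(fa, parts)
        assert stats["participant_spread"] <= 1
        assert stats["image_imbalance"] <= 0.20
        assert stats["ks_max"] <= 0.25

    def test_unequal_image_counts_still_balance(self):
        rng = np.random.default_rng(12)
        parts = [(f"P{i:03d}", float(rng.uniform(450, 850)),
                  int(rng.integers(3, 13))) for i in range(100)]
        fa = assign_folds(parts, k=5, seed=2)
        validate_folds(fa, parts)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            assign_folds([("a", 500.0, 6)], k=5)

    def test_deterministic(self):
        parts = [(f"P{i}", 500.0 + 3 * i, 6) for i in range(23)]
        assert assign_folds(parts, 5, seed=3).folds == assign_folds(parts, 5, seed=3).folds

    def test_no_participant_straddles_folds_in_cv(self, clean_records, participants):
        fa = assign_folds(participants, k=5, seed=0)
        cv = cross_validate(clean_records, fa, seed=0)
        for f, chunk in cv.groupby("fold"):
            val_pids = set(chunk["participant_id"])
            train_pids = {p for p, fold in fa.folds.items() if fold != f}
            assert not (val_pids & train_pids)


class TestTwoStepTraining:
    def test_ten_rows_retain_at_least_nine(self):
        frame = _feature_frame(10, seed=1)
        model = fit_two_step(frame, frame["measured_mm"], seed=0)
        assert model.n_train_step2 >= 9

    def test_gross_outlier_is_trimmed(self):
        frame = _feature_frame(60, seed=2, outlier_mm=300.0)
        model = fit_two_step(frame, frame["measured_mm"], seed=5)
        assert 0 not in model.retained_indices

    def test_trimming_inert_on_clean_linear_data(self):
        """With uniformly small errors, step-2 barely differs from step-1."""
        frame = _feature_frame(400, seed=3)
        config = ModelConfig(features=("total_mm",))
        two_step = fit_two_step(frame, frame["measured_mm"], config, seed=0)
        one_step = fit_two_step(
            frame, frame["measured_mm"],
            ModelConfig(features=("total_mm",), trim_percentile=100.0), seed=0,
        )
        grid = _feature_frame(200, seed=4)
        diff = np.abs(two_step.predict(grid) - one_step.predict(grid))
        assert diff.mean() < 1.0

    def test_bagged_prediction_is_member_mean(self, trained_model, clean_records):
        X = clean_records.head(20)
        members = trained_model.member_predictions(X)
        np.testing.assert_allclose(trained_model.predict(X), members.mean(axis=0))

    def test_trimming_does_not_worsen_training_error(self):
        """The final model's training MAE (on the rows it trained on) never
        exceeds the step-1 model's training MAE on the full, outlier-laden
        training set."""
        for seed in range(8):
            frame = _feature_frame(300, seed=60 + seed, outlier_mm=250.0)
            config = ModelConfig(features=("total_mm",))
            model = fit_two_step(frame, frame["measured_mm"], config, seed=seed)
            step1 = fit_two_step(
                frame, frame["measured_mm"],
                ModelConfig(features=("total_mm",), trim_percentile=100.0),
                seed=seed,
            )
            kept = frame.iloc[model.retained_indices]
            mae2 = np.abs(
                model.predict(kept) - kept["measured_mm"].to_numpy()
            ).mean()
            mae1 = np.abs(
                step1.predict(frame) - frame["measured_mm"].to_numpy()
            ).mean()
            assert mae2 <= mae1 + 1e-9

    def test_too_few_rows_rejected(self):
        frame = _feature_frame(5, seed=7)
        with pytest.raises(ValueError):
            fit_two_step(frame, frame["measured_mm"])


class TestHPO:
    def _records(self, seed, n_participants=30, images_each=4):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_participants):
            y = float(rng.uniform(450, 850))
            for j in range(images_each):
                row = {name: float(rng.normal()) for name in FEATURE_NAMES}
                row["total_mm"] = y + float(rng.normal(0, 3))
                row.update(participant_id=f"P{i:03d}", image_id=f"P{i:03d}_{j}",
                           measured_mm=y, any_warning=False)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_budget_one_returns_single_trial(self):
        records = self._records(1)
        parts = [(p, float(g["measured_mm"].iloc[0]), len(g))
                 for p, g in records.groupby("participant_id")]
        fa = assign_folds(parts, 5, seed=0)
        config, objective, trials = hpo_search(records, fa, budget=1, seed=0)
        assert len(trials) == 1
        assert config == trials[0].config

    def test_returned_config_is_argmin(self):
        records = self._records(2)
        parts = [(p, float(g["measured_mm"].iloc[0]), len(g))
                 for p, g in records.groupby("participant_id")]
        fa = assign_folds(parts, 5, seed=0)
        _, objective, trials = hpo_search(records, fa, budget=8, seed=1)
        assert objective == min(t.objective_mae_mm for t in trials)

    def test_informative_feature_is_selected(self):
        """The single informative feature survives random-subset HPO."""
        hits = 0
        for seed in range(6):
            records = self._records(100 + seed)
            parts = [(p, float(g["measured_mm"].iloc[0]), len(g))
                     for p, g in records.groupby("participant_id")]
            fa = assign_folds(parts, 5, seed=seed)
            config, _, _ = hpo_search(records, fa, budget=25, seed=seed)
            hits += "total_mm" in (config.features or FEATURE_NAMES)
        assert hits >= 5

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            hpo_search(pd.DataFrame(), None, budget=0)


class TestPredictionGating:
    def test_occluded_scene_reports_pose_failure(self, trained_model):
        scene = generate_cohort(1, 1, seed=71,
                                defect_rates={"occluded_part": 1.0})[0]
        rec = bl.predict_image(scene, trained_model)
        assert rec.predicted_mm is None
        assert rec.failure_reason == "pose_failure"

    def test_cardless_scene_reports_card_failure(self, trained_model):
        scene = generate_cohort(1, 1, seed=72)[0]
        px = scene.pixels.copy()
        px[:, :, 2] = px[:, :, 0]  # erase the card's colour signature
        scene = bl.SceneImage(scene.truth, px)
        rec = bl.predict_image(scene, trained_model)
        assert rec.predicted_mm is None
        assert rec.failure_reason == "card_failure"

    def test_clean_scene_predicts_without_warnings(self, trained_model):
        scene = generate_cohort(1, 1, seed=73)[0]
        rec = bl.predict_image(scene, trained_model)
        assert rec.failure_reason is None
        assert np.isfinite(rec.predicted_mm)
        assert rec.warnings.any is False
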