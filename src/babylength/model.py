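"""Bagged body-length regression with outlier-trimmed two-step training.

The model maps per-image quantitative features (card-calibrated segment
lengths in mm, the pixel-per-metric value and its width/height consistency,
landmark confidence, image size) to total body length in millimetres.

Training protocol:

* grouped, length-stratified 5-fold cross-validation — all of one child's
  images stay in a single fold, folds hold similar numbers of children and
  images, and similar length distributions;
* only warning-free images are used for training;
* two-step fit — a bagged ensemble is trained on all training rows, rows
  within the 90th percentile of training absolute error are retained, and
  the ensemble is refitted on the retained rows so gross outliers cannot
  steer the final model;
* hyperparameter optimisation by seeded random search, each trial sampling
  hyperparameters plus a random feature subset and scored by the mean
  warning-free validation MAE across folds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingRegressor,
    GradientBoostingRegressor,
)
from sklearn.tree import DecisionTreeRegressor

from .card import CardDetection, CardSpec, detect_card
from .flags import WarningConfig, WarningSet, evaluate_warnings
from .landmarks import (
    LandmarkProvider,
    LandmarkSet,
    SegmentLengths,
    SyntheticLandmarkProvider,
    extract_landmarks,
    segment_lengths,
)
from .synthetic import SEGMENTS, SceneImage

FEATURE_NAMES: tuple[str, ...] = (
    *(f"{seg}_mm" for seg in SEGMENTS),
    "total_mm",
    "ppm",
    "scale_ratio",
    "confidence_mean",
    "image_diag_px",
)


@dataclass(frozen=True)
class FeatureVector:
    """Per-image quantitative features for the length model."""

    values: tuple[float, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]


def build_features(
    segments: SegmentLengths,
    detection: CardDetection,
    landmarks: LandmarkSet,
    image_size_px: tuple[int, int],
) -> FeatureVector:
    """Assemble the feature vector for one successfully processed image.

    Segment pixel lengths are converted to millimetres with the card's
    pixel-per-metric value; the raw calibration quantities are kept so the
    model can reweight or correct them.
    """
    ppm = detection.pixel_per_metric
    if not np.isfinite(ppm) or ppm <= 0:
        raise ValueError("pixel_per_metric must be positive")
    seg_mm = [segments.lengths_px[s] / ppm for s in SEGMENTS]
    w, h = image_size_px
    values = (
        *seg_mm,
        segments.total_px / ppm,
        ppm,
        detection.scale_w / detection.scale_h,
        landmarks.mean_confidence(),
        float(np.hypot(w, h)),
    )
    return FeatureVector(values=tuple(float(v) for v in values))


# --------------------------------------------------------------------------
# Fold assignment
# --------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Participant -> fold map for grouped stratified cross-validation."""

    folds: dict[str, int]
    k: int

    def fold_of(self, participant_id: str) -> int:
        return self.folds[participant_id]


def assign_folds(
    participants: Sequence[tuple[str, float, int]],
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Grouped, length-stratified fold assignment.

    ``participants`` holds (id, measured_mm, n_images).  Children are sorted
    by measured length and dealt to folds in snake order, which balances
    participant counts to within one and interleaves the length
    distributions; a local swap pass then evens out per-fold image counts
    without moving any child across a large length gap.

    Raises
    ------
    ValueError
        with fewer participants than folds.
    """
    if len(participants) < k:
        raise ValueError("need at least k participants")
    rng = np.random.default_rng(seed)
    order = sorted(
        range(len(participants)),
        key=lambda i: (participants[i][1], participants[i][0]),
    )
    folds: dict[str, int] = {}
    for rank, idx in enumerate(order):
        cycle, pos = divmod(rank, k)
        f = pos if cycle % 2 == 0 else k - 1 - pos
        folds[participants[idx][0]] = f

    # Local swaps between length-adjacent children to balance image counts.
    n_images = {pid: n for pid, _, n in participants}
    ids_sorted = [participants[i][0] for i in order]
    for _ in range(4 * len(participants)):
        counts = np.zeros(k)
        for pid, f in folds.items():
            counts[f] += n_images[pid]
        hi, lo = int(np.argmax(counts)), int(np.argmin(counts))
        if counts[hi] - counts[lo] <= 1:
            break
        best = None
        for a, b in zip(ids_sorted[:-1], ids_sorted[1:]):
            fa, fb = folds[a], folds[b]
            if {fa, fb} != {hi, lo}:
                continue
            delta = (n_images[a] - n_images[b]) * (1 if fa == hi else -1)
            if delta > 0 and (best is None or delta > best[0]):
                best = (delta, a, b)
        if best is None:
            break
        _, a, b = best
        folds[a], folds[b] = folds[b], folds[a]
    del rng  # deterministic; retained for interface stability
    return FoldAssignment(folds=folds, k=k)


def validate_folds(
    assignment: FoldAssignment,
    participants: Sequence[tuple[str, float, int]],
    max_ks_distance: float = 0.25,
    max_image_imbalance: float = 0.20,
) -> dict[str, float]:
    """Check the fold invariants; returns the measured statistics.

    Raises
    ------
    ValueError
        if any invariant is violated.
    """
    k = assignment.k
    lengths = {pid: m for pid, m, _ in participants}
    images = {pid: n for pid, _, n in participants}
    by_fold: list[list[str]] = [[] for _ in range(k)]
    for pid, _, _ in participants:
        by_fold[assignment.fold_of(pid)].append(pid)
    p_counts = np.array([len(f) for f in by_fold])
    if p_counts.max() - p_counts.min() > 1:
        raise ValueError("participant counts differ by more than 1")
    i_counts = np.array([sum(images[p] for p in f) for f in by_fold])
    imbalance = float(np.abs(i_counts - i_counts.mean()).max() / i_counts.mean())
    if imbalance > max_image_imbalance:
        raise ValueError(f"per-fold image counts off by {imbalance:.1%}")
    pooled = np.array([lengths[p] for p, _, _ in participants])
    ks_max = 0.0
    for f in by_fold:
        stat = ks_2samp(np.array([lengths[p] for p in f]), pooled).statistic
        ks_max = max(ks_max, float(stat))
    if ks_max > max_ks_distance:
        raise ValueError(f"fold length distribution KS distance {ks_max:.3f}")
    return {
        "participant_spread": float(p_counts.max() - p_counts.min()),
        "image_imbalance": imbalance,
        "ks_max": ks_max,
    }


# --------------------------------------------------------------------------
# Two-step bagged training
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the bagged length regressor."""

    member: str = "tree"  # "tree" or "gbm" base regressors under bagging
    n_members: int = 30
    max_depth: int | None = None
    learning_rate: float = 0.1  # gbm members only
    gbm_n_estimators: int = 100  # gbm members only
    features: tuple[str, ...] | None = None  # None = all features
    trim_percentile: float = 90.0
    aggregate: str = "mean"  # "mean" or "median" over ensemble members


def _base_estimator(config: ModelConfig, seed: int):
    if config.member == "tree":
        return DecisionTreeRegressor(max_depth=config.max_depth, random_state=seed)
    if config.member == "gbm":
        return GradientBoostingRegressor(
            max_depth=config.max_depth or 3,
            learning_rate=config.learning_rate,
            n_estimators=config.gbm_n_estimators,
            random_state=seed,
        )
    raise ValueError(f"unknown member type: {config.member}")


@dataclass
class TrainedModel:
    """A fitted bagged ensemble plus its training provenance."""

    ensemble: BaggingRegressor
    features: tuple[str, ...]
    config: ModelConfig
    seed: int
    n_train_step1: int
    n_train_step2: int
    trim_threshold_mm: float
    retained_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def _matrix(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[list(self.features)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def member_predictions(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """(n_members, n_rows) predictions of the individual members."""
        m = self._matrix(X)
        return np.stack([est.predict(m) for est in self.ensemble.estimators_])

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Aggregate ensemble prediction in millimetres."""
        members = self.member_predictions(X)
        if self.config.aggregate == "median":
            return np.median(members, axis=0)
        return members.mean(axis=0)


def fit_two_step(
    X: pd.DataFrame,
    y: Sequence[float],
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> TrainedModel:
    """Fit the bagged model with 90th-percentile outlier trimming.

    Step 1 fits the ensemble on all rows and computes each row's training
    absolute error.  Rows at or below the 90th percentile of that error
    (linear-interpolation percentile, boundary inclusive) are retained and
    the ensemble refitted on them, so label or extraction outliers do not
    shape the final fit.

    Raises
    ------
    ValueError
        if fewer than 10 training rows are supplied or the retained set
        would be empty.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 training rows")
    feats = config.features or FEATURE_NAMES
    mat = X[list(feats)].to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    def make(seed_: int) -> BaggingRegressor:
        return BaggingRegressor(
            estimator=_base_estimator(config, seed_),
            n_estimators=config.n_members,
            random_state=seed_,
        )

    step1 = make(s1).fit(mat, y)
    ae = np.abs(step1.predict(mat) - y)
    threshold = float(np.percentile(ae, config.trim_percentile))
    keep = ae <= threshold
    if not keep.any():
        raise ValueError("trimming retained no rows")
    step2 = make(s2).fit(mat[keep], y[keep])
    del s3  # reserved for future stochastic stages
    return TrainedModel(
        ensemble=step2,
        features=tuple(feats),
        config=config,
        seed=seed,
        n_train_step1=len(y),
        n_train_step2=int(keep.sum()),
        trim_threshold_mm=threshold,
        retained_indices=np.nonzero(keep)[0],
    )


# --------------------------------------------------------------------------
# Cross-validation and HPO
# --------------------------------------------------------------------------


def cross_validate(
    records: pd.DataFrame,
    assignment: FoldAssignment,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped cross-validated predictions on warning-free images.

    ``records`` must carry ``participant_id``, ``measured_mm``, the feature
    columns, and a boolean ``any_warning``.  For each fold a model is
    trained on the warning-free rows of the other folds (two-step protocol)
    and predicts the warning-free rows of the held-out fold.  Returns the
    input rows restricted to validation predictions, with ``predicted_mm``
    and ``fold`` columns added.
    """
    out = []
    ss = np.random.SeedSequence([seed, 5])
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(assignment.k)]
    fold_col = records["participant_id"].map(assignment.fold_of)
    usable = ~records["any_warning"]
    for f in range(assignment.k):
        train = records[usable & (fold_col != f)]
        val = records[usable & (fold_col == f)]
        if val.empty:
            continue
        model = fit_two_step(
            train, train["measured_mm"], config, seed=fold_seeds[f]
        )
        chunk = val.copy()
        chunk["predicted_mm"] = model.predict(val)
        chunk["fold"] = f
        out.append(chunk)
    if not out:
        raise ValueError("no validation predictions produced")
    return pd.concat(out, axis=0)


def validation_mae_mm(cv_predictions: pd.DataFrame) -> float:
    return float(
        np.abs(cv_predictions["measured_mm"] - cv_predictions["predicted_mm"]).mean()
    )


@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges for HPO (inclusive bounds)."""

    n_members: tuple[int, int] = (10, 60)
    max_depth_choices: tuple[int | None, ...] = (None, 4, 6, 8, 12)
    member_choices: tuple[str, ...] = ("tree",)
    min_features: int = 1


@dataclass
class Trial:
    config: ModelConfig
    objective_mae_mm: float


def hpo_search(
    records: pd.DataFrame,
    assignment: FoldAssignment,
    budget: int = 20,
    seed: int = 0,
    space: SearchSpace = SearchSpace(),
) -> tuple[ModelConfig, float, list[Trial]]:
    """Seeded random search over hyperparameters and feature subsets.

    Each trial samples a configuration plus a random feature subset and is
    scored by the mean warning-free validation MAE across the folds; the
    arg-min trial's configuration is returned together with its objective
    and the full trial log.

    Raises
    ------
    ValueError
        if ``budget < 1`` or every trial fails.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    trials: list[Trial] = []
    for t in range(budget):
        n_feat = int(rng.integers(space.min_features, len(FEATURE_NAMES) + 1))
        feats = tuple(
            sorted(rng.choice(len(FEATURE_NAMES), size=n_feat, replace=False))
        )
        config = ModelConfig(
            member=str(rng.choice(space.member_choices)),
            n_members=int(rng.integers(space.n_members[0], space.n_members[1] + 1)),
            max_depth=space.max_depth_choices[
                int(rng.integers(len(space.max_depth_choices)))
            ],
            features=tuple(FEATURE_NAMES[i] for i in feats),
        )
        try:
            cv = cross_validate(records, assignment, config, seed=seed + t)
            trials.append(Trial(config, validation_mae_mm(cv)))
        except ValueError:
            continue
    if not trials:
        raise ValueError("all HPO trials failed")
    best = min(trials, key=lambda tr: tr.objective_mae_mm)
    return best.config, best.objective_mae_mm, trials


# --------------------------------------------------------------------------
# Per-image prediction
# --------------------------------------------------------------------------


@dataclass
class PredictionRecord:
    """Outcome of the pipeline on one image."""

    participant_id: str
    image_id: str
    measured_mm: float
    predicted_mm: float | None = None
    failure_reason: str | None = None  # "card_failure" or "pose_failure"
    warnings: WarningSet | None = None

    def __post_init__(self) -> None:
        if (self.predicted_mm is None) == (self.failure_reason is None):
            raise ValueError(
                "exactly one of predicted_mm / failure_reason must be set"
            )


def extract_image_row(
    image: SceneImage,
    landmark_provider: LandmarkProvider | None = None,
    warning_config: WarningConfig = WarningConfig(),
    card: CardSpec = CardSpec(),
    detection: CardDetection | None = None,
) -> tuple[dict | None, str | None]:
    """Run card + pose extraction and feature assembly on one image.

    Returns ``(row, None)`` on success, where ``row`` holds ids, features
    and warning flags, or ``(None, reason)`` on an extraction failure.
    A precomputed ``detection`` may be passed to avoid re-running card
    detection when the same frame is processed repeatedly.
    """
    provider = landmark_provider or SyntheticLandmarkProvider()
    if detection is None:
        detection = detect_card(image, card)
    if not detection.success:
        return None, "card_failure"
    lms = extract_landmarks(image, provider)
    if not lms.success:
        return None, "pose_failure"
    segs = segment_lengths(lms)
    fv = build_features(segs, detection, lms, image.truth.camera.image_size_px)
    warnings = evaluate_warnings(detection, lms, warning_config, card)
    row = {
        "participant_id": image.truth.participant.participant_id,
        "image_id": image.truth.image_id,
        "measured_mm": image.truth.measured_length_mm,
        "true_mm": image.truth.participant.true_length_mm,
        **fv.as_dict(),
        "w0": warnings.w0_card_body_overlap,
        "w1": warnings.w1_card_aspect_ratio,
        "w2": warnings.w2_card_segmentation,
        "w3": warnings.w3_scale_mismatch,
        "any_warning": warnings.any,
    }
    return row, None


def extract_records(
    images: Sequence[SceneImage],
    landmark_provider: LandmarkProvider | None = None,
    warning_config: WarningConfig = WarningConfig(),
    card: CardSpec = CardSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract feature rows for a cohort; returns (rows, failures)."""
    rows, fails = [], []
    for image in images:
        row, reason = extract_image_row(
            image, landmark_provider, warning_config, card
        )
        if row is not None:
            rows.append(row)
        else:
            fails.append(
                {
                    "participant_id": image.truth.participant.participant_id,
                    "image_id": image.truth.image_id,
                    "measured_mm": image.truth.measured_length_mm,
                    "failure_reason": reason,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(fails)


def predict_image(
    image: SceneImage,
    model: TrainedModel,
    landmark_provider: LandmarkProvider | None = None,
    warning_config: WarningConfig = WarningConfig(),
    card: CardSpec = CardSpec(),
) -> PredictionRecord:
    """End-to-end prediction for one image.

    A length is returned only when both the card and the pose extraction
    succeed; otherwise the record carries the distinct failure reason
    (``card_failure`` / ``pose_failure``) and no length.
    """
    row, reason = extract_image_row(image, landmark_provider, warning_config, card)
    pid = image.truth.participant.participant_id
    if row is None:
        return PredictionRecord(
            participant_id=pid,
            image_id=image.truth.image_id,
            measured_mm=image.truth.measured_length_mm,
            failure_reason=reason,
        )
    frame = pd.DataFrame([row])
    pred = float(model.predict(frame)[0])
    return PredictionRecord(
        participant_id=pid,
        image_id=image.truth.image_id,
        measured_mm=image.truth.measured_length_mm,
        predicted_mm=pred,
        warnings=WarningSet(row["w0"], row["w1"], row["w2"], row["w3"]),
    )
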