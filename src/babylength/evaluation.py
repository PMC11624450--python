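"""Error metrics, participant averaging, warning sweep, and TEM benchmarks.

Internally lengths are in millimetres; every reported error statistic is in
centimetres (two-decimal reporting precision), the convention used for
infant anthropometry.  For image *i* with measured length m_i and predicted
length p_i:

    E_i   = m_i - p_i           (cm, signed error)
    AE_i  = |E_i|               (cm)
    APE_i = 100 * AE_i / m_i    (%)

Bias is the mean of E, MAE the mean of AE, MAPE the mean of APE; cumulative
fractions are reported at fixed AE cutoffs (<=1, 2, 5, 10 cm) and APE
cutoffs (<=2, 5, 10, 20 %).  Failures (no prediction) are excluded from the
means but counted by reason.

The TEM (technical error of measurement) is the standard duplicate-
measurement reliability index sqrt(sum d_i^2 / 2N); published interobserver
TEMs for length boards (WHO reference studies and general clinic /
community settings) serve as reporting benchmarks for the model's MAE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PredictionRecord

AE_CUTOFFS_CM = (1.0, 2.0, 5.0, 10.0)
APE_CUTOFFS_PCT = (2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class BenchmarkConstants:
    """Published interobserver TEMs (cm) used for reporting comparisons."""

    who_tems_cm: tuple[float, float] = (0.48, 0.70)
    clinic_tem_cm: float = 1.41
    community_tem_range_cm: tuple[float, float] = (1.25, 1.59)


@dataclass
class MetricsReport:
    """Aggregate error metrics over a set of predictions (cm / percent)."""

    n_images: int
    n_predicted: int
    bias_cm: float
    mae_cm: float
    mape_pct: float
    ae_cutoff_fractions: dict[float, float]
    ape_cutoff_fractions: dict[float, float]
    n_failures_by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        """False when there were no successful predictions to average."""
        return self.n_predicted > 0

    def as_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "n_predicted": self.n_predicted,
            "bias_cm": self.bias_cm,
            "mae_cm": self.mae_cm,
            "mape_pct": self.mape_pct,
            **{f"ae_le_{c:g}cm": v for c, v in self.ae_cutoff_fractions.items()},
            **{f"ape_le_{c:g}pct": v for c, v in self.ape_cutoff_fractions.items()},
            "failures": dict(self.n_failures_by_reason),
        }


@dataclass
class ParticipantAverage:
    participant_id: str
    n_images_used: int
    averaged_prediction_cm: float
    measured_cm: float


def _pairs_cm(records: list[PredictionRecord]) -> tuple[np.ndarray, np.ndarray]:
    ok = [r for r in records if r.predicted_mm is not None]
    m = np.array([r.measured_mm for r in ok]) / 10.0
    p = np.array([r.predicted_mm for r in ok]) / 10.0
    return m, p


def _metrics_from_pairs(
    m_cm: np.ndarray,
    p_cm: np.ndarray,
    n_images: int,
    failures: dict[str, int],
) -> MetricsReport:
    n_pred = len(m_cm)
    if n_pred == 0:
        return MetricsReport(
            n_images=n_images,
            n_predicted=0,
            bias_cm=float("nan"),
            mae_cm=float("nan"),
            mape_pct=float("nan"),
            ae_cutoff_fractions={c: float("nan") for c in AE_CUTOFFS_CM},
            ape_cutoff_fractions={c: float("nan") for c in APE_CUTOFFS_PCT},
            n_failures_by_reason=failures,
        )
    e = m_cm - p_cm
    ae = np.abs(e)
    ape = 100.0 * ae / m_cm
    return MetricsReport(
        n_images=n_images,
        n_predicted=n_pred,
        bias_cm=float(e.mean()),
        mae_cm=float(ae.mean()),
        mape_pct=float(ape.mean()),
        ae_cutoff_fractions={c: float((ae <= c).mean()) for c in AE_CUTOFFS_CM},
        ape_cutoff_fractions={
            c: float((ape <= c).mean()) for c in APE_CUTOFFS_PCT
        },
        n_failures_by_reason=failures,
    )


def error_metrics(records: list[PredictionRecord]) -> MetricsReport:
    """Aggregate per-image error metrics; failures counted separately."""
    failures: dict[str, int] = {}
    for r in records:
        if r.failure_reason is not None:
            failures[r.failure_reason] = failures.get(r.failure_reason, 0) + 1
    m, p = _pairs_cm(records)
    return _metrics_from_pairs(m, p, len(records), failures)


def participant_average(
    records: list[PredictionRecord], min_images: int = 9
) -> tuple[list[ParticipantAverage], MetricsReport]:
    """Average per-image predictions per child and recompute the metrics.

    Only children with at least ``min_images`` successful predictions
    contribute (unweighted mean of the image predictions, in image order
    independence).
    """
    groups: dict[str, list[PredictionRecord]] = {}
    for r in records:
        if r.predicted_mm is not None:
            groups.setdefault(r.participant_id, []).append(r)
    averages: list[ParticipantAverage] = []
    for pid in sorted(groups):
        preds = groups[pid]
        if len(preds) < min_images:
            continue
        averages.append(
            ParticipantAverage(
                participant_id=pid,
                n_images_used=len(preds),
                # sort before averaging so the result is exactly
                # independent of image processing order
                averaged_prediction_cm=float(
                    np.mean(np.sort([r.predicted_mm for r in preds])) / 10.0
                ),
                measured_cm=preds[0].measured_mm / 10.0,
            )
        )
    m = np.array([a.measured_cm for a in averages])
    p = np.array([a.averaged_prediction_cm for a in averages])
    return averages, _metrics_from_pairs(m, p, len(averages), {})


def warning_sweep(records: list[PredictionRecord]) -> pd.DataFrame:
    """Retention and MAE for every subset of ignored warning types.

    For each subset S of {W0, W1, W2, W3}, images whose warnings are all in
    S are retained; the empty subset is the "high-quality images only" row
    and the full subset uses every predicted image.  Returns a table with
    columns ``ignored`` (sorted "+"-joined subset, "" for none),
    ``n_retained``, ``fraction_retained`` (relative to predicted images),
    and ``mae_cm``.
    """
    predicted = [
        r for r in records if r.predicted_mm is not None and r.warnings is not None
    ]
    n_pred = len(predicted)
    names = ("W0", "W1", "W2", "W3")
    rows = []
    for r_size in range(5):
        for subset in itertools.combinations(names, r_size):
            s = frozenset(subset)
            kept = [r for r in predicted if r.warnings.as_set() <= s]
            m = np.array([r.measured_mm for r in kept]) / 10.0
            p = np.array([r.predicted_mm for r in kept]) / 10.0
            rows.append(
                {
                    "ignored": "+".join(sorted(s)),
                    "n_retained": len(kept),
                    "fraction_retained": len(kept) / n_pred if n_pred else float("nan"),
                    "mae_cm": float(np.abs(m - p).mean()) if kept else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def tem(duplicate_pairs: list[tuple[float, float]]) -> float:
    """Technical error of measurement over duplicate pairs (same unit in/out).

    TEM = sqrt( sum (m1 - m2)^2 / (2N) ).

    Raises
    ------
    ValueError
        on empty input.
    """
    if not duplicate_pairs:
        raise ValueError("need at least one duplicate pair")
    d = np.array([a - b for a, b in duplicate_pairs], dtype=float)
    return float(np.sqrt((d**2).sum() / (2 * len(d))))


def benchmark_report(
    metrics: MetricsReport, constants: BenchmarkConstants = BenchmarkConstants()
) -> pd.DataFrame:
    """Side-by-side comparison of MAE/bias with published TEM constants.

    Purely descriptive: each row states where the model's MAE sits relative
    to one published benchmark, with no pass/fail verdict.
    """
    mae = metrics.mae_cm
    rows = []
    for label, value in (
        ("WHO reference TEM", constants.who_tems_cm[0]),
        ("WHO reference TEM", constants.who_tems_cm[1]),
        ("general clinic TEM", constants.clinic_tem_cm),
    ):
        delta = mae - value
        rel = (
            f"below by {-delta:.2f}" if delta < 0 else f"above by {delta:.2f}"
        )
        rows.append(
            {"benchmark": label, "tem_cm": value, "mae_cm": mae,
             "bias_cm": metrics.bias_cm, "comparison": rel}
        )
    lo, hi = constants.community_tem_range_cm
    if mae < lo:
        rel = f"below range by {lo - mae:.2f}"
    elif mae > hi:
        rel = f"above range by {mae - hi:.2f}"
    else:
        rel = "within range"
    rows.append(
        {"benchmark": "community health TEM range",
         "tem_cm": f"{lo}-{hi}", "mae_cm": mae,
         "bias_cm": metrics.bias_cm, "comparison": rel}
    )
    return pd.DataFrame(rows)
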