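"""Error metrics, participant averaging, warning sweep, TEM, benchmarks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import babylength as bl
from babylength.evaluation import (
    AE_CUTOFFS_CM,
    APE_CUTOFFS_PCT,
    benchmark_report,
    error_metrics,
    participant_average,
    tem,
    warning_sweep,
)
from babylength.model import PredictionRecord

from conftest import make_prediction_records


def _rec(pid, m_cm, p_cm=None, reason=None, warnings=None, image="I0"):
    return PredictionRecord(
        participant_id=pid, image_id=f"{pid}_{image}",
        measured_mm=m_cm * 10.0,
        predicted_mm=None if p_cm is None else p_cm * 10.0,
        failure_reason=reason,
        warnings=warnings,
    )


class TestErrorMetrics:
    def test_two_record_arithmetic(self):
        records = [_rec("a", 60.0, 58.0), _rec("b", 50.0, 51.0)]
        rep = error_metrics(records)
        assert rep.bias_cm == pytest.approx(0.5)
        assert rep.mae_cm == pytest.approx(1.5)
        assert rep.mape_pct == pytest.approx((100 * 2 / 60 + 100 * 1 / 50) / 2)
        assert rep.ae_cutoff_fractions[1.0] == pytest.approx(0.5)
        assert rep.ae_cutoff_fractions[2.0] == pytest.approx(1.0)

    def test_failures_counted_not_averaged(self):
        records = [
            _rec("a", 60.0, 59.0),
            _rec("b", 55.0, reason="pose_failure"),
            _rec("c", 52.0, reason="card_failure", image="I1"),
            _rec("d", 58.0, reason="card_failure", image="I2"),
        ]
        rep = error_metrics(records)
        assert rep.n_predicted == 1
        assert rep.n_failures_by_reason == {"pose_failure": 1, "card_failure": 2}
        assert rep.mae_cm == pytest.approx(1.0)

    def test_no_predictions_flagged_undefined(self):
        rep = error_metrics([_rec("a", 60.0, reason="pose_failure")])
        assert not rep.defined
        assert np.isnan(rep.mae_cm)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        records = make_prediction_records(rng, 40, 10)
        rep = error_metrics(records)
        es = [(r.measured_mm - r.predicted_mm) / 10.0 for r in records]
        aes = [abs(e) for e in es]
        apes = [100 * a / (r.measured_mm / 10.0) for a, r in zip(aes, records)]
        assert rep.bias_cm == pytest.approx(sum(es) / len(es), rel=1e-12)
        assert rep.mae_cm == pytest.approx(sum(aes) / len(aes), rel=1e-12)
        assert rep.mape_pct == pytest.approx(sum(apes) / len(apes), rel=1e-12)
        for c in AE_CUTOFFS_CM:
            frac = sum(a <= c for a in aes) / len(aes)
            assert rep.ae_cutoff_fractions[c] == pytest.approx(frac, abs=1e-15)

    def test_cutoff_fractions_nondecreasing(self):
        rng = np.random.default_rng(7)
        rep = error_metrics(make_prediction_records(rng, 30, 8, noise_sd_mm=40.0))
        ae_vals = [rep.ae_cutoff_fractions[c] for c in AE_CUTOFFS_CM]
        ape_vals = [rep.ape_cutoff_fractions[c] for c in APE_CUTOFFS_PCT]
        assert ae_vals == sorted(ae_vals)
        assert ape_vals == sorted(ape_vals)
        assert abs(rep.bias_cm) <= rep.mae_cm


class TestParticipantAverage:
    def test_constant_predictions_average_to_value(self):
        records = [_rec("a", 61.0, 61.0, image=f"I{i}") for i in range(9)]
        averages, rep = participant_average(records, min_images=9)
        assert len(averages) == 1
        assert averages[0].averaged_prediction_cm == pytest.approx(61.0)
        assert rep.mae_cm == pytest.approx(0.0)

    def test_below_threshold_excluded(self):
        records = [_rec("a", 61.0, 60.0, image=f"I{i}") for i in range(8)]
        averages, rep = participant_average(records, min_images=9)
        assert averages == []
        assert not rep.defined

    def test_averaging_reduces_error(self):
        rng = np.random.default_rng(5)
        records = make_prediction_records(rng, 60, 12, noise_sd_mm=25.0)
        per_image = error_metrics(records)
        _, averaged = participant_average(records, min_images=9)
        assert averaged.mae_cm < per_image.mae_cm

    def test_image_order_invariance(self):
        rng = np.random.default_rng(6)
        records = make_prediction_records(rng, 10, 10)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a1, _ = participant_average(records)
        a2, _ = participant_average(shuffled)
        assert [(x.participant_id, x.averaged_prediction_cm) for x in a1] == [
            (x.participant_id, x.averaged_prediction_cm) for x in a2
        ]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        records = make_prediction_records(rng, 25, 11)
        averages, _ = participant_average(records, min_images=9)
        for avg in averages:
            preds = [r.predicted_mm / 10.0 for r in records
                     if r.participant_id == avg.participant_id
                     and r.predicted_mm is not None]
            assert avg.averaged_prediction_cm == pytest.approx(
                sum(preds) / len(preds), rel=1e-12
            )


class TestWarningSweep:
    def test_full_subset_retains_everything(self):
        rng = np.random.default_rng(9)
        table = warning_sweep(make_prediction_records(rng, 20, 6))
        full = table[table["ignored"] == "W0+W1+W2+W3"].iloc[0]
        assert full["fraction_retained"] == pytest.approx(1.0)

    def test_retention_monotone_in_ignored_set(self):
        rng = np.random.default_rng(10)
        table = warning_sweep(make_prediction_records(rng, 20, 6))
        frac = {frozenset(r["ignored"].split("+")) if r["ignored"] else frozenset():
                r["fraction_retained"] for _, r in table.iterrows()}
        for s1 in frac:
            for s2 in frac:
                if s1 <= s2:
                    assert frac[s1] <= frac[s2] + 1e-15

    def test_empty_subset_equals_warning_free_metrics(self):
        rng = np.random.default_rng(11)
        records = make_prediction_records(rng, 20, 6)
        table = warning_sweep(records)
        base = table[table["ignored"] == ""].iloc[0]
        clean = [r for r in records if r.warnings is not None and not r.warnings.any]
        rep = error_metrics(clean)
        assert base["mae_cm"] == pytest.approx(rep.mae_cm, rel=1e-12)
        assert base["n_retained"] == rep.n_predicted

    def test_noisier_flagged_images_raise_mae_when_ignored(self):
        rng = np.random.default_rng(12)
        records = []
        for i in range(40):
            m = float(rng.uniform(450, 850))
            for j in range(6):
                flagged = rng.random() < 0.4
                noise = rng.normal(0, 60.0 if flagged else 10.0)
                w = bl.WarningSet(flagged, False, False, False)
                records.append(PredictionRecord(
                    participant_id=f"P{i}", image_id=f"P{i}_{j}",
                    measured_mm=m, predicted_mm=m + noise, warnings=w))
        table = warning_sweep(records)
        mae_clean = table[table["ignored"] == ""].iloc[0]["mae_cm"]
        mae_all = table[table["ignored"] == "W0+W1+W2+W3"].iloc[0]["mae_cm"]
        assert mae_clean < mae_all


class TestTEM:
    def test_identical_pairs_zero(self):
        assert tem([(60.0, 60.0)] * 5) == 0.0

    def test_single_pair(self):
        assert tem([(61.0, 60.0)]) == pytest.approx(np.sqrt(0.5))

    def test_hand_computed_triple(self):
        pairs = [(60.3, 60.0), (55.0, 55.4), (70.5, 70.0)]
        assert tem(pairs) == pytest.approx(np.sqrt(0.50 / 6), rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tem([])


class TestBenchmarkReport:
    def _metrics(self, mae):
        rep = error_metrics([_rec("a", 60.0, 60.0 - mae)])
        return rep

    def test_above_community_range(self):
        table = benchmark_report(self._metrics(1.77))
        row = table[table["benchmark"] == "community health TEM range"].iloc[0]
        assert row["comparison"] == "above range by 0.18"

    def test_within_community_range(self):
        table = benchmark_report(self._metrics(1.30))
        row = table[table["benchmark"] == "community health TEM range"].iloc[0]
        assert row["comparison"] == "within range"

    def test_below_who_tem(self):
        table = benchmark_report(self._metrics(0.40))
        row = table[(table["benchmark"] == "WHO reference TEM")
                    & (table["tem_cm"] == 0.48)].iloc[0]
        assert row["comparison"].startswith("below")
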