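"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import babylength as bl


@pytest.fixture(scope="session")
def clean_cohort():
    """25 children x 4 defect-free scenes (lazy pixels)."""
    return bl.generate_cohort(25, 4, seed=101)


@pytest.fixture(scope="session")
def clean_records(clean_cohort):
    """Extracted feature rows for the clean cohort (renders 100 frames)."""
    records, failures = bl.extract_records(clean_cohort)
    assert failures.empty
    return records


@pytest.fixture(scope="session")
def trained_model(clean_records):
    usable = clean_records[~clean_records["any_warning"]]
    return bl.fit_two_step(usable, usable["measured_mm"], seed=7)


@pytest.fixture(scope="session")
def participants(clean_records):
    return [
        (pid, float(g["measured_mm"].iloc[0]), int(len(g)))
        for pid, g in clean_records.groupby("participant_id")
    ]


def make_prediction_records(
    rng: np.random.Generator,
    n_participants: int = 50,
    images_each: int = 12,
    noise_sd_mm: float = 15.0,
) -> list[bl.PredictionRecord]:
    """Random prediction records with zero-mean image noise and warnings."""
    records = []
    for i in range(n_participants):
        measured = float(rng.uniform(4500.0, 8500.0)) / 10.0
        for j in range(images_each):
            warn = bl.WarningSet(*(bool(rng.random() < 0.15) for _ in range(4)))
            records.append(
                bl.PredictionRecord(
                    participant_id=f"P{i:03d}",
                    image_id=f"P{i:03d}_I{j:02d}",
                    measured_mm=measured,
                    predicted_mm=measured + float(rng.normal(0, noise_sd_mm)),
                    warnings=warn,
                )
            )
    return records
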