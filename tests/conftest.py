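"""Shared fixtures: tiny deterministic cohorts and a small trained clock."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clockforge.clock import ClockConfig, split_cohort, train_clock
from clockforge.cohort import BiomarkerDescriptor, CohortTable, label_health
from clockforge.preprocess import PreprocessParams, encode_sex, preprocess_fit
from clockforge.simulate import SyntheticSpec, generate_cohort


def make_table(
    n: int = 40,
    markers: dict[str, np.ndarray] | None = None,
    ages: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    icd: list | None = None,
    atc: list | None = None,
    units: dict[str, str] | None = None,
) -> CohortTable:
    """Hand-rolled cohort table for unit tests."""
    rng = np.random.default_rng(0)
    if markers is None:
        markers = {
            "m1": rng.uniform(1, 5, n),
            "m2": rng.uniform(10, 50, n),
        }
    n = len(next(iter(markers.values())))
    frame = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "subject_id": [f"P{i:04d}" for i in range(n)],
            "age": rng.uniform(20, 80, n) if ages is None else np.asarray(ages, float),
            "sex": np.where(rng.random(n) < 0.5, "female", "male") if sex is None else sex,
            "collection_year": 2010,
            "icd_codes": icd if icd is not None else [frozenset()] * n,
            "atc_codes": atc if atc is not None else [frozenset()] * n,
            **markers,
        }
    )
    units = units or {}
    panel = [
        BiomarkerDescriptor(m, units.get(m, ""), int(frame[m].notna().sum()))
        for m in markers
    ]
    return CohortTable(frame, panel)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with diseases, labelled."""
    table, truth = generate_cohort(SyntheticSpec(n_subjects=1200, seed=5))
    return label_health(table), truth


@pytest.fixture(scope="session")
def small_clock_bundle(small_cohort):
    """A cheap trained clock + splits + corrector inputs, shared by unit tests."""
    table, _ = small_cohort
    healthy = table.healthy_subset()
    split = split_cohort(healthy, seed=6)
    parts = {
        p: healthy.with_frame(healthy.frame.loc[split.ids(p)].copy())
        for p in ("train", "validation", "test")
    }
    train_t, fitted, report = preprocess_fit(parts["train"], PreprocessParams(), seed=7)
    val_t = fitted.apply(encode_sex(parts["validation"]))
    test_t = fitted.apply(encode_sex(parts["test"]))
    clock = train_clock(
        ClockConfig(hidden_sizes=(32, 8), max_steps=200, batch_size=256, seed=8),
        train_t,
        val_t,
        preprocessor=fitted,
    )
    return {
        "table": table,
        "train": train_t,
        "validation": val_t,
        "test": test_t,
        "fitted": fitted,
        "clock": clock,
        "trim_report": report,
    }
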