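"""Synthetic cohort generator: validation, truth alignment, planted structure."""

import numpy as np
import pandas as pd
import pytest

from clockforge.simulate import (
    BiomarkerSpec,
    DiseaseSpec,
    SpecError,
    SyntheticSpec,
    gap_benchmark_spec,
    generate_cohort,
    generate_longitudinal,
    reduction_benchmark_spec,
    skew_benchmark_spec,
)


def test_spec_validation():
    with pytest.raises(SpecError, match="missing_rate"):
        SyntheticSpec(missing_rate=1.5).validate()
    with pytest.raises(SpecError, match="sex_ratio"):
        SyntheticSpec(sex_ratio=-0.1).validate()
    with pytest.raises(SpecError, match=">= 0"):
        SyntheticSpec(sigma_b=-1).validate()
    with pytest.raises(SpecError, match="prevalences"):
        SyntheticSpec(
            diseases=(DiseaseSpec("A", 0.6, 1.0), DiseaseSpec("B", 0.6, 1.0))
        ).validate()
    with pytest.raises(SpecError, match="samples_per_subject"):
        SyntheticSpec(samples_per_subject=0).validate()


def test_generate_cohort_shape_and_determinism():
    spec = SyntheticSpec(n_subjects=300, seed=1)
    t1, truth1 = generate_cohort(spec)
    t2, truth2 = generate_cohort(spec)
    assert t1.n_samples == 300
    pd.testing.assert_frame_equal(t1.frame, t2.frame)
    pd.testing.assert_frame_equal(truth1, truth2)
    t3, _ = generate_cohort(SyntheticSpec(n_subjects=300, seed=2))
    assert not t1.frame["age"].equals(t3.frame["age"])
    # schema essentials
    for col in ("sample_id", "age", "sex", "icd_codes", "death_event",
                "followup_years", "creatinine"):
        assert col in t1.frame.columns
    assert set(truth1.columns) >= {"sample_id", "delta", "disease",
                                   "delta_disease", "effective_age"}


def test_truth_aligns_with_table():
    table, truth = generate_cohort(SyntheticSpec(n_subjects=200, seed=3))
    assert list(table.frame["sample_id"]) == list(truth["sample_id"])
    np.testing.assert_allclose(
        truth["effective_age"],
        table.frame["age"] + truth["delta"] + truth["delta_disease"],
    )


def test_effective_age_plant_moves_biomarkers():
    # one noiseless marker with slope 1: value tracks effective age exactly
    spec = SyntheticSpec(
        n_subjects=500,
        biomarkers=(
            BiomarkerSpec("tracker", 0.0, 0.0, slope=1.0, noise_sd=0.0),
            BiomarkerSpec("other", 50.0, 50.0, slope=0.0, noise_sd=1.0),
        ),
        diseases=(DiseaseSpec("E11", 0.3, 10.0),),
        missing_rate=0.0,
        medicated_healthy_fraction=0.0,
        seed=4,
    )
    table, truth = generate_cohort(spec)
    np.testing.assert_allclose(table.frame["tracker"], truth["effective_age"])
    sick = truth["disease"] == "E11"
    assert sick.sum() == pytest.approx(150, abs=40)
    gap = (table.frame["tracker"] - table.frame["age"])[sick].mean() - (
        table.frame["tracker"] - table.frame["age"]
    )[~sick].mean()
    assert gap == pytest.approx(10.0, abs=1.5)


def test_missingness_rate_and_blocks():
    spec = SyntheticSpec(n_subjects=4000, missing_rate=0.22, seed=5)
    table, _ = generate_cohort(spec)
    frac = table.frame[table.biomarker_names].isna().mean().mean()
    assert frac == pytest.approx(0.22, abs=0.02)
    # block missingness: hdl and triglycerides share their block's drops
    hdl_na = table.frame["hdl"].isna()
    tri_na = table.frame["triglycerides"].isna()
    both = (hdl_na & tri_na).mean()
    assert both > 0.22 * 0.22 * 2  # far above independence


def test_no_missingness_when_rate_zero():
    table, _ = generate_cohort(SyntheticSpec(n_subjects=100, missing_rate=0.0, seed=6))
    assert table.frame[table.biomarker_names].notna().all().all()


def test_diseases_exclusive_and_coded():
    table, truth = generate_cohort(SyntheticSpec(n_subjects=3000, seed=7))
    assert (table.frame["icd_codes"].apply(len) <= 1).all()
    coded = table.frame["icd_codes"].apply(lambda s: next(iter(s), ""))
    assert (coded == truth["disease"]).all()
    # N18 multiplies creatinine: group mean clearly elevated
    n18 = truth["disease"] == "N18"
    assert table.frame.loc[n18.to_numpy(), "creatinine"].mean() > 1.25 * (
        table.frame.loc[(truth["disease"] == "").to_numpy(), "creatinine"].mean()
    )


def test_disease_age_range_applied():
    table, truth = generate_cohort(gap_benchmark_spec(seed=8, n_subjects=2000))
    sick = (truth["disease"] != "").to_numpy()
    ages = table.frame["age"].to_numpy()
    assert ages[sick].min() >= 30.0 and ages[sick].max() <= 60.0
    assert ages[~sick].max() > 70.0


def test_mortality_monotone_in_offset():
    # large positive latent offsets must die more often than negative ones
    spec = SyntheticSpec(n_subjects=20000, sigma_b=10.0, diseases=(),
                         accident_hazard=0.0, seed=9)
    table, truth = generate_cohort(spec)
    hi = truth["delta"] > 5
    lo = truth["delta"] < -5
    assert table.frame.loc[hi.to_numpy(), "death_event"].mean() > \
        table.frame.loc[lo.to_numpy(), "death_event"].mean()
    assert (table.frame["followup_years"] <= spec.followup_years).all()


def test_longitudinal_drift_and_icd_timing():
    spec = SyntheticSpec(
        n_subjects=2000, samples_per_subject=3, drift_rate=1.0,
        drift_window=8.0, seed=10,
    )
    table, truth = generate_longitudinal(spec)
    assert table.n_samples == 6000
    pre = (truth["diagnosis_year"] >= 0) & (
        table.frame["collection_year"] < truth["diagnosis_year"]
    )
    post = (truth["diagnosis_year"] >= 0) & (
        table.frame["collection_year"] >= truth["diagnosis_year"]
    )
    # ICD codes appear only at/after diagnosis
    assert (table.frame.loc[pre.to_numpy(), "icd_codes"].apply(len) == 0).all()
    assert (table.frame.loc[post.to_numpy(), "icd_codes"].apply(len) == 1).all()
    # drift ramps linearly toward diagnosis: drift_rate * (window - tau)
    tau = (truth["diagnosis_year"] - table.frame["collection_year"]).to_numpy(float)
    in_ramp = pre.to_numpy() & (tau <= 8.0)
    np.testing.assert_allclose(
        truth["drift"].to_numpy()[in_ramp], 1.0 * (8.0 - tau[in_ramp])
    )
    far = pre.to_numpy() & (tau > 8.0)
    assert (truth["drift"].to_numpy()[far] == 0.0).all()
    assert (truth["drift"].to_numpy()[post.to_numpy()] == 8.0).all()
    never = (truth["diagnosis_year"] < 0).to_numpy()
    assert (truth["drift"].to_numpy()[never] == 0.0).all()


def test_longitudinal_validation():
    with pytest.raises(SpecError, match="samples_per_subject"):
        generate_longitudinal(SyntheticSpec(n_subjects=10, samples_per_subject=1))
    with pytest.raises(SpecError, match="drift_window"):
        generate_longitudinal(
            SyntheticSpec(n_subjects=10, samples_per_subject=2,
                          year_range=(2015, 2020), drift_window=8.0)
        )


def test_benchmark_specs():
    s = skew_benchmark_spec(seed=1)
    assert s.n_subjects == 20000 and s.diseases == ()
    g = gap_benchmark_spec(seed=1)
    assert len(g.diseases) == 1 and g.diseases[0].delta_years == 5.0
    assert g.disease_age_range == (30.0, 60.0)
    r = reduction_benchmark_spec(seed=1)
    names = [b.name for b in r.biomarkers]
    assert names[:3] == ["creatinine", "hba1c", "triglycerides"]
    assert len(names) == 20 and r.missing_rate == 0.0
    for spec in (s, g, r):
        spec.validate()
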