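"""Cohort I/O, health labeling, panel selection, harmonization."""

import numpy as np
import pandas as pd
import pytest

from clockforge.cohort import (
    BiomarkerDescriptor,
    CohortTable,
    EmptySelectionError,
    HarmonizationError,
    RowError,
    SchemaError,
    apply_selection,
    harmonize_panels,
    label_health,
    read_cohort,
    scan_tradeoff,
    select_panel,
    subsample_balanced,
    write_cohort,
)

from conftest import make_table


def _write_csv(tmp_path, df, name="cohort.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def test_read_cohort_basic(tmp_path):
    df = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "age": [30.5, 40.0],
            "sex": ["female", "male"],
            "icd_codes": ["E11;I10", ""],
            "atc_codes": [None, "A10BA02"],
            "glucose": [90.0, None],
            "creatinine": [0.9, 1.1],
        }
    )
    table = read_cohort(_write_csv(tmp_path, df))
    assert table.n_samples == 2
    assert set(table.biomarker_names) == {"glucose", "creatinine"}
    assert table.frame.loc[0, "icd_codes"] == frozenset({"E11", "I10"})
    assert table.frame.loc[1, "icd_codes"] == frozenset()
    assert table.frame.loc[1, "atc_codes"] == frozenset({"A10BA02"})
    # subject_id defaults to sample_id
    assert list(table.frame["subject_id"]) == ["a", "b"]
    by_name = {b.name: b for b in table.panel}
    assert by_name["glucose"].n_measured == 1


def test_read_cohort_schema_mapping(tmp_path):
    df = pd.DataFrame(
        {
            "SubjID": ["a"],
            "AgeYears": [55],
            "Gender": ["male"],
            "glu": [100.0],
        }
    )
    table = read_cohort(
        _write_csv(tmp_path, df),
        schema={"sample_id": "SubjID", "age": "AgeYears", "sex": "Gender"},
    )
    assert table.frame.loc[0, "age"] == 55.0
    assert table.biomarker_names == ["glu"]


def test_read_cohort_missing_mapped_column(tmp_path):
    df = pd.DataFrame({"sample_id": ["a"], "age": [1], "sex": ["f"]})
    with pytest.raises(SchemaError, match="not found"):
        read_cohort(_write_csv(tmp_path, df), schema={"age": "no_such_col"})


def test_read_cohort_missing_mandatory(tmp_path):
    df = pd.DataFrame({"sample_id": ["a"], "sex": ["female"]})
    with pytest.raises(SchemaError, match="age"):
        read_cohort(_write_csv(tmp_path, df))


def test_read_cohort_bad_age(tmp_path):
    df = pd.DataFrame({"sample_id": ["a"], "age": ["old"], "sex": ["f"], "m": [1.0]})
    with pytest.raises(RowError, match="unparseable age"):
        read_cohort(_write_csv(tmp_path, df))


def test_read_cohort_negative_age(tmp_path):
    df = pd.DataFrame({"sample_id": ["a"], "age": [-3], "sex": ["f"], "m": [1.0]})
    with pytest.raises(RowError, match="negative"):
        read_cohort(_write_csv(tmp_path, df))


def test_read_cohort_duplicate_ids(tmp_path):
    df = pd.DataFrame(
        {"sample_id": ["a", "a"], "age": [1, 2], "sex": ["f", "m"], "m": [1.0, 2.0]}
    )
    with pytest.raises(RowError, match="duplicate"):
        read_cohort(_write_csv(tmp_path, df))


def test_read_cohort_explicit_biomarkers_warns_on_extra(tmp_path, caplog):
    df = pd.DataFrame(
        {
            "sample_id": ["a"],
            "age": [40],
            "sex": ["f"],
            "glucose": [90.0],
            "mystery": [7.0],
        }
    )
    with caplog.at_level("WARNING"):
        table = read_cohort(_write_csv(tmp_path, df), biomarker_columns=["glucose"])
    assert table.biomarker_names == ["glucose"]
    assert "mystery" not in table.frame.columns
    assert any("unmapped" in r.message for r in caplog.records)


def test_write_read_roundtrip(tmp_path):
    table = make_table(
        n=5,
        icd=[frozenset({"E11", "N18"})] + [frozenset()] * 4,
    )
    path = tmp_path / "out.csv"
    write_cohort(table, path)
    back = read_cohort(path, biomarker_columns=table.biomarker_names)
    assert back.n_samples == table.n_samples
    assert back.frame.loc[0, "icd_codes"] == frozenset({"E11", "N18"})
    np.testing.assert_allclose(
        back.frame["m1"].to_numpy(), table.frame["m1"].to_numpy()
    )


def test_label_health_rules():
    table = make_table(
        n=4,
        icd=[frozenset(), frozenset({"E11"}), frozenset(), frozenset()],
        atc=[
            frozenset(),
            frozenset(),
            frozenset({"C09AA05"}),  # chronic prefix C09
            frozenset({"J01CA04"}),  # antibiotic: not chronic
        ],
    )
    labelled = label_health(table)
    assert list(labelled.frame["healthy"]) == [True, False, False, True]
    # custom prefix set
    relabelled = label_health(table, chronic_atc_prefixes={"J01"})
    assert list(relabelled.frame["healthy"]) == [True, False, True, False]


def test_healthy_subset_requires_label():
    table = make_table(n=3)
    with pytest.raises(ValueError, match="label_health"):
        table.healthy_subset()


def test_panel_validation():
    frame = pd.DataFrame({"sample_id": ["a"], "age": [1.0], "sex": ["f"], "x": [1.0]})
    with pytest.raises(ValueError, match="missing from table"):
        CohortTable(frame, [BiomarkerDescriptor("nope")])
    with pytest.raises(ValueError, match="unique"):
        CohortTable(frame, [BiomarkerDescriptor("x"), BiomarkerDescriptor("x")])
    with pytest.raises(ValueError, match="n_measured"):
        BiomarkerDescriptor("x", n_measured=-1)


def test_select_panel_fixed_point():
    # m_rare observed in 20% of samples -> dropped at 30% presence;
    # s_poor then has 1 of 2 remaining markers -> below min 2 -> dropped.
    n = 10
    m_rare = np.full(n, np.nan)
    m_rare[:2] = 1.0
    m2 = np.ones(n)
    m3 = np.ones(n)
    m3[0] = np.nan  # sample 0 keeps only m2 after m_rare goes
    table = make_table(markers={"m_rare": m_rare, "m2": m2, "m3": m3})
    sel = select_panel(table, min_markers_per_sample=2, min_presence_fraction=0.3)
    assert set(sel.retained_panel) == {"m2", "m3"}
    assert sel.n_samples_retained == 9
    reduced = apply_selection(table, sel)
    assert reduced.n_samples == 9
    assert set(reduced.biomarker_names) == {"m2", "m3"}
    assert reduced.missing_fraction() == 0.0


def test_select_panel_empty_reports_last_nonempty():
    n = 6
    table = make_table(
        markers={"a": np.full(n, np.nan), "b": np.full(n, np.nan)}
    )
    with pytest.raises(EmptySelectionError) as err:
        select_panel(table, min_markers_per_sample=1, min_presence_fraction=0.5)
    assert err.value.last_nonempty is None


def test_scan_tradeoff_monotone():
    rng = np.random.default_rng(3)
    markers = {
        f"m{i}": np.where(rng.random(200) < 0.2 + 0.1 * i, np.nan, rng.random(200))
        for i in range(5)
    }
    table = make_table(markers=markers)
    sels = scan_tradeoff(table, presence_grid=[0.3, 0.6], count_grid=[1, 3])
    assert len(sels) >= 1
    # stricter presence cannot enlarge the panel at fixed count
    by_key = {
        (s.min_presence_fraction, s.min_markers_per_sample): s for s in sels
    }
    if (0.3, 1) in by_key and (0.6, 1) in by_key:
        assert len(by_key[(0.6, 1)].retained_panel) <= len(
            by_key[(0.3, 1)].retained_panel
        )


def test_harmonize_panels():
    t1 = make_table(markers={"glucose": np.ones(6), "alt": np.ones(6)},
                    units={"glucose": "mg/dL"})
    t2 = make_table(markers={"glucose": np.ones(4), "hdl": np.ones(4)},
                    units={"glucose": "mg/dL"})
    a, b = harmonize_panels(t1, t2, min_markers_per_sample=1)
    assert a.biomarker_names == ["glucose"]
    assert b.biomarker_names == ["glucose"]

    t3 = make_table(markers={"glucose": np.ones(4)}, units={"glucose": "mmol/L"})
    with pytest.raises(HarmonizationError, match="unit mismatch"):
        harmonize_panels(t1, t3, min_markers_per_sample=1)

    t4 = make_table(markers={"x": np.ones(4)})
    with pytest.raises(HarmonizationError, match="no common"):
        harmonize_panels(t1, t4, min_markers_per_sample=1)


def test_subsample_balanced_cap_and_determinism():
    ages = np.concatenate([np.full(30, 40.2), np.full(3, 41.5)])
    table = make_table(markers={"m": np.arange(33.0)}, ages=ages)
    sub1 = subsample_balanced(table, max_per_age_year=10, seed=9)
    sub2 = subsample_balanced(table, max_per_age_year=10, seed=9)
    years = np.floor(sub1.frame["age"]).astype(int)
    assert (years.value_counts() <= 10).all()
    assert (years == 41).sum() == 3  # under-cap year untouched
    assert list(sub1.frame["sample_id"]) == list(sub2.frame["sample_id"])


def test_refresh_counts_and_missing_fraction():
    m = np.array([1.0, np.nan, 3.0, np.nan])
    table = make_table(markers={"m": m, "k": np.ones(4)})
    assert table.missing_fraction() == pytest.approx(0.25)
    refreshed = table.refresh_counts()
    assert {b.name: b.n_measured for b in refreshed.panel} == {"m": 2, "k": 4}
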