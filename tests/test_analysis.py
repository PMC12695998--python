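"""Statistics: rank tests, Bonferroni, ANOVA, stratification, survival."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clockforge.analysis import (
    DIAGNOSIS_BINS,
    P_FLOOR,
    anova_groups,
    apply_survival_exclusions,
    bin_by_diagnosis_offset,
    bonferroni,
    bootstrap_median_ci,
    compare_groups,
    fit_hazard_models,
    mann_whitney,
    prefilter_hba1c,
    quantile_stratify,
    single_code_mask,
    survival_by_stratum,
    test_zero_median as zero_median,
)


def enumerate_mw_p(x, y):
    """Exhaustive two-sided Mann-Whitney p for tie-free samples."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp = pooled[list(comb)]
        rest = np.delete(pooled, list(comb))
        us.append(sum(1 for a in grp for b in rest if a > b))
    us = np.asarray(us)
    n = len(us)
    # two-sided: double the smaller tail of the symmetric U distribution
    lo = np.sum(us <= u_obs) / n
    hi = np.sum(us >= u_obs) / n
    return min(1.0, 2 * min(lo, hi))


def enumerate_wilcoxon_p(values):
    """Exhaustive two-sided signed-rank p for tie-free nonzero samples."""
    v = np.asarray(values, float)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(v)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    n = len(ws)
    lo = np.sum(ws <= w_obs) / n
    hi = np.sum(ws >= w_obs) / n
    return min(1.0, 2 * min(lo, hi))


def test_mann_whitney_matches_enumeration():
    rng = np.random.default_rng(0)
    for n1, n2 in [(3, 4), (5, 5), (6, 3)]:
        x = rng.normal(size=n1)
        y = rng.normal(loc=0.8, size=n2)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(enumerate_mw_p(x, y), abs=1e-12)


def test_mann_whitney_asymptotic_on_ties():
    x = np.array([1.0, 2.0, 2.0])
    y = np.array([2.0, 3.0])
    _, p = mann_whitney(x, y)  # ties force the asymptotic branch
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(ref.pvalue)


def test_wilcoxon_matches_enumeration():
    rng = np.random.default_rng(1)
    for n in (5, 7, 8):
        v = rng.normal(loc=0.5, size=n)
        res = zero_median(v)
        assert res["p"] == pytest.approx(enumerate_wilcoxon_p(v), abs=1e-12)


def test_wilcoxon_drops_zeros_and_degenerate(caplog):
    v = np.array([0.0, 0.0, 1.0, -2.0, 3.0])
    res = zero_median(v)
    assert res["n_used"] == 3
    with caplog.at_level("WARNING"):
        res0 = zero_median(np.zeros(4))
    assert res0["p"] == 1.0 and res0["n_used"] == 0
    with pytest.raises(ValueError):
        zero_median([])


def test_bonferroni_clamp():
    assert bonferroni(0.03, 2) == pytest.approx(0.06)
    assert bonferroni(0.4, 5) == 1.0
    assert bonferroni(0.0, 100) == 0.0


def test_bootstrap_median_ci_seeded():
    rng = np.random.default_rng(2)
    v = rng.normal(5, 2, 200)
    m1 = bootstrap_median_ci(v, seed=3)
    m2 = bootstrap_median_ci(v, seed=3)
    assert m1 == m2
    med, lo, hi = m1
    assert lo <= med <= hi
    assert bootstrap_median_ci([7.0]) == (7.0, 7.0, 7.0)


def test_compare_groups():
    rng = np.random.default_rng(14)
    ref = rng.normal(0, 1, 300)
    groups = {
        "shifted": rng.normal(3, 1, 80),
        "null": rng.normal(0, 1, 80),
        "empty": np.array([]),
    }
    comps = compare_groups(groups, ref, seed=5)
    by = {c.group: c for c in comps}
    assert set(by) == {"shifted", "null"}  # empty skipped
    assert by["shifted"].m == 2  # m defaults to non-empty group count
    assert by["shifted"].p_adjusted < 1e-6
    assert by["shifted"].ci_low <= by["shifted"].median <= by["shifted"].ci_high
    assert by["null"].p_adjusted > 0.05
    assert by["shifted"].p_adjusted == pytest.approx(
        min(1.0, 2 * by["shifted"].p_raw)
    )
    with pytest.raises(ValueError):
        compare_groups(groups, np.array([]))


def test_anova_oracle_and_degenerate():
    g = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]
    res = anova_groups(g)
    assert res["F"] == pytest.approx(3.0)
    ref = stats.f_oneway(*g)
    assert res["p"] == pytest.approx(ref.pvalue)
    # identical groups: F = 0, p = 1
    same = [np.array([1.0, 2.0])] * 3
    assert anova_groups(same) == {"F": 0.0, "p": 1.0}
    # zero within-group variance, nonzero between: F = inf, floored p
    res2 = anova_groups([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
    assert res2["F"] == np.inf and res2["p"] == P_FLOOR
    with pytest.raises(ValueError):
        anova_groups([np.array([1.0])])


def test_quantile_stratify():
    v = np.arange(100.0)
    labels = quantile_stratify(v, 5)
    assert set(labels) == {f"Q{i}" for i in range(1, 6)}
    counts = pd.Series(labels).value_counts()
    assert counts.max() - counts.min() <= 1
    # ties go to the lower stratum
    tied = quantile_stratify(np.array([1.0, 1.0, 1.0, 2.0]), 2)
    assert list(tied) == ["Q1", "Q1", "Q1", "Q2"]
    with pytest.raises(ValueError):
        quantile_stratify(np.arange(3.0), 5)


def test_bin_by_diagnosis_offset():
    assert bin_by_diagnosis_offset(2010, 2017) == "<=-5"
    assert bin_by_diagnosis_offset(2013, 2017) == "-4"
    assert bin_by_diagnosis_offset(2016, 2017) == "-1"
    assert bin_by_diagnosis_offset(2017, 2017) == "0"
    assert bin_by_diagnosis_offset(2018, 2017) == "+1"
    assert bin_by_diagnosis_offset(2030, 2017) == ">=+5"
    assert bin_by_diagnosis_offset(2010, np.nan) == "n/a"
    assert bin_by_diagnosis_offset(2010, None) == "n/a"
    for y in range(2000, 2040):
        assert bin_by_diagnosis_offset(y, 2020) in DIAGNOSIS_BINS + ("n/a",)


def test_prefilter_hba1c(caplog):
    frame = pd.DataFrame({"hba1c": [5.0, 6.5, 7.1, np.nan]})
    with caplog.at_level("WARNING"):
        kept, n_removed = prefilter_hba1c(frame)
    assert len(kept) == 1 and n_removed == 3
    assert kept["hba1c"].iloc[0] == 5.0
    with pytest.raises(KeyError):
        prefilter_hba1c(pd.DataFrame({"x": [1]}))


def test_single_code_mask():
    codes = pd.Series(
        [
            frozenset({"E11"}),
            frozenset({"E119"}),  # same 3-char category
            frozenset({"E11", "I10"}),
            frozenset({"I10"}),
            frozenset(),
        ]
    )
    only = single_code_mask(codes, "E11")
    assert list(only) == [True, True, False, False, False]
    com = single_code_mask(codes, "E11", allow_comorbidities=True)
    assert list(com) == [True, True, True, False, False]


def _toy_survival(n=400, beta=0.5, seed=6):
    rng = np.random.default_rng(seed)
    accel = rng.normal(0, 1, n)
    age = rng.uniform(40, 75, n)
    scale = np.exp(-beta * accel)
    t = rng.exponential(scale)
    event = (t < 2.0).astype(int)
    return pd.DataFrame(
        {
            "acceleration": accel,
            "age": age,
            "sex_code": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(25, 3, n),
            "followup_years": np.minimum(t, 2.0),
            "event": event,
            "death_cause_class": np.where(event == 1, "disease", ""),
        }
    )


def test_apply_survival_exclusions():
    df = _toy_survival(50)
    df.loc[0, "death_cause_class"] = "accident"
    df.loc[0, "event"] = 1
    df.loc[1, "age"] = 85.0
    df.loc[2, "age"] = 79.0  # exactly 79: retained
    out, info = apply_survival_exclusions(df)
    assert info["n_excluded_accidental"] == 1
    assert info["n_excluded_age"] == 1
    assert 79.0 in out["age"].values
    assert len(out) == 48


def test_fit_hazard_models_recovers_sign():
    df = _toy_survival(800, beta=0.5)
    res = fit_hazard_models(df)
    assert res["n_events"] > 100
    m1 = res["model_1"]
    assert m1["coef_ci_low"]["acceleration"] <= 0.5 <= m1["coef_ci_high"]["acceleration"]
    assert m1["hr"]["acceleration"] > 1.0
    # degenerate covariate is skipped, not fatal
    df2 = df.copy()
    df2["sex_code"] = 1.0
    res2 = fit_hazard_models(df2)
    assert "error" in res2["model_3"]
    with pytest.raises(ValueError, match="no events"):
        fit_hazard_models(df.assign(event=0))


def test_survival_by_stratum_ordering():
    df = _toy_survival(600, beta=0.8, seed=7)
    kept, _ = apply_survival_exclusions(df)
    strata = quantile_stratify(kept["acceleration"].to_numpy(), 4)
    out = survival_by_stratum(kept, strata, covariates=("age",))
    assert out["labels"] == ["Q1", "Q2", "Q3", "Q4"]
    assert out["monotone_ordering"] is True
    assert out["acceleration_coef"] > 0
    assert all(len(c) == len(out["times"]) for c in out["curves"].values())
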