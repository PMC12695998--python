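"""Downstream statistics on biological-age acceleration.

Group comparisons against the healthy test cohort (Mann-Whitney U with
Bonferroni correction, bootstrap CIs on medians), one-sample tests against a
zero median (Wilcoxon signed-rank), one-way ANOVA across strata, quantile
stratification (CRP quintiles, survival deciles), longitudinal alignment of
samples to the year of first diagnosis, and Cox proportional-hazards models of
mortality on acceleration with incremental covariate adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Smallest reportable p-value for degenerate (infinite-F) ANOVA inputs.
P_FLOOR = 5e-324

DIAGNOSIS_BINS = (
    "<=-5", "-4", "-3", "-2", "-1", "0", "+1", "+2", "+3", "+4", ">=+5"
)


@dataclass(frozen=True)
class GroupComparison:
    group: str
    n: int
    median: float
    ci_low: float
    ci_high: float
    test: str
    p_raw: float
    p_adjusted: float
    reference: str = "healthy_test"
    m: int = 1


def bootstrap_median_ci(
    values, seed: int = 0, n_boot: int = 2000, level: float = 0.95
) -> tuple[float, float, float]:
    """Median and percentile bootstrap CI (seeded, 2000 resamples by default)."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    if len(v) == 1:
        return med, med, med
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    meds = np.median(v[idx], axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(meds, [alpha, 1 - alpha])
    return med, float(lo), float(hi)


def mann_whitney(x, y, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples.

    Exact enumeration is used when both samples have at most ``exact_max_n``
    observations and there are no ties; the normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = (
        "exact"
        if tie_free and max(len(x), len(y)) <= exact_max_n
        else "asymptotic"
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    accel_by_group: dict[str, np.ndarray],
    reference: np.ndarray,
    m: int | None = None,
    seed: int = 0,
    n_boot: int = 2000,
) -> list[GroupComparison]:
    """Compare each group's acceleration to the healthy reference.

    Two-sided Mann-Whitney U per group vs the reference, Bonferroni-adjusted
    with ``m`` comparisons (defaults to the number of non-empty groups).
    Medians carry seeded bootstrap CIs. Empty groups are skipped with a warning.
    """
    reference = np.asarray(reference, dtype=float)
    if len(reference) == 0:
        raise ValueError("reference group is empty")
    groups = {k: np.asarray(v, dtype=float) for k, v in accel_by_group.items()}
    nonempty = {k: v for k, v in groups.items() if len(v) > 0}
    for k in groups:
        if k not in nonempty:
            logger.warning("group %r is empty; skipped", k)
    if m is None:
        m = len(nonempty)
    out = []
    for i, (label, vals) in enumerate(nonempty.items()):
        u, p = mann_whitney(vals, reference)
        med, lo, hi = bootstrap_median_ci(vals, seed=seed + i, n_boot=n_boot)
        out.append(
            GroupComparison(
                group=label,
                n=len(vals),
                median=med,
                ci_low=lo,
                ci_high=hi,
                test="mann-whitney-u",
                p_raw=p,
                p_adjusted=bonferroni(p, m),
                m=m,
            )
        )
    return out


def bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


def test_zero_median(values, exact_max_n: int = 25) -> dict:
    """Two-sided Wilcoxon signed-rank test of median == 0.

    Zeros are dropped (standard signed-rank convention); exact distribution
    for n <= ``exact_max_n`` after zero removal, normal approximation with
    continuity correction above. All-zero input returns p = 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty input")
    nz = v[v != 0]
    if len(nz) == 0:
        logger.warning("all values zero; signed-rank test degenerate, p = 1")
        return {"statistic": 0.0, "p": 1.0, "n_used": 0}
    method = "exact" if len(nz) <= exact_max_n else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "n_used": len(nz)}


def anova_groups(groups: list[np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA across groups of acceleration values."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    grand = np.concatenate(gs)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in gs)
    if ss_within == 0:
        if ss_between == 0:
            return {"F": 0.0, "p": 1.0}
        return {"F": np.inf, "p": P_FLOOR}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*gs)
    if ss_between == 0:
        return {"F": 0.0, "p": 1.0}
    return {"F": float(f), "p": float(max(p, P_FLOOR))}


def quantile_stratify(values, k: int) -> np.ndarray:
    """Assign population-quantile labels Q1..Qk; ties go to the lower stratum."""
    v = np.asarray(values, dtype=float)
    if k > len(v):
        raise ValueError(f"k={k} exceeds n={len(v)}")
    cuts = np.quantile(v, [i / k for i in range(1, k)])
    if len(cuts) and cuts[0] == cuts[-1] and np.all(v == v[0]):
        logger.warning("all values equal; single stratum Q1")
    ranks = np.sum(v[:, None] > cuts[None, :], axis=1)
    return np.array([f"Q{r + 1}" for r in ranks])


def bin_by_diagnosis_offset(sample_year, diagnosis_year) -> str:
    """Map (collection year - diagnosis year) to the longitudinal bin label.

    Negative offsets are pre-diagnosis; returns "n/a" when the diagnosis year
    is unknown.
    """
    if diagnosis_year is None or (
        isinstance(diagnosis_year, float) and np.isnan(diagnosis_year)
    ):
        return "n/a"
    offset = int(sample_year) - int(diagnosis_year)
    if offset <= -5:
        return "<=-5"
    if offset >= 5:
        return ">=+5"
    if offset < 0:
        return str(offset)
    if offset == 0:
        return "0"
    return f"+{offset}"


def prefilter_hba1c(
    frame: pd.DataFrame, threshold: float = 6.5, column: str = "hba1c"
) -> tuple[pd.DataFrame, int]:
    """Keep rows with HbA1c strictly below the diabetes threshold (6.5%).

    Rows with HbA1c at/above threshold are removed; rows with missing HbA1c
    are removed too (cannot certify) with a warning. Returns the filtered
    frame and the number of rows removed.
    """
    if column not in frame.columns:
        raise KeyError(f"column {column!r} not present")
    vals = frame[column]
    n_missing = int(vals.isna().sum())
    if n_missing:
        logger.warning("dropping %d rows with missing %s", n_missing, column)
    keep = vals.notna() & (vals < threshold)
    return frame[keep].copy(), int((~keep).sum())


def apply_survival_exclusions(
    df: pd.DataFrame,
    accidental_classes: set[str] = frozenset({"accident"}),
    max_age: float = 79.0,
) -> tuple[pd.DataFrame, dict]:
    """Drop accidental deaths and participants older than ``max_age``.

    Age ``max_age`` itself is retained (strictly older excluded).
    """
    accidental = df["death_cause_class"].isin(accidental_classes) & (
        df["event"] == 1
    )
    too_old = df["age"] > max_age
    out = df[~accidental & ~too_old].copy()
    return out, {
        "n_excluded_accidental": int(accidental.sum()),
        "n_excluded_age": int(too_old.sum()),
    }


DEFAULT_HAZARD_SPECS = (
    ("model_1", ("acceleration",)),
    ("model_2", ("acceleration", "age")),
    ("model_3", ("acceleration", "age", "sex_code")),
    ("model_4", ("acceleration", "age", "sex_code", "bmi")),
)


def fit_hazard_models(
    survival: pd.DataFrame,
    specs=DEFAULT_HAZARD_SPECS,
    accidental_classes: set[str] = frozenset({"accident"}),
    max_age: float = 79.0,
) -> dict:
    """Cox proportional-hazards fits with incremental covariate adjustment.

    ``survival`` needs columns: acceleration, age, sex_code, bmi (as used by
    the specs), followup_years, event (0/1), death_cause_class. Accidental
    deaths and participants older than ``max_age`` are excluded before
    fitting. Returns per-spec hazard ratios with 95% CIs plus exclusion counts.
    """
    from lifelines import CoxPHFitter

    df, exclusions = apply_survival_exclusions(survival, accidental_classes, max_age)
    if int(df["event"].sum()) == 0:
        raise ValueError("no events remain after exclusions; cannot fit")
    results = {"exclusions": exclusions, "n": len(df), "n_events": int(df["event"].sum())}
    for name, covs in specs:
        sub = df[list(covs) + ["followup_years", "event"]].dropna()
        degenerate = [c for c in covs if sub[c].nunique() <= 1]
        if degenerate:
            logger.warning("%s: constant covariates %s; skipped", name, degenerate)
            results[name] = {"error": f"constant covariates: {degenerate}"}
            continue
        cph = CoxPHFitter()
        cph.fit(sub, duration_col="followup_years", event_col="event")
        summ = cph.summary
        results[name] = {
            "coef": summ["coef"].to_dict(),
            "hr": summ["exp(coef)"].to_dict(),
            "hr_ci_low": summ["exp(coef) lower 95%"].to_dict(),
            "hr_ci_high": summ["exp(coef) upper 95%"].to_dict(),
            "coef_ci_low": summ["coef lower 95%"].to_dict(),
            "coef_ci_high": summ["coef upper 95%"].to_dict(),
            "p": summ["p"].to_dict(),
            "n": len(sub),
        }
    return results


def survival_by_stratum(
    survival: pd.DataFrame,
    strata: np.ndarray,
    covariates: tuple[str, ...] = ("age",),
    times: np.ndarray | None = None,
) -> dict:
    """Adjusted survival curves per acceleration stratum.

    Fits a single Cox model on continuous acceleration plus the covariates,
    then evaluates model-implied survival curves at each stratum's median
    acceleration (covariates held at their means) — the partial-effects view.
    Returns the curves, per-stratum event counts, and a monotonicity report
    (whether curve ordering follows stratum ordering). Strata without events
    are flagged.
    """
    from lifelines import CoxPHFitter

    df = survival.copy()
    df["_stratum"] = strata
    labels = sorted(pd.unique(df["_stratum"]), key=lambda s: int(str(s).lstrip("Q")))
    cols = ["acceleration", *covariates, "followup_years", "event"]
    fit_df = df[cols].dropna()
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="followup_years", event_col="event")
    if times is None:
        tmax = float(fit_df["followup_years"].max())
        times = np.linspace(0.0, tmax, 50)
    base = {c: float(fit_df[c].mean()) for c in covariates}
    curves = {}
    flagged = []
    for lab in labels:
        grp = df[df["_stratum"] == lab]
        if grp["event"].sum() == 0:
            flagged.append(lab)
        x = pd.DataFrame(
            [{**base, "acceleration": float(grp["acceleration"].median())}]
        )
        sf = cph.predict_survival_function(x, times=times)
        curves[lab] = sf.iloc[:, 0].to_numpy()
    # ordering check at the latest evaluated time: higher stratum -> lower survival
    finals = np.array([curves[lab][-1] for lab in labels])
    monotone = bool(np.all(np.diff(finals) <= 1e-12))
    return {
        "labels": labels,
        "times": np.asarray(times),
        "curves": curves,
        "monotone_ordering": monotone,
        "strata_without_events": flagged,
        "acceleration_coef": float(cph.summary.loc["acceleration", "coef"]),
    }


def single_code_mask(
    icd_sets: pd.Series, code: str, allow_comorbidities: bool = False
) -> pd.Series:
    """Samples carrying a given 3-character ICD category.

    With ``allow_comorbidities=False`` (the single-code isolation rule) the
    sample's ICD set must reduce to exactly this one 3-character category.
    """
    prefix = code[:3]

    def _match(codes: frozenset) -> bool:
        cats = {c[:3] for c in codes}
        if allow_comorbidities:
            return prefix in cats
        return cats == {prefix}

    return icd_sets.map(_match)
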