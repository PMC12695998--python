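"""Synthetic clinical-cohort generator with the structure the clock assumes.

Real hospital cohorts of this kind are proprietary, so every part of the
pipeline is exercised on generated tables with the same schema and the same
statistical structure: age- and sex-dependent biomarker means, a latent
per-subject biological-age offset delta ~ N(0, sigma_b^2) (years), disease
groups that shift the *effective age* (age + delta + Delta_disease) rather
than the raw outputs — so a planted offset is recoverable as a predicted-age
displacement by any consistent regressor — block missingness (~22% of cells),
and mortality whose hazard rises with age (Gompertz baseline) and with the
latent offset (log-hazard beta per year of delta), sampled by inversion.

Ground truth (per-sample delta, disease assignment, applied offsets) is
returned alongside the table and is never consumed by the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import BiomarkerDescriptor, CohortTable


class SpecError(ValueError):
    """The synthetic spec is internally inconsistent."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """value = base_sex + slope * effective_age + quad * (effective_age - 50)^2
    + N(0, noise_sd), floored at 0."""

    name: str
    base_female: float
    base_male: float
    slope: float = 0.0
    quad: float = 0.0
    noise_sd: float = 1.0
    units: str = ""


@dataclass(frozen=True)
class DiseaseSpec:
    """Exclusive disease assignment with an effective-age shift (years) and
    optional biomarker-specific multiplicative effects."""

    icd_code: str
    prevalence: float
    delta_years: float
    multipliers: dict = field(default_factory=dict)
    atc_code: str | None = None
    atc_probability: float = 0.5


#: Per-marker noise for informative markers is pinned at 9 age-equivalent
#: years (noise_sd = 9 * |slope|): individually weak-to-moderate age markers
#: whose 7-marker panel jointly determines effective age to about +/- 3.4 y.
_AGE_EQUIV_NOISE = 9.0


def default_biomarkers() -> tuple[BiomarkerSpec, ...]:
    informative = [
        BiomarkerSpec("creatinine", 0.55, 0.75, slope=0.004, noise_sd=0.036, units="mg/dL"),
        BiomarkerSpec("hba1c", 4.5, 4.55, slope=0.015, noise_sd=0.135, units="%"),
        BiomarkerSpec("alt", 38.0, 48.0, slope=-0.15, noise_sd=1.35, units="U/L"),
        BiomarkerSpec("hdl", 75.0, 62.0, slope=-0.12, noise_sd=1.08, units="mg/dL"),
        BiomarkerSpec("triglycerides", 60.0, 80.0, slope=0.9, noise_sd=8.1, units="mg/dL"),
        BiomarkerSpec("albumin", 4.9, 5.0, slope=-0.006, noise_sd=0.054, units="g/dL"),
        BiomarkerSpec("glucose", 72.0, 76.0, slope=0.25, noise_sd=2.25, units="mg/dL"),
    ]
    noise = [
        BiomarkerSpec(f"noise_{i:02d}", 10.0 + i, 10.5 + i, slope=0.0, noise_sd=2.0)
        for i in range(1, 14)
    ]
    return tuple(informative + noise)


def default_diseases() -> tuple[DiseaseSpec, ...]:
    """Diseases act through the effective-age shift; the kidney-disease entry
    additionally elevates creatinine specifically (its clinical signature),
    which makes it the planted answer for attribution-ranking checks."""
    return (
        DiseaseSpec("E11", 0.06, 5.0, {}, atc_code="A10BA02"),
        DiseaseSpec("N18", 0.04, 8.0, {"creatinine": 1.4}, atc_code="C09AA05"),
        DiseaseSpec("I10", 0.05, 3.0, {}, atc_code="C09AA05"),
        DiseaseSpec("D56", 0.01, -4.0, {}),
    )


#: Marker groups dropped together under block missingness (lab panels are
#: ordered and reported as blocks).
MISSINGNESS_BLOCKS = (
    ("hdl", "triglycerides"),
    ("alt", "albumin"),
    ("hba1c", "glucose"),
    ("creatinine",),
)


@dataclass(frozen=True)
class SyntheticSpec:
    n_subjects: int = 8000
    samples_per_subject: int = 1
    age_range: tuple[float, float] = (20.0, 80.0)
    disease_age_range: tuple[float, float] | None = None
    sex_ratio: float = 0.5  # fraction female
    sigma_b: float = 5.0  # sd of the latent biological-age offset, years
    biomarkers: tuple[BiomarkerSpec, ...] = field(default_factory=default_biomarkers)
    diseases: tuple[DiseaseSpec, ...] = field(default_factory=default_diseases)
    medicated_healthy_fraction: float = 0.03  # chronic meds, no ICD code
    missing_rate: float = 0.22
    block_missingness: bool = True
    year_range: tuple[int, int] = (2005, 2020)
    followup_years: float = 15.0
    gompertz_rate: float = 4e-5  # baseline hazard scale at age 0, per year
    gompertz_shape: float = 0.09  # log-hazard slope per year of age
    beta_acceleration: float = 0.05  # log-hazard per year of latent offset
    accident_hazard: float = 5e-4  # flat competing accidental-death hazard
    # longitudinal extras
    drift_rate: float = 1.0  # latent-offset rise, years per year pre-diagnosis
    drift_window: float = 8.0  # onset of pre-diagnosis drift, years
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.missing_rate <= 1:
            raise SpecError("missing_rate must be in [0, 1]")
        if not 0 <= self.sex_ratio <= 1:
            raise SpecError("sex_ratio must be in [0, 1]")
        if self.sigma_b < 0 or any(b.noise_sd < 0 for b in self.biomarkers):
            raise SpecError("sigma_b and noise sds must be >= 0")
        if sum(d.prevalence for d in self.diseases) > 1:
            raise SpecError("disease prevalences sum to > 1 (exclusive diseases)")
        if self.samples_per_subject < 1:
            raise SpecError("samples_per_subject must be >= 1")
        if self.drift_rate < 0 or self.drift_window < 0:
            raise SpecError("drift parameters must be >= 0")


def _biomarker_values(
    spec: SyntheticSpec, eff_age: np.ndarray, female: np.ndarray, rng
) -> dict[str, np.ndarray]:
    out = {}
    for b in spec.biomarkers:
        base = np.where(female, b.base_female, b.base_male)
        val = base + b.slope * eff_age + b.quad * (eff_age - 50.0) ** 2
        val = val + rng.normal(0.0, b.noise_sd, size=len(eff_age))
        out[b.name] = np.maximum(val, 0.0)
    return out


def _apply_missingness(
    spec: SyntheticSpec, values: dict[str, np.ndarray], rng
) -> dict[str, np.ndarray]:
    if spec.missing_rate == 0:
        return values
    n = len(next(iter(values.values())))
    out = {k: v.copy() for k, v in values.items()}
    grouped = set()
    if spec.block_missingness:
        for block in MISSINGNESS_BLOCKS:
            present = [m for m in block if m in out]
            if not present:
                continue
            drop = rng.random(n) < spec.missing_rate
            for m in present:
                out[m][drop] = np.nan
                grouped.add(m)
    for name in out:
        if name in grouped:
            continue
        drop = rng.random(n) < spec.missing_rate
        out[name][drop] = np.nan
    return out


def _mortality(
    spec: SyntheticSpec, age: np.ndarray, delta: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inversion-sampled event times from a Gompertz hazard with frailty.

    h(t) = rate * exp(shape * (age + t) + beta * delta); a flat accidental
    hazard competes. Returns (event 0/1, followup years, cause class).
    """
    n = len(age)
    b = spec.gompertz_shape
    lam = spec.gompertz_rate * np.exp(b * age + spec.beta_acceleration * delta)
    e = rng.exponential(1.0, size=n)
    t_disease = np.log1p(b * e / lam) / b
    t_accident = (
        rng.exponential(1.0 / spec.accident_hazard, size=n)
        if spec.accident_hazard > 0
        else np.full(n, np.inf)
    )
    t = np.minimum(np.minimum(t_disease, t_accident), spec.followup_years)
    event = (t < spec.followup_years).astype(int)
    cause = np.where(
        event == 0, "", np.where(t_accident < t_disease, "accident", "disease")
    )
    return event, t, cause


def _assign_diseases(spec: SyntheticSpec, n: int, rng) -> np.ndarray:
    """Exclusive disease assignment by prevalence; -1 = healthy."""
    u = rng.random(n)
    assign = np.full(n, -1)
    lo = 0.0
    for i, d in enumerate(spec.diseases):
        hi = lo + d.prevalence
        assign[(u >= lo) & (u < hi)] = i
        lo = hi
    return assign


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, pd.DataFrame]:
    """Generate a cross-sectional cohort table plus its ground-truth sidecar."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects * spec.samples_per_subject
    subj = np.repeat(np.arange(spec.n_subjects), spec.samples_per_subject)
    female_subj = rng.random(spec.n_subjects) < spec.sex_ratio
    delta_subj = rng.normal(0.0, spec.sigma_b, size=spec.n_subjects)
    disease_subj = _assign_diseases(spec, spec.n_subjects, rng)

    lo, hi = spec.age_range
    age_subj = rng.uniform(lo, hi, size=spec.n_subjects)
    if spec.disease_age_range is not None:
        dlo, dhi = spec.disease_age_range
        sick = disease_subj >= 0
        age_subj[sick] = rng.uniform(dlo, dhi, size=int(sick.sum()))

    age = age_subj[subj]
    female = female_subj[subj]
    delta = delta_subj[subj]
    disease = disease_subj[subj]

    delta_disease = np.zeros(n)
    for i, d in enumerate(spec.diseases):
        delta_disease[disease == i] = d.delta_years
    eff_age = age + delta + delta_disease

    values = _biomarker_values(spec, eff_age, female, rng)
    for i, d in enumerate(spec.diseases):
        mask = disease == i
        for marker, mult in d.multipliers.items():
            values[marker][mask] *= mult
    values = _apply_missingness(spec, values, rng)

    icd, atc = [], []
    medicated = rng.random(n) < spec.medicated_healthy_fraction
    for j in range(n):
        i = disease[j]
        if i >= 0:
            d = spec.diseases[i]
            icd.append(frozenset({d.icd_code}))
            has_med = d.atc_code is not None and rng.random() < d.atc_probability
            atc.append(frozenset({d.atc_code}) if has_med else frozenset())
        else:
            icd.append(frozenset())
            atc.append(frozenset({"C09AA05"}) if medicated[j] else frozenset())

    event, followup, cause = _mortality(spec, age, delta + delta_disease, rng)
    year = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)

    crp = np.exp(rng.normal(0.0, 0.6, size=n) + 0.04 * (delta + delta_disease))
    srh = np.clip(
        np.round(3.0 - 0.12 * (delta + delta_disease) + rng.normal(0, 0.8, n)), 1, 5
    ).astype(int)
    bmi = np.clip(rng.normal(24.5, 3.5, n) + 0.1 * delta, 15, 50)

    frame = pd.DataFrame(
        {
            "sample_id": [f"S{j:07d}" for j in range(n)],
            "subject_id": [f"P{s:06d}" for s in subj],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "collection_year": year,
            "icd_codes": icd,
            "atc_codes": atc,
            **values,
            "death_event": event,
            "followup_years": followup,
            "death_cause_class": cause,
            "self_reported_health": srh,
            "crp": crp,
            "bmi": bmi,
        }
    )
    panel = [
        BiomarkerDescriptor(b.name, b.units, int(frame[b.name].notna().sum()))
        for b in spec.biomarkers
    ]
    truth = pd.DataFrame(
        {
            "sample_id": frame["sample_id"],
            "subject_id": frame["subject_id"],
            "delta": delta,
            "disease": [
                spec.diseases[i].icd_code if i >= 0 else "" for i in disease
            ],
            "delta_disease": delta_disease,
            "effective_age": eff_age,
        }
    )
    return CohortTable(frame, panel), truth


def generate_longitudinal(spec: SyntheticSpec) -> tuple[CohortTable, pd.DataFrame]:
    """Repeated sampling with diagnosis years and pre-diagnosis latent drift.

    Subjects destined for a disease carry a diagnosis year inside the sampling
    window. A sample taken tau years before diagnosis (0 <= tau <= drift_window)
    receives an extra latent offset drift_rate * (drift_window - tau), rising
    linearly toward diagnosis; samples at/after diagnosis carry the full drift
    plus the disease's delta and multipliers, and only they carry the ICD code.
    """
    spec.validate()
    if spec.samples_per_subject < 2:
        raise SpecError("longitudinal generation needs samples_per_subject >= 2")
    y0, y1 = spec.year_range
    if spec.drift_window > (y1 - y0):
        raise SpecError("drift_window exceeds the sampling-year window")
    rng = np.random.default_rng(spec.seed)
    n_sub = spec.n_subjects
    k = spec.samples_per_subject
    n = n_sub * k
    subj = np.repeat(np.arange(n_sub), k)
    female_subj = rng.random(n_sub) < spec.sex_ratio
    delta_subj = rng.normal(0.0, spec.sigma_b, size=n_sub)
    disease_subj = _assign_diseases(spec, n_sub, rng)
    age0 = rng.uniform(*spec.age_range, size=n_sub)
    diag_year = np.where(
        disease_subj >= 0, rng.integers(y0, y1 + 1, size=n_sub), -1
    )

    years = rng.integers(y0, y1 + 1, size=n)
    age = age0[subj] + (years - y0)
    female = female_subj[subj]
    delta = delta_subj[subj]
    disease = disease_subj[subj]
    dy = diag_year[subj]

    tau = np.where(dy >= 0, dy - years, np.inf)  # years until diagnosis
    drift = np.where(
        dy >= 0,
        spec.drift_rate * np.clip(spec.drift_window - np.maximum(tau, 0.0), 0.0, spec.drift_window),
        0.0,
    )
    diagnosed = (dy >= 0) & (years >= dy)
    delta_disease = np.zeros(n)
    for i, d in enumerate(spec.diseases):
        delta_disease[(disease == i) & diagnosed] = d.delta_years
    eff_age = age + delta + drift + delta_disease

    values = _biomarker_values(spec, eff_age, female, rng)
    for i, d in enumerate(spec.diseases):
        mask = (disease == i) & diagnosed
        for marker, mult in d.multipliers.items():
            values[marker][mask] *= mult
    values = _apply_missingness(spec, values, rng)

    icd = [
        frozenset({spec.diseases[disease[j]].icd_code}) if diagnosed[j] else frozenset()
        for j in range(n)
    ]
    event, followup, cause = _mortality(spec, age, delta + drift + delta_disease, rng)

    frame = pd.DataFrame(
        {
            "sample_id": [f"S{j:07d}" for j in range(n)],
            "subject_id": [f"P{s:06d}" for s in subj],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "collection_year": years,
            "icd_codes": icd,
            "atc_codes": [frozenset()] * n,
            **values,
            "death_event": event,
            "followup_years": followup,
            "death_cause_class": cause,
            "diagnosis_year": np.where(dy[range(n)] >= 0, dy, np.nan),
        }
    )
    panel = [
        BiomarkerDescriptor(b.name, b.units, int(frame[b.name].notna().sum()))
        for b in spec.biomarkers
    ]
    truth = pd.DataFrame(
        {
            "sample_id": frame["sample_id"],
            "subject_id": frame["subject_id"],
            "delta": delta,
            "drift": drift,
            "disease": [
                spec.diseases[i].icd_code if i >= 0 else "" for i in disease
            ],
            "diagnosis_year": dy,
            "delta_disease": delta_disease,
            "effective_age": eff_age,
        }
    )
    return CohortTable(frame, panel), truth


def skew_benchmark_spec(seed: int = 0, n_subjects: int = 20000) -> SyntheticSpec:
    """An all-healthy cohort for studying the prediction skew itself: every
    subject contributes to the train/validation/test split, so integer age
    years carry enough training samples for stable per-year median bias."""
    return SyntheticSpec(
        n_subjects=n_subjects,
        diseases=(),
        medicated_healthy_fraction=0.0,
        seed=seed,
    )


def gap_benchmark_spec(
    seed: int = 0, n_subjects: int = 12000, delta_years: float = 5.0,
    prevalence: float = 0.09,
) -> SyntheticSpec:
    """A single planted disease acting purely through the effective-age shift.

    The disease subgroup is drawn from the interior of the age range (30-60):
    conditional-mean age predictors attenuate group gaps within roughly two
    total standard deviations (sigma_b plus marker-estimation noise, ~13 y
    here) of the training age range boundaries — the same regression-to-the-
    mean geometry the skew corrector addresses. The planted shift moves the
    group's EFFECTIVE ages up by delta_years, so the upper age bound keeps
    age + delta_years, not just age, out of the attenuation zone. Offset
    recovery is therefore assessed away from the boundaries; the boundary
    attenuation itself is a documented model property.
    """
    return SyntheticSpec(
        n_subjects=n_subjects,
        diseases=(DiseaseSpec("E11", prevalence, delta_years, {}),),
        disease_age_range=(30.0, 60.0),
        medicated_healthy_fraction=0.0,
        seed=seed,
    )


def reduction_benchmark_spec(seed: int = 0, n_subjects: int = 3000) -> SyntheticSpec:
    """A 3-informative + 17-noise panel with a known elimination answer."""
    informative = [
        BiomarkerSpec("creatinine", 0.55, 0.75, slope=0.004, noise_sd=0.004 * _AGE_EQUIV_NOISE),
        BiomarkerSpec("hba1c", 4.5, 4.55, slope=0.015, noise_sd=0.015 * _AGE_EQUIV_NOISE),
        BiomarkerSpec("triglycerides", 60.0, 80.0, slope=0.9, noise_sd=0.9 * _AGE_EQUIV_NOISE),
    ]
    noise = [
        BiomarkerSpec(f"noise_{i:02d}", 10.0 + i, 10.5 + i, slope=0.0, noise_sd=2.0)
        for i in range(1, 18)
    ]
    return SyntheticSpec(
        n_subjects=n_subjects,
        biomarkers=tuple(informative + noise),
        diseases=(),
        missing_rate=0.0,
        seed=seed,
    )
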