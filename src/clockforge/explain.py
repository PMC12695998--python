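"""Shapley attributions against age-matched healthy backgrounds.

A standard Shapley explanation measures deviation from the model's global
mean prediction, which in an age clock is dominated by the subject's age
itself. Here the background is restricted to healthy training samples within
a +/- ``window``-year band around the subject's chronological age, so
attributions read as deviations from age-matched healthy expectation.
Additionally the skew-correction offset at the subject's age is subtracted
from the base value (``adjusted_base``), aligning explanations with the
corrected biological-age scale.

Two backends are provided:

* exact closed form for linear models: phi_i = w_i * (x_i - mean background x_i);
* interventional permutation sampling for arbitrary models (the MLP clock).
  Every sampled permutation telescopes from the background mean to the full
  prediction, so local accuracy (sum of attributions + base = prediction)
  holds to floating-point precision regardless of the number of permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import MLP, TrainedClock
from .cohort import CohortTable
from .correction import SkewCorrector

logger = logging.getLogger(__name__)


class BackgroundError(ValueError):
    """Not enough healthy training samples to form a background."""


@dataclass(frozen=True)
class AttributionConfig:
    """Window half-width in years, minimum background size, and sampling effort."""

    window: float = 2.0
    min_background: int = 50
    max_background: int = 200
    n_permutations: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.min_background < 2:
            raise ValueError("min_background must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class LinearModel:
    """A linear predictor f(x) = w . x + b with exact Shapley attributions."""

    coef: np.ndarray
    intercept: float = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ np.asarray(self.coef, dtype=float) + (
            self.intercept
        )


@dataclass
class AttributionReport:
    """Per-feature Shapley values (years) for one sample."""

    feature_names: list[str]
    values: np.ndarray
    base_value: float
    adjusted_base: float
    raw_prediction: float
    sample_id: str = ""
    age: float = np.nan
    background_size: int = 0
    window_used: float = np.nan

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.feature_names)


def build_background(
    train_healthy: CohortTable,
    age: float,
    config: AttributionConfig = AttributionConfig(),
    exclude_sample_id: str | None = None,
) -> tuple[CohortTable, float]:
    """Healthy training samples within [age - w, age + w], widening if sparse.

    The window is widened symmetrically by one year at a time until at least
    ``min_background`` samples match (each widening is logged); the window
    actually used is returned alongside the table.
    """
    frame = train_healthy.frame
    if exclude_sample_id is not None:
        frame = frame[frame["sample_id"] != exclude_sample_id]
    if len(frame) < config.min_background:
        raise BackgroundError(
            f"training set has {len(frame)} samples, "
            f"fewer than min_background={config.min_background}"
        )
    ages = frame["age"].to_numpy(dtype=float)
    w = config.window
    while True:
        mask = (ages >= age - w) & (ages <= age + w)
        if mask.sum() >= config.min_background:
            break
        w += 1.0
        logger.info("background window widened to +/- %.0f y at age %.1f", w, age)
    if w != config.window:
        logger.warning(
            "background at age %.1f required window +/- %.0f y (requested %.0f)",
            age,
            w,
            config.window,
        )
    sub = frame[mask]
    if len(sub) > config.max_background:
        rng = np.random.default_rng(config.seed)
        sub = sub.iloc[rng.choice(len(sub), config.max_background, replace=False)]
    return train_healthy.with_frame(sub.reset_index(drop=True)), w


def _predict_fn(model):
    if isinstance(model, TrainedClock):
        return model.predict
    if isinstance(model, (MLP, LinearModel)):
        return model.predict
    if callable(model):
        return model
    raise TypeError(f"cannot explain model of type {type(model)!r}")


def _shapley_linear(model: LinearModel, x: np.ndarray, bg: np.ndarray) -> np.ndarray:
    return np.asarray(model.coef, dtype=float) * (x - bg.mean(axis=0))


def _shapley_permutation(
    predict, x: np.ndarray, bg: np.ndarray, n_permutations: int, seed: int
) -> np.ndarray:
    """Interventional Shapley values by (antithetic) permutation sampling."""
    rng = np.random.default_rng(seed)
    d = len(x)
    m = len(bg)
    phi = np.zeros(d)
    perms = []
    for _ in range((n_permutations + 1) // 2):
        p = rng.permutation(d)
        perms.append(p)
        perms.append(p[::-1])  # antithetic counterpart
    perms = perms[:n_permutations]
    for perm in perms:
        # one big batch: background, then d cumulative replacements
        z = np.repeat(bg[None, :, :], d + 1, axis=0)  # (d+1, m, d)
        for step, j in enumerate(perm, start=1):
            z[step:, :, j] = x[j]
        v = predict(z.reshape(-1, d)).reshape(d + 1, m).mean(axis=1)
        phi[perm] += np.diff(v)
    return phi / len(perms)


def explain_sample(
    model,
    sample_x: np.ndarray,
    background_x: np.ndarray,
    feature_names: list[str],
    corrector: SkewCorrector | None = None,
    age: float = np.nan,
    sample_id: str = "",
    config: AttributionConfig = AttributionConfig(),
    window_used: float = np.nan,
) -> AttributionReport:
    """Attribute one prediction to its features against the given background.

    ``sample_x`` and ``background_x`` must be preprocessed identically (the
    matrices the model actually consumes). The base value is the mean model
    output over the background; ``adjusted_base`` subtracts the corrector
    offset at the subject's age.
    """
    x = np.asarray(sample_x, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background_x, dtype=float))
    if bg.shape[0] < 2:
        raise BackgroundError("background must contain at least 2 rows")
    if bg.shape[1] != len(x) or len(feature_names) != len(x):
        raise ValueError("feature dimension mismatch")
    predict = _predict_fn(model)
    raw = float(np.asarray(predict(x.reshape(1, -1))).ravel()[0])
    base = float(np.mean(predict(bg)))
    if isinstance(model, LinearModel):
        phi = _shapley_linear(model, x, bg)
    else:
        phi = _shapley_permutation(predict, x, bg, config.n_permutations, config.seed)
    if corrector is not None and np.isfinite(age):
        adjusted = base - float(corrector.offset(age)[0])
    else:
        adjusted = base
    return AttributionReport(
        feature_names=list(feature_names),
        values=phi,
        base_value=base,
        adjusted_base=adjusted,
        raw_prediction=raw,
        sample_id=sample_id,
        age=age,
        background_size=bg.shape[0],
        window_used=window_used,
    )


def explain_cohort(
    clock: TrainedClock,
    samples: CohortTable,
    train_healthy: CohortTable,
    corrector: SkewCorrector | None = None,
    config: AttributionConfig = AttributionConfig(),
    preprocess: bool = False,
) -> list[AttributionReport]:
    """Explain every sample in a table against its own age-matched background.

    Tables are expected already preprocessed (pass ``preprocess=True`` to run
    them through the clock's preprocessor first).
    """
    if preprocess and clock.preprocessor is not None:
        samples = clock.preprocessor.apply(samples)
        train_healthy = clock.preprocessor.apply(train_healthy)
    feats = clock.feature_names
    reports = []
    for _, row in samples.frame.iterrows():
        bg_table, w = build_background(
            train_healthy, float(row["age"]), config,
            exclude_sample_id=str(row["sample_id"]),
        )
        bg_x = bg_table.frame[feats].to_numpy(dtype=float)
        x = row[feats].to_numpy(dtype=float)
        reports.append(
            explain_sample(
                clock,
                x,
                bg_x,
                feats,
                corrector=corrector,
                age=float(row["age"]),
                sample_id=str(row["sample_id"]),
                config=config,
                window_used=w,
            )
        )
    return reports


def aggregate_group(reports: list[AttributionReport], group_label: str = "") -> pd.DataFrame:
    """Per-feature summary of a group's attributions, ranked by mean value.

    Returns one row per feature with mean, median, std, and mean absolute
    attribution; rows sorted by descending mean attribution (the per-disease
    panel view).
    """
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    mat = pd.DataFrame([r.as_series() for r in reports])
    out = pd.DataFrame(
        {
            "mean": mat.mean(),
            "median": mat.median(),
            "std": mat.std(ddof=0),
            "mean_abs": mat.abs().mean(),
            "n": len(mat),
        }
    )
    out["group"] = group_label
    return out.sort_values("mean", ascending=False)


def reports_to_frame(reports: list[AttributionReport]) -> pd.DataFrame:
    """Long-format export: one row per (sample, feature)."""
    rows = []
    for r in reports:
        for name, val in zip(r.feature_names, r.values):
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "age": r.age,
                    "feature": name,
                    "attribution": float(val),
                    "base": r.base_value,
                    "adjusted_base": r.adjusted_base,
                }
            )
    return pd.DataFrame(rows)
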