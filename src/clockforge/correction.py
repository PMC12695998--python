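"""Prediction-skew correction via kernel-smoothed per-age median curves.

First-generation age clocks systematically over-predict young and under-predict
old samples (regression to the mean). The corrector estimates this skew from
TRAINING predictions only: for each integer age year it takes the median raw
prediction, fits a smooth curve through the (age, median) pairs with kernel
ridge regression (additive chi-squared kernel, alpha = 0.001 — suited to
smooth, non-negative inputs like age in years), and defines

    offset(a) = smoothed_median(a) - a.

Applying the corrector subtracts offset(age) from each raw prediction, so
within one integer age year the correction is a constant shift: ranks,
pairwise differences, and same-age group gaps are preserved exactly. The
acceleration is the corrected (biological) age minus the chronological age.

Note the important caveat: because the correction only removes the average
age-specific error, it must follow a model that already carries biological
signal. A constant-output model passed through this corrector yields
near-perfect chronological age "predictions" that contain no information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.kernel_ridge import KernelRidge


@dataclass
class SkewCorrector:
    """Per-age median curve smoothed by kernel ridge; fitted on training data only."""

    age_grid: np.ndarray
    raw_medians: np.ndarray
    smoother: KernelRidge
    valid_range: tuple[float, float]
    year_offsets: np.ndarray  # one offset per integer year in valid_range

    def offset(self, ages) -> np.ndarray:
        """Median-prediction offset, constant within each integer age year.

        The per-year offsets are precomputed once at fit time (the smoothed
        curve evaluated at the bin center floor(age) + 0.5, the abscissa the
        medians were fitted at) and looked up here, so a given age year maps
        to one bit-identical offset no matter how queries are batched: ranks,
        pairwise differences, and same-age group gaps are preserved exactly.
        Ages outside the fitted range are clamped to the boundary year — the
        kernel fit is not extrapolated.
        """
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, _ = self.valid_range
        year_lo = int(np.floor(lo))
        idx = np.clip(
            np.floor(a).astype(int) - year_lo, 0, len(self.year_offsets) - 1
        )
        return self.year_offsets[idx]

    def to_json(self) -> str:
        return json.dumps(
            {
                "age_grid": self.age_grid.tolist(),
                "raw_medians": self.raw_medians.tolist(),
                "valid_range": list(self.valid_range),
                "year_offsets": self.year_offsets.tolist(),
                "dual_coef": np.asarray(self.smoother.dual_coef_).ravel().tolist(),
                "kernel": self.smoother.kernel,
                "alpha": self.smoother.alpha,
            },
            indent=2,
        )


def fit_corrector(
    train_predictions,
    train_ages,
    alpha: float = 0.001,
    kernel: str = "additive_chi2",
    min_count: int = 10,
) -> SkewCorrector:
    """Fit the skew corrector from training predictions and training ages.

    Age years with fewer than ``min_count`` training samples are excluded from
    the (age, median) fit pairs; their noisy medians would corrupt the smooth.
    """
    pred = np.asarray(train_predictions, dtype=float).ravel()
    ages = np.asarray(train_ages, dtype=float).ravel()
    if len(pred) != len(ages):
        raise ValueError("predictions and ages must have equal length")
    if not (np.isfinite(pred).all() and np.isfinite(ages).all()):
        raise ValueError("non-finite predictions or ages")
    if (ages < 0).any():
        raise ValueError("the additive chi-squared kernel requires non-negative ages")
    years = np.floor(ages).astype(int)
    grouped = pd.Series(pred).groupby(years)
    counts = grouped.size()
    medians = grouped.median()[counts >= min_count]
    if len(medians) < 2:
        # fall back to all years before declaring failure
        medians = grouped.median()
    if len(medians) < 2:
        raise ValueError("need at least 2 distinct integer age years to fit")
    # a sample in integer year y has ages in [y, y+1), so the per-year median
    # belongs at the bin center y + 0.5; fitting at the left edge would shift
    # the whole correction by half a year times the curve's slope
    grid = medians.index.to_numpy(dtype=float) + 0.5
    vals = medians.to_numpy(dtype=float)
    smoother = KernelRidge(alpha=alpha, kernel=kernel)
    with warnings.catch_warnings():
        # near-interpolating fit routinely triggers a benign singular-matrix
        # fallback inside sklearn's dual solver
        warnings.filterwarnings("ignore", message="Singular matrix")
        smoother.fit(grid.reshape(-1, 1), vals)
    # precompute one offset per integer year covered by the fitted range
    # (including sparse interior years); lookup keeps offsets bit-stable
    # across arbitrarily batched queries
    all_years = np.arange(int(medians.index.min()), int(medians.index.max()) + 1)
    centers = all_years + 0.5
    year_offsets = smoother.predict(centers.reshape(-1, 1)) - centers
    return SkewCorrector(
        age_grid=grid,
        raw_medians=vals,
        smoother=smoother,
        valid_range=(float(grid.min() - 0.5), float(grid.max() + 0.5)),
        year_offsets=year_offsets,
    )


def apply_corrector(corrector: SkewCorrector, predictions, ages) -> pd.DataFrame:
    """Subtract the age-specific offset; return raw, biological age, acceleration.

    ``clamped`` flags samples whose age fell outside the corrector's training
    range (boundary offset used).
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    a = np.asarray(ages, dtype=float).ravel()
    if not (np.isfinite(pred).all() and np.isfinite(a).all()):
        raise ValueError("non-finite predictions or ages")
    off = corrector.offset(a)
    bio = pred - off
    lo, hi = corrector.valid_range
    return pd.DataFrame(
        {
            "raw": pred,
            "biological_age": bio,
            "acceleration": bio - a,
            "offset": off,
            "clamped": (a < lo) | (a > hi),
        }
    )


@dataclass
class InvertibleTransform:
    """A stored forward/inverse mapping of the age target (benchmark baselines)."""

    name: str
    forward_fn: object
    inverse_fn: object
    params: dict = field(default_factory=dict)

    def forward(self, x):
        return self.forward_fn(np.asarray(x, dtype=float))

    def inverse(self, y):
        return self.inverse_fn(np.asarray(y, dtype=float))


def baseline_transforms(train_ages, mode: str, **kwargs):
    """Alternative skew-mitigation strategies, provided for benchmarking.

    - ``subsample``: delegates to per-age-year capped subsampling (returns the
      resampled table; pass ``table`` and ``cap``/``seed``).
    - ``logistic``: squashes ages onto (0, 1) with a logistic map centered on
      the age range; min/max train ages map to fixed bounds (0.01 / 0.99).
    - ``quantile_uniform``: maps ages to their empirical quantiles (uniform
      target distribution); inverse by interpolation restores training ages.
    """
    ages = np.asarray(train_ages, dtype=float).ravel()
    if mode == "subsample":
        from .cohort import subsample_balanced

        table = kwargs["table"]
        return subsample_balanced(
            table, kwargs.get("cap", 1000), kwargs.get("seed", 0)
        )
    if mode == "logistic":
        lo, hi = float(ages.min()), float(ages.max())
        if hi <= lo:
            raise ValueError("degenerate age distribution: logistic map undefined")
        bound = 0.99
        mu = (lo + hi) / 2.0
        s = (hi - lo) / (2.0 * np.log(bound / (1 - bound)))

        def fwd(x):
            return 1.0 / (1.0 + np.exp(-(x - mu) / s))

        def inv(y):
            y = np.clip(y, 1e-12, 1 - 1e-12)
            return mu + s * np.log(y / (1.0 - y))

        return InvertibleTransform("logistic", fwd, inv, {"mu": mu, "s": s})
    if mode == "quantile_uniform":
        order = np.sort(ages)
        n = len(order)
        if n < 2 or order[0] == order[-1]:
            raise ValueError("degenerate age distribution: quantile map undefined")
        q = (np.arange(n) + 0.5) / n

        def fwd(x):
            return np.interp(x, order, q)

        def inv(y):
            return np.interp(y, q, order)

        return InvertibleTransform("quantile_uniform", fwd, inv, {"n": n})
    raise ValueError(f"unknown baseline transform mode {mode!r}")


def skew_metrics(predictions, ages, min_count: int = 1) -> dict:
    """Bias diagnostics: per-age median bias curve, OLS slope, overall median bias."""
    pred = np.asarray(predictions, dtype=float).ravel()
    a = np.asarray(ages, dtype=float).ravel()
    years = np.floor(a).astype(int)
    g = pd.Series(pred - a).groupby(years)
    bias = g.median()
    counts = g.size()
    bias = bias[counts >= min_count]
    if len(np.unique(years)) < 2:
        raise ValueError("need at least 2 age years for skew metrics")
    slope, _ = np.polyfit(a, pred, 1)
    return {
        "bias_by_year": bias,
        "counts_by_year": counts,
        "slope": float(slope),
        "overall_median_bias": float(np.median(pred - a)),
    }
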