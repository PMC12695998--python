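"""Outlier trimming, iterative imputation, and min-max scaling.

Fixed pipeline order: trim -> impute -> scale. Fitting and applying are
separated so that transforms learned on training data can be applied to test
or external validation data without leakage (``fit_scope='train_only'``); a
``'full_table'`` scope reproducing whole-dataset preprocessing is also
supported and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cohort import CohortTable

logger = logging.getLogger(__name__)

SEX_CODES = {"female": 0.0, "male": 1.0}


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables for the trim/impute/scale pipeline.

    outlier_fraction: per-biomarker upper-tail fraction removed (0.005 = top 0.5%).
    impute_floor: lower clamp for imputed values (0 prevents negative lab values).
    fit_scope: 'train_only' (anti-leakage default) or 'full_table'.
    two_sided: also trim the lower tail (off by default; the rule is "top" outliers).
    """

    outlier_fraction: float = 0.005
    impute_floor: float = 0.0
    scaler: str = "minmax"
    fit_scope: str = "train_only"
    two_sided: bool = False
    imputer_max_iter: int = 10
    imputer_initial_strategy: str = "median"

    def __post_init__(self):
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.scaler != "minmax":
            raise ValueError(f"unknown scaler {self.scaler!r}")
        if self.fit_scope not in ("train_only", "full_table"):
            raise ValueError(f"unknown fit_scope {self.fit_scope!r}")


class UnfittableColumnError(ValueError):
    """A biomarker has no observed values in the fit scope."""


def trim_outliers(
    table: CohortTable, fraction: float = 0.005, two_sided: bool = False
) -> tuple[CohortTable, pd.DataFrame]:
    """Remove, per biomarker, samples strictly above the (1-fraction) quantile.

    A sample flagged by several biomarkers is removed once; the report counts
    it under each flagging biomarker. With ``two_sided``, values strictly
    below the ``fraction`` quantile are removed as well.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    mat = table.biomarker_matrix()
    flagged = np.zeros(len(mat), dtype=bool)
    rows = []
    for name in mat.columns:
        col = mat[name]
        obs = col.dropna()
        if obs.empty:
            rows.append({"biomarker": name, "n_removed": 0, "upper_cut": np.nan})
            continue
        hi = float(obs.quantile(1 - fraction))
        mask = (col > hi).to_numpy()
        cut_lo = np.nan
        if two_sided:
            cut_lo = float(obs.quantile(fraction))
            mask |= (col < cut_lo).to_numpy()
        flagged |= mask
        rows.append(
            {
                "biomarker": name,
                "n_removed": int(mask.sum()),
                "upper_cut": hi,
                **({"lower_cut": cut_lo} if two_sided else {}),
            }
        )
    report = pd.DataFrame(rows)
    trimmed = table.with_frame(table.frame[~flagged].reset_index(drop=True))
    return trimmed, report


@dataclass
class FittedPreprocessor:
    """Frozen state of the trim/impute/scale pipeline.

    Holds per-biomarker upper cuts (informational), the fitted chained-equations
    imputer, per-biomarker min/max for scaling, and the panel it was fitted on.
    Applying is deterministic given this state; apply-time values outside the
    fitted range are NOT clipped and may scale outside [0, 1].
    """

    panel: list[str]
    params: PreprocessParams
    imputer: IterativeImputer
    mins: pd.Series
    maxs: pd.Series
    upper_cuts: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def impute(self, table: CohortTable) -> CohortTable:
        missing = [n for n in self.panel if n not in table.frame.columns]
        if missing:
            raise KeyError(f"table lacks fitted biomarkers: {missing}")
        frame = table.frame.copy()
        values = self.imputer.transform(frame[self.panel].to_numpy(dtype=float))
        values = np.maximum(values, self.params.impute_floor)
        frame[self.panel] = values
        return table.with_frame(frame)

    def scale(self, table: CohortTable) -> CohortTable:
        mat = table.frame[self.panel]
        if mat.isna().to_numpy().any():
            raise ValueError("missing values remain; impute before scaling")
        frame = table.frame.copy()
        span = self.maxs - self.mins
        for name in self.panel:
            if span[name] == 0:
                logger.warning("constant biomarker %r scaled to 0", name)
                frame[name] = 0.0
            else:
                frame[name] = (frame[name] - self.mins[name]) / span[name]
        return table.with_frame(frame)

    def apply(self, table: CohortTable) -> CohortTable:
        return self.scale(self.impute(table))


def fit_imputer(
    table: CohortTable, params: PreprocessParams, seed: int
) -> FittedPreprocessor:
    """Fit the chained-equations imputer and the min-max scaler state.

    Each biomarker is regressed on the others in round-robin cycles (Bayesian
    ridge conditionals, median initial fill); imputed values are clamped to
    ``impute_floor``. Scaling min/max are taken from the imputed fit-scope data.
    """
    panel = table.biomarker_names
    if len(panel) < 2:
        raise ValueError("imputation requires at least 2 biomarkers")
    mat = table.biomarker_matrix()
    dead = [n for n in panel if mat[n].notna().sum() == 0]
    if dead:
        raise UnfittableColumnError(
            f"biomarkers with no observed values in fit scope: {dead}"
        )
    imputer = IterativeImputer(
        max_iter=params.imputer_max_iter,
        initial_strategy=params.imputer_initial_strategy,
        min_value=params.impute_floor,
        random_state=int(seed) % (2**31),
        sample_posterior=False,
        keep_empty_features=False,
    )
    imputed = imputer.fit_transform(mat.to_numpy(dtype=float))
    imputed = np.maximum(imputed, params.impute_floor)
    frame = pd.DataFrame(imputed, columns=panel)
    cuts = pd.Series(
        {n: float(mat[n].dropna().quantile(1 - params.outlier_fraction)) for n in panel}
    )
    return FittedPreprocessor(
        panel=list(panel),
        params=params,
        imputer=imputer,
        mins=frame.min(),
        maxs=frame.max(),
        upper_cuts=cuts,
    )


def encode_sex(table: CohortTable) -> CohortTable:
    """Encode sex as female=0 / male=1; drop records with missing sex.

    Sex bypasses imputation and scaling: it enters the model as this binary
    code directly.
    """
    frame = table.frame.copy()
    sex = frame["sex"].map(
        lambda s: SEX_CODES.get(str(s).strip().lower(), np.nan)
        if not isinstance(s, float) or not np.isnan(s)
        else np.nan
    )
    n_bad = int(sex.isna().sum())
    if n_bad:
        logger.warning("dropping %d records with missing/unknown sex", n_bad)
    frame = frame[sex.notna()].copy()
    frame["sex_code"] = sex[sex.notna()].astype(float)
    return table.with_frame(frame.reset_index(drop=True))


def preprocess_fit(
    table: CohortTable, params: PreprocessParams, seed: int
) -> tuple[CohortTable, FittedPreprocessor, pd.DataFrame]:
    """Run trim -> fit impute -> scale on the fit scope; return transformed
    table, fitted state, and the outlier-removal report."""
    table = encode_sex(table)
    trimmed, report = trim_outliers(table, params.outlier_fraction, params.two_sided)
    fitted = fit_imputer(trimmed, params, seed)
    out = fitted.apply(trimmed)
    return out, fitted, report
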