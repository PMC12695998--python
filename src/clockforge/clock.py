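"""Age-stratified splitting and the multilayer-perceptron age regressor.

The regressor is a fully-connected network (hidden sizes 1000 and 100, ReLU,
single linear output) trained with Adam on mean squared error against
chronological age in raw years. Training is step-based (not epoch-based):
batches of 2048 for up to 2000 steps, validation loss monitored every 10
steps, and the weights from the best validation evaluation returned. All
randomness (weight init, batch order, splitting) is seeded, so a given
config + seed + data reproduces bit-identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .preprocess import FittedPreprocessor


class DivergenceError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"non-finite training loss at step {step}")
        self.step = step


@dataclass(frozen=True)
class ClockConfig:
    """Training recipe for the age regressor."""

    hidden_sizes: tuple[int, ...] = (1000, 100)
    learning_rate: float = 5e-3
    weight_decay: float = 1e-4
    batch_size: int = 2048
    max_steps: int = 2000
    eval_interval: int = 10
    checkpoint: str = "best_val"  # or "last_step"
    seed: int = 0

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        for name in ("batch_size", "max_steps", "eval_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning_rate and weight_decay must be >= 0")
        if self.checkpoint not in ("best_val", "last_step"):
            raise ValueError(f"unknown checkpoint mode {self.checkpoint!r}")


class MLP:
    """Minimal seeded feed-forward regressor (ReLU hidden layers, linear output)."""

    def __init__(self, n_features: int, hidden_sizes: tuple[int, ...], seed: int):
        rng = np.random.default_rng(seed)
        sizes = [n_features, *hidden_sizes, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He (Kaiming) init, appropriate for ReLU
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray, keep_activations: bool = False):
        acts = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = np.maximum(h, 0.0)
            if keep_activations:
                acts.append(h)
        return (h, acts) if keep_activations else h

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float)).ravel()

    def state(self) -> list[np.ndarray]:
        return [a.copy() for a in (*self.weights, *self.biases)]

    def load_state(self, state: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [a.copy() for a in state[:k]]
        self.biases = [a.copy() for a in state[k:]]


class _Adam:
    """Adam with decoupled-from-nothing (L2-in-gradient) weight decay."""

    def __init__(self, params, lr, weight_decay, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class SplitAssignment:
    """Per-sample train/validation/test labels, stratified by integer age year."""

    labels: pd.Series  # index-aligned with the cohort frame; values in {train,validation,test}
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> pd.Index:
        return self.labels.index[self.labels == part]


def split_cohort(
    healthy: CohortTable,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    min_stratum: int = 5,
) -> SplitAssignment:
    """Stratified random split of the healthy cohort by integer age year.

    Strata with fewer than ``min_stratum`` records are merged with the nearest
    age stratum before splitting. Deterministic under ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if healthy.has_health_label and not healthy.frame["healthy"].all():
        raise ValueError("split_cohort expects only healthy records")
    rng = np.random.default_rng(seed)
    frame = healthy.frame
    years = np.floor(frame["age"].to_numpy()).astype(int)

    # merge sparse strata into the nearest (by age) non-sparse one
    uniq, counts = np.unique(years, return_counts=True)
    big = uniq[counts >= min_stratum]
    strata = years.copy()
    if len(big):
        for y in uniq[counts < min_stratum]:
            strata[years == y] = big[np.argmin(np.abs(big - y))]
    labels = np.empty(len(frame), dtype=object)
    f_tr, f_va, _ = fractions
    for y in np.unique(strata):
        idx = np.flatnonzero(strata == y)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_tr = int(round(f_tr * n))
        n_va = int(round(f_va * n))
        n_va = min(n_va, n - n_tr)
        labels[idx[:n_tr]] = "train"
        labels[idx[n_tr : n_tr + n_va]] = "validation"
        labels[idx[n_tr + n_va :]] = "test"
    return SplitAssignment(
        labels=pd.Series(labels, index=frame.index), fractions=fractions, seed=seed
    )


@dataclass
class TrainedClock:
    """Fitted age regressor plus its preprocessing state and feature list."""

    model: MLP
    feature_names: list[str]
    config: ClockConfig
    preprocessor: FittedPreprocessor | None = None
    metadata: dict = field(default_factory=dict)

    def features_from(self, table: CohortTable, preprocess: bool = True) -> np.ndarray:
        if preprocess and self.preprocessor is not None:
            table = self.preprocessor.apply(table)
        missing = [f for f in self.feature_names if f not in table.frame.columns]
        if missing:
            raise KeyError(f"samples missing clock features: {missing}")
        return table.frame[self.feature_names].to_numpy(dtype=float)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


def _mse_grads(model: MLP, x: np.ndarray, y: np.ndarray):
    pred, acts = model.forward(x, keep_activations=True)
    err = pred.ravel() - y
    loss = float(np.mean(err**2))
    n = len(y)
    delta = (2.0 / n) * err.reshape(-1, 1)
    grads_w, grads_b = [], []
    last = len(model.weights) - 1
    for i in range(last, -1, -1):
        a_in = acts[i]
        grads_w.append(a_in.T @ delta)
        grads_b.append(delta.sum(axis=0))
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0)
    grads_w.reverse()
    grads_b.reverse()
    return loss, grads_w + grads_b


def train_mlp(
    config: ClockConfig,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> tuple[MLP, dict]:
    """Train the regressor; return the checkpointed model and training metadata."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    x_val = np.asarray(x_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    model = MLP(x_train.shape[1], config.hidden_sizes, seed=config.seed)
    opt = _Adam(
        model.weights + model.biases, config.learning_rate, config.weight_decay
    )
    rng = np.random.default_rng(config.seed + 1)
    n = len(y_train)
    order = rng.permutation(n)
    pos = 0
    best_loss, best_state, best_step = np.inf, model.state(), 0
    history = []
    for step in range(1, config.max_steps + 1):
        if config.batch_size >= n:
            bx, by = x_train, y_train
        else:
            if pos + config.batch_size > n:
                order = rng.permutation(n)
                pos = 0
            batch = order[pos : pos + config.batch_size]
            pos += config.batch_size
            bx, by = x_train[batch], y_train[batch]
        loss, grads = _mse_grads(model, bx, by)
        if not np.isfinite(loss):
            raise DivergenceError(step)
        opt.step(grads)
        if step % config.eval_interval == 0 or step == config.max_steps:
            val_pred = model.predict(x_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            if not np.isfinite(val_loss):
                raise DivergenceError(step)
            history.append({"step": step, "train_loss": loss, "val_loss": val_loss})
            if val_loss < best_loss:
                best_loss, best_state, best_step = val_loss, model.state(), step
    meta = {
        "steps_run": config.max_steps,
        "best_eval_step": best_step,
        "best_val_loss": best_loss,
        "history": history,
        "checkpoint": config.checkpoint,
        "seed": config.seed,
    }
    if config.checkpoint == "best_val":
        model.load_state(best_state)
    return model, meta


def train_clock(
    config: ClockConfig,
    train: CohortTable,
    validation: CohortTable,
    feature_names: list[str] | None = None,
    preprocessor: FittedPreprocessor | None = None,
) -> TrainedClock:
    """Train an age clock on preprocessed cohort tables.

    Features default to the table's biomarker panel plus the binary sex code;
    the target is chronological age in raw (unscaled) years.
    """
    if feature_names is None:
        feature_names = train.biomarker_names + ["sex_code"]
    x_tr = train.frame[feature_names].to_numpy(dtype=float)
    y_tr = train.frame["age"].to_numpy(dtype=float)
    x_va = validation.frame[feature_names].to_numpy(dtype=float)
    y_va = validation.frame["age"].to_numpy(dtype=float)
    model, meta = train_mlp(config, x_tr, y_tr, x_va, y_va)
    return TrainedClock(
        model=model,
        feature_names=list(feature_names),
        config=config,
        preprocessor=preprocessor,
        metadata=meta,
    )


def predict_age(
    clock: TrainedClock, samples: CohortTable, preprocess: bool = False
) -> np.ndarray:
    """Raw (uncorrected) predicted ages in years, one finite value per sample."""
    x = clock.features_from(samples, preprocess=preprocess)
    pred = clock.predict(x)
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite predictions produced")
    return pred


def evaluate(predictions: np.ndarray, ages: np.ndarray) -> dict:
    """R^2 (vs the mean-of-truth baseline), MAE in years, and Pearson r.

    The correlation is reported as None when either vector has zero variance.
    """
    p = np.asarray(predictions, dtype=float).ravel()
    a = np.asarray(ages, dtype=float).ravel()
    if len(p) != len(a) or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    ss_res = float(np.sum((a - p) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mae = float(np.mean(np.abs(a - p)))
    if np.std(p) == 0 or np.std(a) == 0:
        pcc = None
    else:
        pcc = float(np.corrcoef(p, a)[0, 1])
    return {"r2": r2, "mae": mae, "pcc": pcc}
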