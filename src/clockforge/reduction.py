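"""Panel reduction: correlation pruning, cost exclusion, Shapley elimination.

The pipeline that turned a 34-marker panel into a 7-feature clock: first drop
redundant markers (pairwise Pearson |r| above a threshold, keeping the member
with the larger measurement count), optionally drop named markers for assay
cost reasons, then repeatedly retrain the clock and remove the markers with
the smallest mean absolute age-matched Shapley attribution, several at a time
early on (the schedule) and one at a time thereafter, down to a target size.
Sex is ranked but never eliminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clock import ClockConfig, TrainedClock, evaluate, train_clock
from .cohort import CohortTable
from .explain import AttributionConfig, build_background, explain_sample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReductionConfig:
    correlation_threshold: float = 0.5
    elimination_schedule: tuple[int, ...] = (5, 5)
    cost_exclusions: frozenset[str] = frozenset()
    target_size: int = 7
    seed: int = 0
    n_explain: int = 60          # eval samples used per ranking step
    attribution: AttributionConfig = field(default_factory=AttributionConfig)

    def __post_init__(self):
        if any(k < 1 for k in self.elimination_schedule):
            raise ValueError("schedule entries must be >= 1")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")


@dataclass
class ReductionStep:
    step: int
    removed: tuple[str, ...]
    provenance: str  # correlation | cost | shap
    surviving_panel: tuple[str, ...]
    metrics: dict | None = None
    ranking: pd.DataFrame | None = None


@dataclass
class ReductionTrace:
    steps: list[ReductionStep]
    final_panel: tuple[str, ...]
    final_clock: TrainedClock | None = None
    final_metrics: dict | None = None

    def removed_all(self) -> list[str]:
        return [name for s in self.steps for name in s.removed]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            m = s.metrics or {}
            rows.append(
                {
                    "step": s.step,
                    "removed": ";".join(s.removed),
                    "reason": s.provenance,
                    "panel_size": len(s.surviving_panel),
                    "r2": m.get("r2"),
                    "mae": m.get("mae"),
                    "pcc": m.get("pcc"),
                }
            )
        return pd.DataFrame(rows)


def prune_correlated(
    table: CohortTable, threshold: float = 0.5
) -> tuple[list[str], dict[str, str]]:
    """Greedy redundancy pruning on pairwise Pearson correlation.

    Biomarkers are visited in descending measurement-count order (ties broken
    by panel order) and accepted unless |r| with an already-accepted biomarker
    exceeds ``threshold`` (strictly). The removal map records, for each pruned
    biomarker, the retained biomarker that displaced it. Correlations use
    pairwise-complete observations.
    """
    if len(table.panel) < 2:
        raise ValueError("need at least 2 biomarkers to prune")
    table = table.refresh_counts()
    usable = [b for b in table.panel if b.n_measured > 0]
    for b in table.panel:
        if b.n_measured == 0:
            logger.warning("biomarker %r has no observed values; excluded", b.name)
    order = sorted(
        range(len(usable)), key=lambda i: (-usable[i].n_measured, i)
    )
    corr = table.biomarker_matrix().corr().abs()
    accepted: list[str] = []
    removal_map: dict[str, str] = {}
    for i in order:
        name = usable[i].name
        blocker = next(
            (a for a in accepted if pd.notna(corr.loc[name, a]) and corr.loc[name, a] > threshold),
            None,
        )
        if blocker is None:
            accepted.append(name)
        else:
            removal_map[name] = blocker
    # restore panel order among accepted markers
    panel_order = {b.name: i for i, b in enumerate(table.panel)}
    accepted.sort(key=lambda n: panel_order[n])
    return accepted, removal_map


def rank_features(
    clock: TrainedClock,
    eval_table: CohortTable,
    background_table: CohortTable,
    config: AttributionConfig = AttributionConfig(),
    n_explain: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank the clock's features by mean |Shapley attribution| (descending).

    Attributions are computed on up to ``n_explain`` evaluation samples, each
    against its own age-matched background drawn from ``background_table``
    (healthy training samples). Ties are broken by feature-list order. The sex
    code is ranked like any feature but flagged as exempt from elimination.
    """
    if eval_table.n_samples == 0:
        raise ValueError("evaluation table is empty")
    frame = eval_table.frame
    if len(frame) > n_explain:
        rng = np.random.default_rng(seed)
        frame = frame.iloc[rng.choice(len(frame), n_explain, replace=False)]
    feats = clock.feature_names
    totals = np.zeros(len(feats))
    for _, row in frame.iterrows():
        bg_table, w = build_background(
            background_table, float(row["age"]), config,
            exclude_sample_id=str(row["sample_id"]),
        )
        bg_x = bg_table.frame[feats].to_numpy(dtype=float)
        rep = explain_sample(
            clock,
            row[feats].to_numpy(dtype=float),
            bg_x,
            feats,
            age=float(row["age"]),
            config=config,
            window_used=w,
        )
        totals += np.abs(rep.values)
    impact = totals / len(frame)
    out = pd.DataFrame(
        {
            "feature": feats,
            "impact": impact,
            "exempt": [f == "sex_code" for f in feats],
            "panel_order": range(len(feats)),
        }
    )
    return out.sort_values(
        ["impact", "panel_order"], ascending=[False, True]
    ).reset_index(drop=True)


def iterate_reduction(
    train: CohortTable,
    validation: CohortTable,
    clock_config: ClockConfig,
    config: ReductionConfig,
) -> ReductionTrace:
    """Run the full reduction loop; returns the ordered trace.

    ``train`` and ``validation`` must be preprocessed (imputed, scaled, with a
    ``sex_code`` column). Correlation pruning and cost exclusions are recorded
    as steps 0 and 1; each subsequent step retrains the clock on the surviving
    panel (step-indexed seed), ranks features on the validation split, and
    removes the bottom-k non-exempt biomarkers (k follows the schedule, then 1).
    """
    steps: list[ReductionStep] = []
    panel = list(train.biomarker_names)

    if config.correlation_threshold is not None:
        kept, removal_map = prune_correlated(train, config.correlation_threshold)
        removed = tuple(n for n in panel if n not in kept)
        panel = kept
        if removed:
            steps.append(
                ReductionStep(0, removed, "correlation", tuple(panel))
            )
    cost_removed = tuple(n for n in panel if n in config.cost_exclusions)
    if cost_removed:
        panel = [n for n in panel if n not in config.cost_exclusions]
        steps.append(ReductionStep(len(steps), cost_removed, "cost", tuple(panel)))

    if config.target_size > len(panel):
        raise ValueError(
            f"target_size {config.target_size} exceeds pruned panel size {len(panel)}"
        )

    schedule = list(config.elimination_schedule)
    step_no = len(steps)
    while len(panel) > config.target_size:
        cfg = replace(clock_config, seed=clock_config.seed + step_no)
        features = panel + ["sex_code"]
        clock = train_clock(cfg, train, validation, feature_names=features)
        preds = clock.predict(validation.frame[features].to_numpy(dtype=float))
        metrics = evaluate(preds, validation.frame["age"].to_numpy(dtype=float))
        ranking = rank_features(
            clock,
            validation,
            train,
            config=config.attribution,
            n_explain=config.n_explain,
            seed=config.seed + step_no,
        )
        k = schedule.pop(0) if schedule else 1
        k = min(k, len(panel) - config.target_size)
        eliminable = ranking[~ranking["exempt"]]
        removed = tuple(eliminable["feature"].tail(k))
        panel = [n for n in panel if n not in removed]
        steps.append(
            ReductionStep(
                step_no, removed, "shap", tuple(panel),
                metrics=metrics, ranking=ranking,
            )
        )
        step_no += 1

    # final clock on the target-size panel
    cfg = replace(clock_config, seed=clock_config.seed + step_no)
    features = panel + ["sex_code"]
    final_clock = train_clock(cfg, train, validation, feature_names=features)
    preds = final_clock.predict(validation.frame[features].to_numpy(dtype=float))
    final_metrics = evaluate(preds, validation.frame["age"].to_numpy(dtype=float))
    return ReductionTrace(
        steps=steps,
        final_panel=tuple(panel),
        final_clock=final_clock,
        final_metrics=final_metrics,
    )
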