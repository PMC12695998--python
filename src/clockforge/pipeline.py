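"""End-to-end orchestration: simulate/ingest -> label -> select -> preprocess
-> split -> train -> correct -> (optional) reduce -> explain -> analyze.

Every run writes its artifacts plus a manifest (config hash, seed, stage list,
sha256 digest of every file) into the output directory; an identical config
reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, cohort, correction, explain, preprocess, reduction, simulate
from .clock import ClockConfig, evaluate, split_cohort, train_clock
from .config import PipelineConfig, config_digest

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stages_run: list[str] = []
    metrics: dict = {"seed": config.seed}

    def stage(name):
        stages_run.append(name)
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        if config.cohort_path is None:
            spec = simulate.SyntheticSpec(
                n_subjects=config.simulate.n_subjects,
                sigma_b=config.simulate.sigma_b,
                missing_rate=config.simulate.missing_rate,
                age_range=(config.simulate.age_min, config.simulate.age_max),
                seed=config.stage_seed("simulate"),
            )
            table, truth = simulate.generate_cohort(spec)
            truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            table = cohort.read_cohort(config.cohort_path)
    except Exception as err:  # noqa: BLE001
        raise StageError("ingest", err) from err

    try:
        stage("label")
        table = cohort.label_health(table)
        stage("select_panel")
        sel = cohort.select_panel(
            table,
            config.panel.min_markers_per_sample,
            config.panel.min_presence_fraction,
        )
        (out / "panel_selection.json").write_text(sel.to_json())
        table = cohort.apply_selection(table, sel)
    except Exception as err:  # noqa: BLE001
        raise StageError("select_panel", err) from err

    try:
        stage("split")
        healthy = table.healthy_subset()
        split = split_cohort(
            healthy, config.clock.fractions, seed=config.stage_seed("split")
        )
        parts = {
            p: healthy.with_frame(healthy.frame.loc[split.ids(p)].copy())
            for p in ("train", "validation", "test")
        }
        unhealthy = table.with_frame(table.frame[~table.frame["healthy"]].copy())
    except Exception as err:  # noqa: BLE001
        raise StageError("split", err) from err

    try:
        stage("preprocess")
        params = preprocess.PreprocessParams(
            outlier_fraction=config.preprocess.outlier_fraction,
            impute_floor=config.preprocess.impute_floor,
            fit_scope=config.preprocess.fit_scope,
            two_sided=config.preprocess.two_sided,
        )
        fit_on = (
            parts["train"]
            if params.fit_scope == "train_only"
            else table.healthy_subset()
        )
        train_t, fitted, trim_report = preprocess.preprocess_fit(
            fit_on, params, seed=config.stage_seed("preprocess")
        )
        trim_report.to_csv(out / "outlier_report.csv", index=False)
        if params.fit_scope == "train_only":
            pass  # train_t is the transformed training table
        else:
            train_t = fitted.apply(preprocess.encode_sex(parts["train"]))
        val_t = fitted.apply(preprocess.encode_sex(parts["validation"]))
        test_t = fitted.apply(preprocess.encode_sex(parts["test"]))
        unhealthy_t = fitted.apply(preprocess.encode_sex(unhealthy))
    except Exception as err:  # noqa: BLE001
        raise StageError("preprocess", err) from err

    try:
        stage("train")
        clock_cfg = ClockConfig(
            hidden_sizes=config.clock.hidden_sizes,
            learning_rate=config.clock.learning_rate,
            weight_decay=config.clock.weight_decay,
            batch_size=config.clock.batch_size,
            max_steps=config.clock.max_steps,
            eval_interval=config.clock.eval_interval,
            checkpoint=config.clock.checkpoint,
            seed=config.stage_seed("train"),
        )
        clock = train_clock(clock_cfg, train_t, val_t, preprocessor=fitted)
        feats = clock.feature_names
        raw_test = clock.predict(test_t.frame[feats].to_numpy(float))
        metrics["uncorrected_test"] = evaluate(
            raw_test, test_t.frame["age"].to_numpy(float)
        )
    except Exception as err:  # noqa: BLE001
        raise StageError("train", err) from err

    try:
        stage("correct")
        raw_train = clock.predict(train_t.frame[feats].to_numpy(float))
        corr = correction.fit_corrector(
            raw_train,
            train_t.frame["age"].to_numpy(float),
            alpha=config.correction.alpha,
            kernel=config.correction.kernel,
            min_count=config.correction.min_count,
        )
        (out / "corrector.json").write_text(corr.to_json())
        corrected = correction.apply_corrector(
            corr, raw_test, test_t.frame["age"].to_numpy(float)
        )
        metrics["corrected_test"] = evaluate(
            corrected["biological_age"], test_t.frame["age"].to_numpy(float)
        )
        sk = correction.skew_metrics(raw_test, test_t.frame["age"].to_numpy(float))
        metrics["uncorrected_slope"] = sk["slope"]
        sk_c = correction.skew_metrics(
            corrected["biological_age"], test_t.frame["age"].to_numpy(float)
        )
        metrics["corrected_slope"] = sk_c["slope"]
    except Exception as err:  # noqa: BLE001
        raise StageError("correct", err) from err

    if config.reduction.enabled:
        try:
            stage("reduce")
            red_cfg = reduction.ReductionConfig(
                correlation_threshold=config.reduction.correlation_threshold,
                elimination_schedule=config.reduction.elimination_schedule,
                cost_exclusions=frozenset(config.reduction.cost_exclusions),
                target_size=config.reduction.target_size,
                seed=config.stage_seed("reduce"),
                n_explain=config.reduction.n_explain,
            )
            trace = reduction.iterate_reduction(train_t, val_t, clock_cfg, red_cfg)
            trace.to_frame().to_csv(out / "reduction_trace.csv", index=False)
            metrics["final_panel"] = list(trace.final_panel)
            metrics["reduced_metrics"] = trace.final_metrics
        except Exception as err:  # noqa: BLE001
            raise StageError("reduce", err) from err

    try:
        stage("explain")
        ex_cfg = explain.AttributionConfig(
            window=config.explain.window,
            min_background=min(config.explain.min_background, max(2, train_t.n_samples // 2)),
            n_permutations=config.explain.n_permutations,
            seed=config.stage_seed("explain"),
        )
        sub = test_t.with_frame(test_t.frame.head(config.explain.n_samples).copy())
        reports = explain.explain_cohort(clock, sub, train_t, corrector=corr, config=ex_cfg)
        explain.reports_to_frame(reports).to_csv(out / "attributions.csv", index=False)
    except Exception as err:  # noqa: BLE001
        raise StageError("explain", err) from err

    try:
        stage("analyze")
        raw_unhealthy = clock.predict(unhealthy_t.frame[feats].to_numpy(float))
        corr_unhealthy = correction.apply_corrector(
            corr, raw_unhealthy, unhealthy_t.frame["age"].to_numpy(float)
        )
        codes = unhealthy_t.frame["icd_codes"]
        top = (
            pd.Series([c for s in codes for c in s]).value_counts().head(10).index
            if len(unhealthy_t.frame)
            else []
        )
        groups = {}
        for code in top:
            mask = analysis.single_code_mask(codes, code).to_numpy()
            if mask.sum() >= 5:
                groups[code] = corr_unhealthy["acceleration"].to_numpy()[mask]
        ref = correction.apply_corrector(
            corr, raw_test, test_t.frame["age"].to_numpy(float)
        )["acceleration"].to_numpy()
        comps = analysis.compare_groups(
            groups, ref, seed=config.stage_seed("analyze")
        )
        metrics["group_comparisons"] = [vars(c) for c in comps]
    except Exception as err:  # noqa: BLE001
        raise StageError("analyze", err) from err

    _write_json(out / "metrics.json", metrics)
    manifest = {
        "config_digest": config_digest(config),
        "seed": config.seed,
        "stages": stages_run,
        "files": {
            p.name: _digest(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(out / "manifest.json", manifest)
    return out
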