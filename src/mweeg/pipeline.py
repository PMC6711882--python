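"""End-to-end orchestration: simulate -> extract -> label -> classify -> evaluate.

A run is a pure function of its :class:`RunConfig`: the same config (and its
seeds) reproduces the same outputs bit for bit. Each stage writes its outputs
under the run directory and the run closes with a manifest recording the
config hash, package version, per-stage timings and collected warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import classify, evaluate, labeling, spectral, sterp, synth

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable description of a full synthetic-cohort run."""

    seed: int = 0
    tasks: tuple[str, ...] = ("SART", "VS")
    n_subjects: int = 4
    #: per-subject mind-wandering rates; None draws them from a truncated
    #: normal matching the observed between-subject spread
    mw_rates: tuple[float, ...] | None = None
    mw_rate_mean: float = 0.38
    mw_rate_sd: float = 0.15
    mw_rate_range: tuple[float, float] = (0.16, 0.82)
    n_blocks: int = 12
    n_probes: int = 54
    probe_gaps: tuple[int, int] = (7, 24)
    epochs_for: str = "labeled"
    gen_overrides: dict = field(default_factory=dict)
    normalization_scope: str = "global"
    model: classify.ModelSpec = field(default_factory=classify.ModelSpec)
    min_trials_per_cell: int = labeling.MIN_TRIALS_PER_CELL
    run_single_markers: bool = False
    n1_window_hi_ms: float = 200.0   # set 230 for the widened N1 search

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            m = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in d["model"].items()}
            d["model"] = classify.ModelSpec(**m)
        for key in ("tasks", "probe_gaps", "mw_rate_range", "mw_rates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(self.to_dict()))))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Check every design/band/model invariant; returns violations (empty = ok)."""
    v = []
    for task in config.tasks:
        if task not in synth.TRIALS_PER_BLOCK:
            v.append(f"tasks: unknown task {task!r}")
    if config.n_subjects < 1:
        v.append("n_subjects: must be >= 1")
    if config.n_probes < 1:
        v.append("n_probes: must be >= 1")
    g = config.probe_gaps
    if not (7 <= g[0] <= g[1] <= 24):
        v.append(f"probe_gaps: {g} outside [7, 24]")
    if config.mw_rates is not None and any(not 0 <= r <= 1 for r in config.mw_rates):
        v.append("mw_rates: outside [0, 1]")
    lo, hi = config.mw_rate_range
    if not 0 <= lo < hi <= 1:
        v.append(f"mw_rate_range: {config.mw_rate_range} invalid")
    for band in spectral.DEFAULT_BANDS:
        if not band.lo < band.hi:
            v.append(f"band {band.name}: lo >= hi")
    try:
        gen = synth.GenParams(**config.gen_overrides)
        v += [f"gen: {msg}" for msg in gen.validate()]
    except TypeError as e:
        v.append(f"gen_overrides: {e}")
    try:
        _ = config.model if isinstance(config.model, classify.ModelSpec) \
            else classify.ModelSpec(**config.model)
    except ValueError as e:
        v.append(f"model: {e}")
    if config.normalization_scope not in ("global", "train_fold_only"):
        v.append(f"normalization_scope: {config.normalization_scope!r}")
    if config.epochs_for not in ("all", "labeled"):
        v.append(f"epochs_for: {config.epochs_for!r}")
    return v


def _subject_mw_rates(config: RunConfig, rng: np.random.Generator) -> np.ndarray:
    if config.mw_rates is not None:
        return np.asarray(config.mw_rates, dtype=float)
    lo, hi = config.mw_rate_range
    draws = rng.normal(config.mw_rate_mean, config.mw_rate_sd, size=4 * config.n_subjects)
    draws = draws[(draws >= lo) & (draws <= hi)]
    while draws.size < config.n_subjects:  # pragma: no cover - extreme configs
        draws = np.concatenate([draws, rng.uniform(lo, hi, config.n_subjects)])
    return draws[:config.n_subjects]


def _components_for(config: RunConfig):
    if config.n1_window_hi_ms != 200.0:
        return sterp.with_n1_window(window_ms=(100.0, config.n1_window_hi_ms))
    return sterp.DEFAULT_COMPONENTS


def run_subject_task(subject: int, task: str, mw_rate: float, config: RunConfig,
                     seed: int):
    """Simulate and fully process one subject on one task.

    Returns a dict with the labeled feature table, label/behavior summaries
    and trial counts; the heavy intermediates (epochs) are not retained.
    """
    gen = synth.GenParams(**{"mw_rate": mw_rate, **config.gen_overrides})
    epochs, probes, design = synth.simulate_session(
        task, gen, seed=seed, epochs_for=config.epochs_for,
        design_kwargs={"n_blocks": config.n_blocks, "n_probes": config.n_probes,
                       "probe_gaps": config.probe_gaps})
    labels = labeling.select_trials(design, probes)
    counts = labeling.label_counts(labels, epochs.trials)
    clean = epochs.trials.loc[~epochs.trials["artifact"].astype(bool), "trial_id"]
    labels = labels[labels["trial_id"].isin(clean)].reset_index(drop=True)
    sub = epochs.select_trials(labels["trial_id"].to_numpy())
    erp = sterp.extract_erp_features(sub, _components_for(config))
    spec_feats = spectral.extract_spectral_features(sub)
    table = classify.assemble_features(erp, spec_feats, labels)
    behav = sub.trials.groupby("state", observed=True).agg(
        accuracy=("correct", "mean"), rt_ms=("rt_ms", "mean")).reset_index()
    return {"subject": subject, "task": task, "mw_rate": mw_rate,
            "counts": counts, "table": table, "behavior": behav,
            "n_probes_labeled": labels["source_probe"].nunique()}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline for a synthetic cohort and write a run dir.

    Stages: simulate+extract per subject and task, apply inclusion criteria,
    per-subject LOOCV and (with two tasks) across-task transfer, optional
    single-marker models, then group-level evaluation. Any stage error aborts
    the run with the failing stage named. Returns the manifest dict.
    """
    bad = validate_config(config)
    if bad:
        raise ValueError("invalid config: " + "; ".join(bad))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": _version, "config": config.to_dict(),
                "config_hash": config.config_hash(), "stages": {}, "warnings": []}
    collected: list[str] = []
    t_all = time.time()

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                self_inner.ctx = warnings.catch_warnings(record=True)
                self_inner.log = self_inner.ctx.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                collected.extend(f"{name}: {w.message}" for w in self_inner.log)
                self_inner.ctx.__exit__(None, None, None)
                manifest["stages"][name] = {"seconds": round(time.time() - self_inner.t0, 3)}
                if exc_type is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return _Stage()

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    mw_rates = _subject_mw_rates(config, rng)

    results = []
    with stage("simulate_extract_label"):
        if config.n_probes < 1:
            raise ValueError("labeling requires at least one probe")
        subj_seeds = ss.spawn(config.n_subjects * len(config.tasks))
        k = 0
        for subject in range(config.n_subjects):
            for task in config.tasks:
                seed = int(subj_seeds[k].generate_state(1)[0] % (2 ** 31))
                k += 1
                results.append(run_subject_task(subject, task, float(mw_rates[subject]),
                                                config, seed))

    with stage("inclusion"):
        counts = {}
        for r in results:
            counts.setdefault(r["subject"], {})[r["task"]] = r["counts"]
        inclusion = labeling.apply_inclusion_criteria(
            counts, config.min_trials_per_cell, out_dir / "inclusion.json")
        included = set(inclusion["included"])

    with stage("classify"):
        per_subject = []
        all_preds = []
        tables = {(r["subject"], r["task"]): r["table"] for r in results}
        for r in results:
            if r["subject"] not in included:
                continue
            preds, m = classify.loocv(r["table"], config.model,
                                      scope=config.normalization_scope)
            m.update({"subject": r["subject"], "task": r["task"],
                      "mw_rate": r["mw_rate"]})
            per_subject.append(m)
            preds.insert(0, "subject", r["subject"])
            preds.insert(1, "task", r["task"])
            all_preds.append(preds)
        if len(config.tasks) == 2:
            t1, t2 = config.tasks
            for subject in sorted(included):
                for tr, te in ((t1, t2), (t2, t1)):
                    preds, m = classify.cross_task_predict(
                        tables[(subject, tr)], tables[(subject, te)],
                        config.model, scope=config.normalization_scope)
                    m.update({"subject": subject, "task": f"{tr}-{te}",
                              "mw_rate": float(mw_rates[subject])})
                    per_subject.append(m)
                    preds.insert(0, "subject", subject)
                    preds.insert(1, "task", f"{tr}-{te}")
                    all_preds.append(preds)
        metrics = pd.DataFrame(per_subject)
        predictions = pd.concat(all_preds, ignore_index=True) if all_preds \
            else pd.DataFrame()
        predictions.to_csv(out_dir / "predictions.csv", index=False)
        metrics.to_csv(out_dir / "metrics.csv", index=False)

    single_markers = None
    if config.run_single_markers and len(config.tasks) == 2:
        with stage("single_markers"):
            rows = []
            for subject in sorted(included):
                pooled = pd.concat(
                    [classify.zscore(tables[(subject, t)], "global")
                     for t in config.tasks], ignore_index=True)
                sm = classify.single_marker_models(pooled, config.model)
                sm.insert(0, "subject", subject)
                rows.append(sm)
            single_markers = pd.concat(rows, ignore_index=True)
            single_markers.to_csv(out_dir / "single_markers.csv", index=False)

    with stage("evaluate"):
        sections = {"cohort": {"n_subjects": config.n_subjects,
                               "included": sorted(included),
                               "mw_rates": [float(x) for x in mw_rates]},
                    "classification": metrics}
        group = {}
        for scheme_task in metrics["task"].unique():
            sub = metrics[metrics["task"] == scheme_task]
            if len(sub) >= 2 and sub["accuracy"].std(ddof=1) > 0:
                r = evaluate.one_sample_t(sub["accuracy"], 0.5)
                group[f"accuracy_vs_chance[{scheme_task}]"] = dataclasses.asdict(r)
        # classifier-bias correlations need rate spread and enough subjects
        loo = metrics[metrics["scheme"] == "loocv"]
        for task in config.tasks:
            sub = loo[loo["task"] == task].dropna(subset=["sensitivity",
                                                          "specificity"])
            if len(sub) >= 3 and sub["mw_rate"].nunique() > 1:
                try:
                    for metric in ("sensitivity", "specificity"):
                        rho, p = evaluate.spearman(sub["mw_rate"], sub[metric])
                        group[f"spearman_mw_{metric}[{task}]"] = {"rho": rho, "p": p}
                except ValueError:
                    pass
        sections["group_stats"] = group
        if single_markers is not None:
            sections["single_markers"] = single_markers
        report = evaluate.build_report(sections, out_dir)

    manifest["warnings"] = collected
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    blob = json.dumps(manifest, indent=1, sort_keys=True, default=str)
    (out_dir / "manifest.json").write_text(blob)
    manifest["report"] = report
    return manifest
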