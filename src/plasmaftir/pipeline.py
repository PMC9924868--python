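"""End-to-end analysis orchestration.

One :class:`RunConfig` drives the whole chain — simulate (or load) spectra,
preprocess, band-ratio features, univariate statistics, then for every
requested region x model: nested-CV tuning, test-set evaluation, permutation
significance and a wavenumber-importance profile — writing a machine-readable
summary plus per-stage outputs into a run directory.  A single master seed
deterministically derives every stage seed, so identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SpectraSet, read_spectra_csv, write_spectra_csv
from .simulate import CohortConfig, default_band_library, generate_cohort
from .preprocess import PreprocessConfig, RegionSpec, run_preprocess
from .features import compute_ratios
from .stats import t_test_two_sample
from .classify import (
    CVScheme,
    ModelSpec,
    default_mtry_grid,
    make_split,
    tune_and_refit,
)
from .evaluate import (
    confusion_from_predictions,
    confusion_metrics,
    evaluate_subgroups,
    importance_pls,
    importance_rf,
    importance_rocfilter,
    permutation_test_accuracy,
    roc_auc,
    smooth_roc,
)

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]

RATIO_COLUMNS = ("lipid_protein_intensity", "lipid_protein_area", "lipid_oxidation")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2^31 from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Settings for one full analysis run.

    ``input_csv = None`` simulates a cohort with ``simulate`` overrides
    (CohortConfig field names).  ``permutation_mode`` is "full" (re-tune the
    grid inside every permutation), "fixed" (re-run split/refit/test at the
    observed tuning value — used when the budget is tight) or "off".
    """

    input_csv: str | None = None
    simulate: dict = field(default_factory=dict)
    regions: tuple[str, ...] = ("fingerprint", "high")
    models: tuple[str, ...] = ("pca_lda", "pls_da", "rf")
    derivative: str = "second"
    sg_window: int = 13
    sg_polyorder: int = 2
    train_fraction: float = 0.75
    cv_k: int = 5
    cv_repeats: int = 10
    pls_grid: tuple[int, ...] = tuple(range(1, 11))
    rf_n_trees: int = 500
    rf_grid: tuple[int, ...] | None = None  # None -> default_mtry_grid(p)
    n_permutations: int = 0
    permutation_mode: str = "full"
    seed: int = 0
    out_dir: str = "runs/latest"

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # output location does not change run identity
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _load_or_simulate(config: RunConfig) -> SpectraSet:
    if config.input_csv:
        return read_spectra_csv(config.input_csv)
    overrides = dict(config.simulate)
    mult = overrides.pop("ms_multipliers", None)
    if mult is not None:
        overrides["band_library"] = default_band_library(
            {float(k): float(v) for k, v in mult.items()}
        )
    overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
    return generate_cohort(CohortConfig(**overrides))


def _model_spec(config: RunConfig, method: str, p: int, seed: int) -> ModelSpec:
    if method == "pls_da":
        grid = tuple(g for g in config.pls_grid if g <= p)
        return ModelSpec(method, tuning_grid=grid, seed=seed)
    if method == "rf":
        grid = tuple(config.rf_grid) if config.rf_grid else default_mtry_grid(p)
        return ModelSpec(method, tuning_grid=tuple(g for g in grid if g <= p),
                         n_trees=config.rf_n_trees, seed=seed)
    return ModelSpec(method, seed=seed)


def _analyse_model(
    config: RunConfig, region: str, method: str, processed: SpectraSet
) -> dict:
    """Split, tune, refit, evaluate one region x model cell."""
    X = processed.intensities
    y = processed.class_labels
    ids = processed.subject_ids
    seed = stage_seed(config.seed, f"{region}:{method}")
    cv = CVScheme(k=config.cv_k, repeats=config.cv_repeats, seed=seed)
    spec = _model_spec(config, method, X.shape[1], seed)

    def protocol(Xa, ya, record_trace=False):
        plan = make_split(
            subject_ids=ids, class_labels=ya,
            train_fraction=config.train_fraction, seed=seed,
        )
        tr = np.isin(ids, plan.train_ids)
        te = ~tr
        fitted = tune_and_refit(Xa[tr], ya[tr], spec, cv, record_trace=record_trace)
        pred = fitted.predict(Xa[te])
        acc = float((pred == ya[te]).mean())
        return plan, tr, te, fitted, pred, acc

    plan, tr, te, fitted, pred, test_acc = protocol(X, y, record_trace=True)
    cm = confusion_from_predictions(y[te], pred)
    sens, spcf, acc = confusion_metrics(cm)
    scores = fitted.decision_function(X[te])
    roc = roc_auc(scores, y[te])
    smoothed = smooth_roc(scores, y[te])
    subgroups = evaluate_subgroups(pred, processed.meta.iloc[np.flatnonzero(te)])

    perm_p = np.nan
    if config.n_permutations > 0 and config.permutation_mode != "off":
        if config.permutation_mode == "fixed":
            perm_spec = ModelSpec(
                method,
                tuning_grid=(
                    (fitted.chosen_tuning_value,) if method != "pca_lda" else ()
                ),
                n_trees=config.rf_n_trees, seed=seed,
            )
        else:
            perm_spec = spec

        def perm_pipeline(Xa, ya):
            plan_p = make_split(
                subject_ids=ids, class_labels=ya,
                train_fraction=config.train_fraction, seed=seed,
            )
            trp = np.isin(ids, plan_p.train_ids)
            f = tune_and_refit(Xa[trp], ya[trp], perm_spec, cv,
                               record_trace=False)
            return (f.predict(Xa[~trp]) == ya[~trp]).mean()

        perm_p, _, _ = permutation_test_accuracy(
            perm_pipeline, X, y,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, f"perm:{region}:{method}"),
        )

    if method == "pls_da":
        imp = importance_pls(fitted, processed.wavenumbers)
    elif method == "rf":
        imp = importance_rf(fitted, processed.wavenumbers)
    else:
        imp = importance_rocfilter(X[tr], y[tr], processed.wavenumbers)

    cv_acc = [m["accuracy"] for m in fitted.cv_trace]
    return {
        "region": region,
        "model": method,
        "n_train": int(tr.sum()),
        "n_test": int(te.sum()),
        "chosen_tuning_value": fitted.chosen_tuning_value,
        "cv_accuracy_mean": float(np.mean(cv_acc)) if cv_acc else np.nan,
        "cv_trace": fitted.cv_trace,
        "confusion": {"tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp},
        "sensitivity": sens,
        "specificity": spcf,
        "accuracy": acc,
        "auc": roc.auc,
        "auc_smoothed": smoothed.auc,
        "permutation_p": perm_p,
        "subgroups": subgroups,
        "importance": imp,
        "test_ids": list(plan.test_ids),
    }


def run_full_analysis(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Outputs: ``spectra.csv`` (raw cohort), ``features.csv`` (per-subject
    band ratios), ``stats.csv`` (HC vs MS t-tests on the ratios), per-cell
    ``evaluation_<region>_<model>.json`` and ``importance_<region>_<model>.csv``,
    ``summary.csv`` (one row per region x model) and ``run_log.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log: dict = {"config": asdict(config), "config_hash": cfg_hash,
                 "stages": []}

    def _stage(name):
        log["stages"].append({"stage": name, "t": time.time()})

    try:
        _stage("load")
        raw = _load_or_simulate(config)
        write_spectra_csv(raw, out / "spectra.csv")

        _stage("features")
        full = RegionSpec("custom", float(raw.wavenumbers.min()),
                          float(raw.wavenumbers.max()))
        absorb = run_preprocess(
            raw, PreprocessConfig(region=full, derivative="none")
        )
        feats = compute_ratios(absorb)
        _write_csv(feats, out / "features.csv", cfg_hash)

        _stage("stats")
        stat_rows = []
        for col in RATIO_COLUMNS:
            hc = feats.loc[feats["class_label"] == "HC", col].dropna()
            ms = feats.loc[feats["class_label"] == "MS", col].dropna()
            if len(hc) >= 2 and len(ms) >= 2:
                res = t_test_two_sample(ms, hc, variant="student")
                stat_rows.append(
                    {"feature": col, "method": res.method,
                     "statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value, "stars": res.stars}
                )
        _write_csv(pd.DataFrame(stat_rows), out / "stats.csv", cfg_hash)

        summary_rows = []
        for region in config.regions:
            _stage(f"preprocess:{region}")
            processed = run_preprocess(
                raw,
                PreprocessConfig(
                    region=RegionSpec(region),
                    derivative=config.derivative,
                    sg_window=config.sg_window,
                    sg_polyorder=config.sg_polyorder,
                ),
            )
            for method in config.models:
                _stage(f"model:{region}:{method}")
                cell = _analyse_model(config, region, method, processed)
                imp = cell.pop("importance")
                subgroups = cell.pop("subgroups")
                _write_csv(
                    imp.frame(),
                    out / f"importance_{region}_{method}.csv",
                    cfg_hash,
                )
                cell_json = dict(
                    cell,
                    config_hash=cfg_hash,
                    subgroups=subgroups.to_dict(orient="records"),
                )
                with open(out / f"evaluation_{region}_{method}.json", "w") as fh:
                    json.dump(cell_json, fh, indent=2, default=float)
                summary_rows.append(
                    {
                        "region": region,
                        "model": method,
                        "chosen_tuning_value": cell["chosen_tuning_value"],
                        "cv_accuracy_mean": cell["cv_accuracy_mean"],
                        "sensitivity": cell["sensitivity"],
                        "specificity": cell["specificity"],
                        "accuracy": cell["accuracy"],
                        "auc": cell["auc"],
                        "auc_smoothed": cell["auc_smoothed"],
                        "permutation_p": cell["permutation_p"],
                        "config_hash": cfg_hash,
                    }
                )

        _stage("summary")
        _write_csv(pd.DataFrame(summary_rows), out / "summary.csv", cfg_hash)
        log["status"] = "OK"
    except Exception as exc:
        stage = log["stages"][-1]["stage"] if log["stages"] else "init"
        log["status"] = "FAILED"
        log["failed_stage"] = stage
        log["error"] = repr(exc)
        (out / "FAILED").write_text(f"{stage}: {exc!r}\n")
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return out
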