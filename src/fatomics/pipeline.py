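"""End-to-end orchestration: extract -> select -> fit -> evaluate.

The stages mirror how the modeling study is run: per-study feature
extraction into a CSV, an event-stratified 80/20 train/test split, mRMR +
Cox elastic-net fitting on the training split only, and an evaluation
report covering training, bootstrap-validation and held-out test metrics,
median-split Kaplan-Meier stratification, and categorical NRI against an
EAT-volume-only reference model.

Every run records an audit log of which study ids each stage touched, so
leakage of test subjects into selection or fitting is checkable after the
fact (:func:`assert_no_leakage`).
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import evaluation as ev
from .extraction import FatWindow
from .features import default_catalog, extract_all
from .imaging import read_mask, read_volume
from .modeling import (
    CoxEnetModel,
    MRMRSelector,
    fit_cox_elastic_net,
    filter_min_followup,
    univariable_cox,
)

__all__ = ["PipelineConfig", "cmd_extract", "cmd_fit_eval", "assert_no_leakage"]

log = logging.getLogger("fatomics")


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; defaults follow the study design."""

    fat_lo: float = -190.0  # adipose HU window
    fat_hi: float = -30.0
    mrmr_k: int = 50  # 148 -> 50 reduction
    l1_ratio: float = 0.8  # elastic-net mixing alpha
    folds: int = 10  # CV folds for lambda
    max_features: int = 15  # final active-set cap
    bootstrap_iterations: int = 1000
    auc_horizon_years: float = 2.0
    test_fraction: float = 0.2  # event-stratified held-out split
    min_followup_days: float = 10.0
    ray_step_mm: float | None = None  # default: min(spacing)/2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def window(self) -> FatWindow:
        return FatWindow(self.fat_lo, self.fat_hi)


def cmd_extract(manifest, out_csv=None, config: PipelineConfig | None = None):
    """Extract the 148-feature vector for every study in the manifest.

    ``manifest`` is a DataFrame (or CSV path) with columns
    ``study_id, volume, mask``. Per-study failures are logged and collected
    without aborting the batch. Returns ``(features_df, failures)``.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if len(manifest) == 0:
        raise ValueError("empty study manifest")
    catalog = default_catalog(config.window)
    rows, failures = {}, {}
    for rec in manifest.itertuples(index=False):
        t0 = _time.perf_counter()
        try:
            vol = read_volume(rec.volume)
            sac = read_mask(rec.mask)
            fv = extract_all(vol, sac, config.window, catalog, config.ray_step_mm)
            rows[rec.study_id] = fv.values
            log.info("extracted %s in %.1fs", rec.study_id, _time.perf_counter() - t0)
        except Exception as exc:  # per-study isolation is the contract
            failures[rec.study_id] = f"{type(exc).__name__}: {exc}"
            log.error("failed %s: %s", rec.study_id, failures[rec.study_id])
    features = pd.DataFrame.from_dict(rows, orient="index", columns=catalog.names)
    features.index.name = "study_id"
    if out_csv is not None:
        features.to_csv(out_csv)
    return features, failures


def assert_no_leakage(audit: dict) -> None:
    """Raise if any test-split subject appears in a selection/fitting stage."""
    test_ids = set(audit["test_ids"])
    for stage in ("mrmr", "fit", "bootstrap"):
        touched = set(audit.get(stage, ()))
        leaked = touched & test_ids
        if leaked:
            raise AssertionError(f"stage {stage!r} touched test subjects: {sorted(leaked)[:5]}")


def cmd_fit_eval(
    features,
    survival,
    config: PipelineConfig | None = None,
    out_model=None,
    out_report=None,
    reference_feature: str = "EAT_vol",
):
    """Event-stratified split, mRMR + elastic net on training, full report.

    Returns ``(model, report)`` where ``report`` carries training, bootstrap
    and test metrics (C-index, AUC at the configured horizon, AIC, risk-score
    HR), median-split KM stratification for both splits, categorical NRI
    against the single-feature reference model, the resolved configuration
    and the audit log of study ids touched per stage.
    """
    config = config or PipelineConfig()
    if not isinstance(features, pd.DataFrame):
        features = pd.read_csv(features, index_col="study_id")
    if not isinstance(survival, pd.DataFrame):
        survival = pd.read_csv(survival, index_col="study_id")
    survival = filter_min_followup(survival, config.min_followup_days)
    common = features.index.intersection(survival.index)
    if len(common) == 0:
        raise ValueError("no overlapping study_ids between features and survival tables")
    X = features.loc[common]
    surv = survival.loc[common]
    time = surv["time_days"].to_numpy(float)
    event = surv["event"].to_numpy(int)

    idx = np.arange(len(common))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=config.test_fraction,
        stratify=event,
        random_state=config.seed,
        shuffle=True,
    )
    if event[train_idx].sum() < 2 or event[test_idx].sum() < 2:
        raise ValueError("fewer than 2 events in a split")
    audit = {
        "train_ids": sorted(common[train_idx]),
        "test_ids": sorted(common[test_idx]),
    }
    X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
    y_tr = (time[train_idx], event[train_idx])
    y_te = (time[test_idx], event[test_idx])

    log.info("mRMR selection (k=%d) on %d training subjects", config.mrmr_k, len(train_idx))
    selector = MRMRSelector(k=config.mrmr_k).fit(X_tr, y_tr)
    audit["mrmr"] = audit["train_ids"]
    selected50 = selector.selected_features_

    log.info("Cox elastic net (alpha=%.2f, %d folds, cap %d)", config.l1_ratio,
             config.folds, config.max_features)
    model = fit_cox_elastic_net(
        X_tr[selected50], y_tr,
        alpha=config.l1_ratio, folds=config.folds, seed=config.seed,
        max_features=config.max_features,
    )
    audit["fit"] = audit["train_ids"]
    est = model.estimator_

    scores_tr = est.predict(X_tr[selected50])
    scores_te = est.predict(X_te[selected50])

    def _split_metrics(scores, y, y_train=None):
        out = {"c_index": ev.concordance_index(scores, y)}
        try:
            out["auc_2y"] = ev.time_dependent_auc(
                scores, y, config.auc_horizon_years, y_train=y_train
            )
        except ValueError as exc:
            out["auc_2y"] = None
            out["auc_2y_note"] = str(exc)
        return out

    report = {
        "config": config.to_dict(),
        "selected_50": selected50,
        "model_features": model.feature_names,
        "training": _split_metrics(scores_tr, y_tr),
        "test": _split_metrics(scores_te, y_te, y_train=y_tr),
    }
    if model.feature_names:
        report["training"]["aic"] = ev.aic(X_tr, y_tr, model.feature_names)
        report["training"]["score_hr"] = univariable_cox(scores_tr, y_tr)
    report["km"] = {
        "train": _km_summary(scores_tr, y_tr),
        "test": _km_summary(scores_te, y_te),
    }
    if config.bootstrap_iterations >= 2 and model.feature_names:
        audit["bootstrap"] = audit["train_ids"]
        report["bootstrap"] = ev.bootstrap_validate(
            X_tr, y_tr, model.feature_names,
            iterations=config.bootstrap_iterations, seed=config.seed,
            folds=config.folds, l1_ratio=config.l1_ratio,
        )
    if reference_feature in X.columns:
        ref_model = fit_cox_elastic_net(
            X_tr[[reference_feature]], y_tr, alpha=config.l1_ratio,
            folds=config.folds, seed=config.seed, max_features=None,
        )
        ref_est = ref_model.estimator_
        try:
            report["nri_vs_reference"] = {
                "reference": reference_feature,
                "train": ev.categorical_nri(
                    scores_tr, ref_est.predict(X_tr[[reference_feature]]), y_tr,
                    config.auc_horizon_years,
                ),
                "test": ev.categorical_nri(
                    scores_te, ref_est.predict(X_te[[reference_feature]]), y_te,
                    config.auc_horizon_years,
                ),
            }
        except ValueError as exc:
            report["nri_vs_reference"] = {"reference": reference_feature, "note": str(exc)}
    report["audit"] = audit
    assert_no_leakage(audit)

    if out_model is not None:
        model.to_json(out_model)
    if out_report is not None:
        with open(out_report, "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    return model, report


def _km_summary(scores, y) -> dict:
    try:
        km = ev.km_stratify(scores, y)
    except ValueError as exc:
        return {"note": str(exc)}
    return {
        "logrank_p": km["logrank_p"],
        "group_hr": km["group_hr"],
        "median_survival_high_days": _median_survival(km["curves"]["high"]),
        "median_survival_low_days": _median_survival(km["curves"]["low"]),
    }


def _median_survival(curve: pd.DataFrame):
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
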