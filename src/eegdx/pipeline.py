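"""End-to-end orchestration: simulate -> features -> select -> classify -> report.

``run_pipeline`` realizes the whole protocol on a synthetic cohort and
leaves a self-describing artifact tree: the configuration copy, cohort
manifest, feature matrix, selection report, per-subject predictions,
confusion matrix and metrics JSON.  Identical config + seed gives identical
artifacts.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bumps import MorletParams
from .classify import SelectionConfig, SVMConfig, loso_evaluate
from .config import RunConfig
from .epen import EpEnConfig
from .features import extract_cohort_features
from .preprocess import bandpass_1_30
from .report import compare_feature_table
from .synth import CohortSpec, generate_cohort

log = logging.getLogger("eegdx")

__all__ = ["run_pipeline", "simulate_cohort", "compute_features", "evaluate_features"]


def simulate_cohort(config: RunConfig):
    """Generate the synthetic cohort described by the config (group-merged later)."""
    c = config.cohort
    spec = CohortSpec(
        n_per_group=dict(c.n_per_group),
        fs=c.fs,
        duration=c.duration,
        effect_entropy=c.effect_entropy,
        effect_theta_bursts=c.effect_theta_bursts,
        effect_beta_bursts=c.effect_beta_bursts,
        noise_sd=c.noise_sd,
        alpha_snr=c.alpha_snr,
        seed=config.seed,
    )
    if config.group_scheme == "2":
        spec.n_per_group = {g: spec.n_per_group.get(g, 0) for g in ("SCI", "AD")}
    return generate_cohort(spec)


def compute_features(cohort, config: RunConfig) -> pd.DataFrame:
    """1-30 Hz prefilter then the primary feature bank for every subject."""
    epen_cfg = EpEnConfig(seed=config.seed, **config.epen.model_dump())
    morlet = MorletParams(
        cycles=config.morlet.cycles,
        f_min=config.morlet.f_min,
        f_max=config.morlet.f_max,
        f_step=config.morlet.f_step,
    )
    filtered = [bandpass_1_30(rec) for rec in cohort]
    return extract_cohort_features(
        filtered, epen_cfg, morlet, bm_agg=config.morlet.agg, subset=config.feature_subset
    )


def _merged_groups(features: pd.DataFrame, config: RunConfig) -> pd.Series:
    groups = features["group"].copy()
    if config.group_scheme == "3":
        groups = groups.replace({"MCI": "Other", "OtherPath": "Other"})
    return groups


def evaluate_features(features: pd.DataFrame, config: RunConfig):
    """LOSO evaluation of an already computed feature table."""
    groups = _merged_groups(features, config)
    primary = features.drop(columns="group")
    svm_cfg = SVMConfig(seed=config.seed, **config.svm.model_dump())
    sel_cfg = SelectionConfig(seed=config.seed, **config.selection.model_dump())
    return loso_evaluate(primary, groups, svm_cfg, sel_cfg)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full protocol; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    t0 = time.time()
    try:
        config.to_yaml(out / "config.yaml")
        log.info("simulating cohort (seed=%d)", config.seed)
        cohort = simulate_cohort(config)
        pd.DataFrame(
            {"subject_id": [r.subject_id for r in cohort],
             "group": [r.group for r in cohort]}
        ).to_csv(out / "manifest.csv", index=False)

        log.info("extracting features for %d subjects", len(cohort))
        features = compute_features(cohort, config)
        features.to_csv(out / "features.csv")

        log.info("LOSO evaluation (%s-group scheme)", config.group_scheme)
        result = evaluate_features(features, config)
        result.predictions.to_csv(out / "predictions.csv")
        result.confusion.to_frame().to_csv(out / "confusion.csv")

        # selection report: how often each feature was chosen across folds
        freq: dict[str, dict[str, int]] = {}
        for fold in result.fold_info:
            for pair, feats in fold["selected"].items():
                bucket = freq.setdefault(pair, {})
                for f in feats:
                    bucket[f] = bucket.get(f, 0) + 1
        n_folds = len(result.fold_info)
        selection_report = {
            pair: {f: c / n_folds for f, c in sorted(b.items(), key=lambda kv: -kv[1])}
            for pair, b in freq.items()
        }
        (out / "selection_report.json").write_text(json.dumps(selection_report, indent=1))

        groups = _merged_groups(features, config)
        labels = result.confusion.labels
        stats = (
            compare_feature_table(features.drop(columns="group"), groups, labels[0], labels[1])
            if len(labels) >= 2 else pd.DataFrame()
        )
        stats.to_csv(out / "group_stats.csv")

        metrics = {
            "accuracy": result.accuracy,
            "sensitivity": result.confusion.sensitivity,
            "specificity": result.confusion.specificity,
            "confusion_percent": result.confusion.percent.tolist(),
            "labels": labels,
            "n_subjects": int(len(features)),
            "seed": config.seed,
            "runtime_s": round(time.time() - t0, 2),
            "versions": {"eegdx": __version__, "python": platform.python_version(),
                         "numpy": np.__version__},
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        log.info("done in %.1f s: accuracy %.3f", time.time() - t0, result.accuracy)
        return out
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
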