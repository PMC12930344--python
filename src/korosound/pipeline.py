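"""End-to-end orchestration: simulate -> features -> stats -> classify.

One config drives every stage; two runs with the same config produce
identical ``features.csv`` and ``report.json`` (all randomness flows
from the recorded seed).  Artifacts land in the output directory:

* ``features.csv``    — ten features + subject_id + group label per recording
* ``cohort.csv``      — simulated subject metadata
* ``report.json``     — group comparisons, logistic fit, correlations,
                        adjusted models (Table-style analogues)
* ``metrics.json``    — compact-CNN confusion metrics
* ``history.csv``     — per-epoch training curves
* ``manifest.json``   — config hash, seed, package/library versions
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .io import write_cohort
from .stats import (
    compare_groups,
    fit_adjusted,
    fit_logistic,
    pearson_with_power,
)
from .synth import PRESETS, generate_cohort

log = logging.getLogger("korosound")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohorts
    group1_preset: str = "young"
    group2_preset: str = "older"
    n_per_group: int = 50
    hospital_n: int = 81
    # feature pipeline
    features: FeatureConfig = field(default_factory=FeatureConfig)
    # stats
    family_alpha: float = 0.05
    hl_groups: int = 10
    # classifier
    train_classifier: bool = True
    image_size: int = 48
    scalogram_band: tuple = (5.0, 100.0)
    n_scales: int = 64
    epochs: int = 15
    batch_size: int = 16
    learning_rate: float = 1e-3
    # output
    out_dir: str = "korosound_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scalogram_band"] = list(self.scalogram_band)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str) -> PipelineConfig:
    """Read a TOML config with [features] and top-level pipeline keys."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    feat = FeatureConfig(**raw.pop("features", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "scalogram_band" in raw:
        raw["scalogram_band"] = tuple(raw["scalogram_band"])
    return PipelineConfig(features=feat, **raw)


def _feature_table(recordings, subjects, config) -> pd.DataFrame:
    rows = []
    for rec, subj in zip(recordings, subjects):
        try:
            fv = extract_features(rec, config.features)
        except Exception as exc:
            log.warning("feature extraction failed for %s: %s", rec.subject_id, exc)
            continue
        row = fv.as_dict()
        row["subject_id"] = subj.subject_id
        row["group_label"] = subj.group_label
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report bundle as a dict.

    Any stage failure raises :class:`StageFailure` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    t_start = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    try:
        stage("simulate")
        recs1, subj1, _ = generate_cohort(config.group1_preset, config.n_per_group, seed=config.seed)
        recs2, subj2, _ = generate_cohort(
            config.group2_preset, config.n_per_group, seed=config.seed + 1
        )
        write_cohort(subj1 + subj2, out / "cohort.csv")
    except Exception as exc:
        raise StageFailure("simulate", exc) from exc

    try:
        stage("features")
        feat = _feature_table(recs1 + recs2, subj1 + subj2, config)
        if feat.empty:
            raise ValueError("no recordings yielded features")
        feat.to_csv(out / "features.csv", index=False)
    except Exception as exc:
        raise StageFailure("features", exc) from exc

    try:
        stage("stats-groups")
        comps = compare_groups(
            feat[FEATURE_NAMES], feat["group_label"].to_numpy(), family_alpha=config.family_alpha
        )
        report["group_comparison"] = [dataclasses.asdict(c) for c in comps]
        stage("stats-logistic")
        y = (feat["group_label"] == subj2[0].group_label).astype(int).to_numpy()
        try:
            logi = fit_logistic(feat[FEATURE_NAMES], y, hl_groups=config.hl_groups)
            report["logistic"] = {
                "predictors": [dataclasses.asdict(p) for p in logi.predictors],
                "intercept": logi.intercept,
                "hosmer_lemeshow": {
                    "chi2": logi.hosmer_lemeshow[0],
                    "p": logi.hosmer_lemeshow[1],
                    "n_groups": logi.hosmer_lemeshow[2],
                },
                "accuracy": logi.accuracy,
                "n": logi.n,
                "separable": False,
            }
        except ValueError as exc:
            # groups that separate perfectly on the features leave the ML
            # logistic undefined; fall back to a ridge-penalized fit and
            # report accuracy only (Wald/OR columns are meaningless here)
            log.warning("logistic fell back to ridge fit: %s", exc)
            from sklearn.linear_model import LogisticRegression

            Xs = feat[FEATURE_NAMES].to_numpy()
            Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0)
            clf = LogisticRegression(C=1.0, max_iter=1000).fit(Xs, y)
            report["logistic"] = {
                "predictors": [
                    {"name": n, "coef": float(c)}
                    for n, c in zip(FEATURE_NAMES, clf.coef_[0])
                ],
                "accuracy": float(clf.score(Xs, y)),
                "n": int(y.size),
                "separable": True,
                "note": "perfect separation; ridge-penalized coefficients, standardized features",
            }
    except Exception as exc:
        raise StageFailure("stats", exc) from exc

    try:
        stage("hospital")
        recs_h, subj_h, _ = generate_cohort("hospital", config.hospital_n, seed=config.seed + 2)
        feat_h = _feature_table(recs_h, subj_h, config)
        meta = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "age": s.age,
                    "bmi": s.bmi,
                    "sbp": s.sbp,
                    "diabetes": int(s.diabetes),
                    "bapwv": s.bapwv,
                }
                for s in subj_h
            ]
        )
        dfh = feat_h.merge(meta, on="subject_id")
        corrs, adjusted = [], []
        for name in FEATURE_NAMES:
            c = pearson_with_power(dfh[name], dfh["bapwv"], feature=name)
            corrs.append(dataclasses.asdict(c))
            if c.p < 0.05:
                a = fit_adjusted(dfh, outcome="bapwv", feature=name)
                adjusted.append(dataclasses.asdict(a))
        report["bapwv_correlation"] = corrs
        report["adjusted_models"] = adjusted
    except Exception as exc:
        raise StageFailure("hospital", exc) from exc

    if config.train_classifier:
        try:
            stage("classifier")
            from .classifier import TrainConfig, build_dataset, evaluate_classifier, train_compact_cnn

            labels = [0] * len(recs1) + [1] * len(recs2)
            ds = build_dataset(
                recs1 + recs2,
                labels,
                seed=config.seed,
                image_size=config.image_size,
                f_min=config.scalogram_band[0],
                f_max=config.scalogram_band[1],
                n_scales=config.n_scales,
            )
            model, history = train_compact_cnn(
                ds.subset("train"),
                ds.subset("val"),
                TrainConfig(
                    epochs=config.epochs,
                    batch_size=config.batch_size,
                    learning_rate=config.learning_rate,
                ),
                seed=config.seed,
            )
            metrics = evaluate_classifier(model, ds.subset("test"))
            history.to_csv(out / "history.csv", index=False)
            (out / "metrics.json").write_text(json.dumps(metrics.as_dict(), indent=2))
            report["classifier"] = metrics.as_dict()
        except Exception as exc:
            raise StageFailure("classifier", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "korosound": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete in %.1fs", time.time() - t_start)
    return report


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit reporting."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error
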