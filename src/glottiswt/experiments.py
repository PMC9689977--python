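"""Config-driven experiment harness.

Reproduces the study designs on synthetic cohorts: binary detection,
multiclass pathology categorization, the common-descriptor mode
(Mean-D2/D3/D4 only), cross-cohort transfer, and sweeps over the wavelet
decomposition level and the wavelet family.  Every experiment is a pure
function of ``(config, seed)``: cohorts, fold splits and classifier
initializations all derive from the config seed, so re-running a config
reproduces its report bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierSpec, cross_validate, evaluate_metrics, _fit_predict
from .errors import ConfigError
from .features import COMMON3, MinMaxScaler
from .iaif import IaifConfig
from .pipeline import cohort_feature_table
from .selection import rank_features
from .synth import binary_cohort_spec, make_cohort, multiclass_cohort_spec

MODES = ("detection", "multiclass", "cross_dataset", "sweep_levels", "sweep_wavelets")


@dataclass
class CohortConfig:
    """How to materialize one cohort: synthesized from a recipe name."""

    kind: str = "binary"  # "binary" | "multiclass"
    n_per_class: int = 30
    pathology: str = "polyp-like"
    duration_s: float = 2.0
    formant_scale_range: tuple = (0.9, 1.1)

    def spec(self):
        if self.kind == "binary":
            return binary_cohort_spec(
                n_per_class=self.n_per_class,
                pathology=self.pathology,
                duration_s=self.duration_s,
                formant_scale_range=tuple(self.formant_scale_range),
            )
        if self.kind == "multiclass":
            return multiclass_cohort_spec(n_per_class=self.n_per_class, duration_s=self.duration_s)
        raise ConfigError(f"unknown cohort kind: {self.kind!r}")


@dataclass
class ExperimentConfig:
    """Full experiment description; serializable to/from YAML."""

    mode: str = "detection"
    cohorts: list = field(default_factory=lambda: [CohortConfig()])
    feature_subset: str = "all"  # "all" | "top_k:N" | "common3"
    classifiers: list = field(default_factory=lambda: ["sgd", "svm_rbf"])
    cv_k: int = 10
    seed: int = 0
    wavelet: str = "haar"
    levels: int = 4
    iaif_method: str = "dap"
    ig_bins: int = 10

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode: {self.mode!r} (expected one of {MODES})")
        if self.mode == "cross_dataset" and len(self.cohorts) < 2:
            raise ConfigError("cross_dataset mode needs at least 2 cohorts")
        if self.feature_subset.startswith("top_k:"):
            k = int(self.feature_subset.split(":", 1)[1])
            if k > 7 * 2 * self.levels:
                raise ConfigError("top_k exceeds the feature-vector dimension")
        elif self.feature_subset not in ("all", "common3"):
            raise ConfigError(f"unknown feature subset: {self.feature_subset!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortConfig(**c) for c in raw.pop("cohorts", [{}])]
        return cls(cohorts=cohorts, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _subset_args(subset: str):
    """Map a feature-subset name to cross_validate keyword arguments."""
    if subset == "all":
        return {}
    if subset == "common3":
        return {"feature_subset": list(COMMON3)}
    if subset.startswith("top_k:"):
        return {"rank_top_k": int(subset.split(":", 1)[1])}
    raise ConfigError(f"unknown feature subset: {subset!r}")


def _classifier_spec(name: str) -> ClassifierSpec:
    return ClassifierSpec(name=name)


def _feature_cols(table: pd.DataFrame):
    return [c for c in table.columns if c not in ("id", "label")]


def _cohort_table(cfg: ExperimentConfig, cohort: CohortConfig, seed: int, levels=None, wavelet=None):
    recs, _ = make_cohort(cohort.spec(), seed=seed)
    return cohort_feature_table(
        recs,
        wavelet=wavelet or cfg.wavelet,
        levels=levels or cfg.levels,
        iaif_cfg=IaifConfig(method=cfg.iaif_method),
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment; returns a JSON-serializable report.

    The report carries per-classifier (and per-condition) metric blocks,
    the information-gain ranking of the first cohort, and provenance
    (config hash, seed, wavelet, level, IAIF settings).
    """
    seed = config.seed
    report = {
        "mode": config.mode,
        "seed": seed,
        "config_hash": config.config_hash(),
        "provenance": {
            "wavelet": config.wavelet,
            "levels": config.levels,
            "iaif_method": config.iaif_method,
            "cv_k": config.cv_k,
            "ig_bins": config.ig_bins,
        },
        "results": {},
    }

    if config.mode in ("detection", "multiclass"):
        table = _cohort_table(config, config.cohorts[0], seed)
        cols = _feature_cols(table)
        labels = table["label"].to_numpy()
        ranking = rank_features(table[cols], labels, bins=config.ig_bins)
        report["ranking"] = ranking.as_frame().to_dict(orient="records")
        subsets = (
            ["all", "top_k:3"] if config.mode == "detection" else ["all", "top_k:5", "top_k:3"]
        )
        if config.feature_subset != "all":
            subsets = [config.feature_subset]
        for clf_name in config.classifiers:
            for subset in subsets:
                rep = cross_validate(
                    table[cols],
                    labels,
                    _classifier_spec(clf_name),
                    k=config.cv_k,
                    seed=seed,
                    ig_bins=config.ig_bins,
                    **_subset_args(subset),
                )
                report["results"][f"{clf_name}|{subset}"] = rep.as_dict()

    elif config.mode == "cross_dataset":
        tables = [
            _cohort_table(config, c, seed + 1000 * i) for i, c in enumerate(config.cohorts)
        ]
        cols = list(COMMON3) if config.feature_subset == "common3" else _feature_cols(tables[0])
        for clf_name in config.classifiers:
            matrix = {}
            for i, train_tab in enumerate(tables):
                for j, test_tab in enumerate(tables):
                    if i == j:
                        continue
                    scaler = MinMaxScaler().fit(train_tab[cols])
                    Xtr = scaler.transform(train_tab[cols]).to_numpy()
                    Xte = scaler.transform(test_tab[cols]).to_numpy()
                    ytr = train_tab["label"].to_numpy()
                    yte = test_tab["label"].to_numpy()
                    pred, scores = _fit_predict(_classifier_spec(clf_name), Xtr, ytr, Xte, seed)
                    rep = evaluate_metrics(yte, pred, scores)
                    matrix[f"train{i}->test{j}"] = rep.as_dict()
            report["results"][clf_name] = matrix

    elif config.mode == "sweep_levels":
        for levels in range(1, 6):
            table = _cohort_table(config, config.cohorts[0], seed, levels=levels)
            cols = _feature_cols(table)
            labels = table["label"].to_numpy()
            for clf_name in config.classifiers:
                rep = cross_validate(
                    table[cols], labels, _classifier_spec(clf_name), k=config.cv_k, seed=seed
                )
                report["results"][f"{clf_name}|J={levels}"] = rep.as_dict()

    elif config.mode == "sweep_wavelets":
        for wavelet in ("haar",) + tuple(f"db{k}" for k in range(2, 13)):
            table = _cohort_table(config, config.cohorts[0], seed, wavelet=wavelet)
            cols = _feature_cols(table)
            labels = table["label"].to_numpy()
            for clf_name in config.classifiers:
                rep = cross_validate(
                    table[cols], labels, _classifier_spec(clf_name), k=config.cv_k, seed=seed
                )
                report["results"][f"{clf_name}|{wavelet}"] = rep.as_dict()

    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a report's metric blocks into a table (one row per condition)."""
    rows = []
    for key, block in report["results"].items():
        if "auc" in block:
            rows.append({"condition": key, **{m: block[m] for m in ("auc", "ca_pct", "f1", "ppv_pct", "recall_pct")}})
        else:  # cross-dataset nested matrix
            for pair, rep in block.items():
                rows.append(
                    {"condition": f"{key}|{pair}", **{m: rep[m] for m in ("auc", "ca_pct", "f1", "ppv_pct", "recall_pct")}}
                )
    return pd.DataFrame(rows)
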