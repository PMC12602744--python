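"""Declarative end-to-end pipeline: extract -> preprocess -> split ->
train -> evaluate -> explain, under a single seed.

One :class:`PipelineConfig` drives the whole run; re-running with an
identical config reproduces identical outputs byte for byte.  Every
stage is logged with its timing, and per-record extractor failures are
warnings, not errors (the missing-value policy).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .classify import (
    ClassifierSpec,
    ConfusionMatrix,
    compute_metrics,
    cross_validate,
    feature_matrix,
    fit_classifier,
    roc_auc_cv,
)
from .dataset import preprocess, stratified_split, consolidate, write_feature_csv
from .errors import ParameterError
from .explain import (
    MarginalValueFunction,
    shapley_sampled,
    summarize_global,
)
from .features import ExtractionConfig

logger = logging.getLogger("vocalmarkers")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    root: str = ""
    output_dir: str = "vocalmarkers_out"
    f0_min: float = 60.0
    f0_max: float = 500.0
    classical_definitions: bool = False
    fit_on_all: bool = False  # compatibility: standardize before splitting
    test_fraction: float = 0.30
    cv_folds: int = 10
    roc_folds: int = 3
    classifier: str = "svm"
    explain_mode: str = "sampled"
    n_background: int = 100
    n_explain: int = 5
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ParameterError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2 or self.roc_folds < 2:
            raise ParameterError("fold counts must be >= 2")
        if self.explain_mode not in ("exact", "sampled"):
            raise ParameterError("explain_mode must be 'exact' or 'sampled'")
        if not 0 < self.f0_min < self.f0_max:
            raise ParameterError("need 0 < f0_min < f0_max")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            f0_min=self.f0_min,
            f0_max=self.f0_max,
            classical_definitions=self.classical_definitions,
        )


def _stage(name: str):
    logger.info("stage %s: starting", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write features, report and explanations.

    Returns the report dictionary that is also written to
    ``<output_dir>/report.json``.
    """
    root = Path(config.root)
    if not config.root or not root.is_dir():
        raise ParameterError(f"dataset root {config.root!r} is not a directory")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("extract")
    table = consolidate(root, config=config.extraction())
    write_feature_csv(table, out_dir / "features.csv")
    _done("extract", t0)

    t0 = _stage("split+preprocess")
    train_raw, test_raw = stratified_split(table, config.test_fraction, config.seed)
    if config.fit_on_all:
        fit_mask = np.ones(len(table), dtype=bool)
    else:
        fit_mask = table.index.isin(train_raw.index)
    processed, params = preprocess(table, fit_rows=fit_mask)
    train = processed.loc[train_raw.index]
    test = processed.loc[test_raw.index]
    _done("split+preprocess", t0)

    t0 = _stage("train+evaluate")
    spec = ClassifierSpec(family=config.classifier)
    model = fit_classifier(spec, train, seed=config.seed)
    X_test, y_test, _ = feature_matrix(test)
    cm = ConfusionMatrix.from_predictions(
        y_test, model.predict(X_test), labels=tuple(model.classes)
    )
    holdout = compute_metrics(cm)
    pooled, _folds, cv_cm = cross_validate(
        spec, processed, k=min(config.cv_folds, _max_folds(processed)),
        seed=config.seed,
    )
    roc = roc_auc_cv(
        spec, processed, k=min(config.roc_folds, _max_folds(processed)),
        seed=config.seed,
    )
    _done("train+evaluate", t0)

    t0 = _stage("explain")
    X_train, _, names = feature_matrix(train)
    rng = np.random.default_rng(config.seed)
    m = min(config.n_background, X_train.shape[0])
    background = X_train[rng.choice(X_train.shape[0], size=m, replace=False)]
    vf = MarginalValueFunction(model.predict_margin, background)
    n_explain = min(config.n_explain, X_test.shape[0])
    explanations = [
        shapley_sampled(
            vf, X_test[i], feature_names=names,
            n_permutations=config.n_permutations, seed=config.seed + i,
        )
        for i in range(n_explain)
    ]
    summary = summarize_global(explanations) if explanations else None
    expl_payload = {
        "mode": "sampled",
        "baseline": explanations[0].baseline if explanations else None,
        "records": [
            {"fx": e.fx, "phi": e.phi, "seed": config.seed + i}
            for i, e in enumerate(explanations)
        ],
        "ranking": summary.ranking if summary else [],
    }
    (out_dir / "explanations.json").write_text(json.dumps(expl_payload, indent=2))
    _done("explain", t0)

    report = {
        "config": asdict(config),
        "n_records": int(len(table)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "holdout": {
            "confusion_matrix": cm.matrix.tolist(),
            "labels": [int(c) for c in cm.labels],
            "metrics": holdout.rounded(4),
        },
        "cross_validation": {
            "folds": int(min(config.cv_folds, _max_folds(processed))),
            "pooled_metrics": pooled.rounded(4),
            "confusion_matrix": cv_cm.matrix.tolist(),
        },
        "roc": {"mean_auc": roc["mean_auc"], "sd_auc": roc["sd_auc"]},
        "explain": {"ranking": expl_payload["ranking"][:10]},
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _max_folds(table) -> int:
    counts = table["class_label"].value_counts()
    return max(2, int(counts.min()))
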