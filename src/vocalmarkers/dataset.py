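"""Dataset assembly: folder consolidation, standardization, imputation,
augmentation and stratified splitting.

``consolidate`` walks a ``<root>/<subject>/<content>_<k>.wav`` tree, builds
each subject's formant inventory from their vowel recordings, extracts
the 28-feature vector for every recording, and emits one CSV row per
recording.  ``preprocess`` mean-imputes missing cells and z-scores each
feature, fitting the imputation/scaling parameters on a designated row
subset (normally the training split) and applying them to all rows.
``augment_minority`` balances classes at the waveform level by
speed-perturbing minority-class recordings with factors in a narrow band
around 1, and ``stratified_split`` produces a record-level train/test
partition with per-class proportions preserved to within one record.
"""

from __future__ import annotations

import json
import logging
import math
import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateColumnError,
    EmptyDatasetError,
    ParameterError,
    StratificationError,
    UnsupportedFormatError,
)
from .features import (
    ExtractionConfig,
    FEATURE_NAMES,
    build_formant_inventory,
    extract_record_features,
)
from .signal_io import Waveform, discover_recordings, read_wav

logger = logging.getLogger("vocalmarkers")

META_COLUMNS = ("record_id", "subject_id", "content", "class_label", "augmented")


@dataclass
class StandardizationParams:
    """Per-column imputation means and z-scoring (mean, sd) pairs."""

    impute_means: pd.Series
    means: pd.Series
    sds: pd.Series


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        try:
            return json.loads(sidecar.read_text())
        except json.JSONDecodeError:
            return {}
    return {}


def consolidate(
    root: str | os.PathLike,
    out_csv: str | os.PathLike | None = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Extract one 28-feature row per recording under ``root``.

    Corrupt files are logged and skipped; an empty root is an error.
    Deterministic: the walk is sorted and extraction is seed-free.
    """
    paths = discover_recordings(root)
    if not paths:
        raise EmptyDatasetError(f"no WAV recordings under {root}")

    by_subject: dict[str, list[tuple[Path, Waveform, dict]]] = {}
    for path in paths:
        try:
            wave = read_wav(path)
        except (UnsupportedFormatError, FileNotFoundError) as exc:
            logger.warning("skipping unreadable recording %s: %s", path, exc)
            continue
        meta = _read_sidecar(path)
        if meta.get("class_label") is not None:
            wave = wave.replace(class_label=int(meta["class_label"]))
        by_subject.setdefault(wave.subject_id or path.parent.name, []).append(
            (path, wave, meta)
        )
    if not by_subject:
        raise EmptyDatasetError(f"no readable WAV recordings under {root}")

    rows = []
    for subject in sorted(by_subject):
        entries = by_subject[subject]
        inventory = build_formant_inventory([w for _, w, _ in entries], config)
        for path, wave, _meta in entries:
            feats = extract_record_features(wave, inventory, config)
            row = {
                "record_id": f"{subject}/{path.stem}",
                "subject_id": subject,
                "content": wave.content or "unknown",
                "class_label": wave.class_label if wave.class_label is not None else -1,
                "augmented": wave.augmented,
            }
            row.update(feats)
            rows.append(row)
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))
    if out_csv is not None:
        write_feature_csv(table, out_csv)
    return table


def write_feature_csv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Comma-separated, UTF-8, header row, empty cells for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.10g", na_rep="", encoding="utf-8")


def read_feature_csv(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ParameterError(f"feature CSV lacks columns: {missing}")
    return table


def preprocess(
    table: pd.DataFrame,
    fit_rows: np.ndarray | None = None,
    params: StandardizationParams | None = None,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Impute missing feature cells, then z-score every feature column.

    Imputation means and scaling parameters are estimated on ``fit_rows``
    only (a boolean mask; default all rows) and applied to all rows —
    fitting on the training split keeps the test split untouched by
    leakage.  Passing ``params`` reapplies previously fitted parameters.
    A column with no usable fitting value is an error; a zero-variance
    column is scaled with sd 1 under a warning.
    """
    out = table.copy()
    cols = [c for c in FEATURE_NAMES if c in out.columns]
    if not cols:
        raise ParameterError("table has no feature columns")

    if params is None:
        if fit_rows is None:
            fit_rows = np.ones(len(out), dtype=bool)
        fit_rows = np.asarray(fit_rows, dtype=bool)
        if fit_rows.sum() == 0:
            raise ParameterError("fit_rows selects no rows")
        fit = out.loc[fit_rows, cols]
        impute_means = fit.mean(axis=0, skipna=True)
        bad = impute_means.index[impute_means.isna()]
        if len(bad):
            raise DegenerateColumnError(
                f"column(s) with no non-missing fitting value: {list(bad)}"
            )
        imputed_fit = fit.fillna(impute_means)
        means = imputed_fit.mean(axis=0)
        sds = imputed_fit.std(axis=0, ddof=0)
        zero_var = sds.index[sds <= 1e-12]
        if len(zero_var):
            warnings.warn(
                f"zero-variance column(s) {list(zero_var)}: sd replaced by 1",
                stacklevel=2,
            )
            sds = sds.mask(sds <= 1e-12, 1.0)
        params = StandardizationParams(impute_means=impute_means, means=means, sds=sds)

    out[cols] = (out[cols].fillna(params.impute_means) - params.means) / params.sds
    return out, params


def _stretch(samples: np.ndarray, factor: float) -> np.ndarray:
    """Resample to ``len/factor`` samples: factor > 1 plays faster (shorter)."""
    n_out = max(2, int(round(samples.size / factor)))
    grid = np.linspace(0.0, samples.size - 1.0, n_out)
    return np.interp(grid, np.arange(samples.size), samples)


def augment_minority(
    records: list[Waveform],
    factor_range: tuple[float, float] = (0.99, 1.01),
    seed: int = 0,
) -> list[Waveform]:
    """Balance classes by duplicating minority recordings with a slight
    speed perturbation drawn uniformly from ``factor_range``.

    Returns the original recordings plus the augmented copies (flagged
    ``augmented=True``); deterministic per seed.
    """
    lo, hi = factor_range
    if not (0.9 < lo <= hi < 1.1):
        raise ParameterError("factor_range must lie strictly inside (0.9, 1.1)")
    labels = [w.class_label for w in records]
    if any(lbl is None for lbl in labels):
        raise ParameterError("all records need class labels for augmentation")
    counts: dict[int, int] = {}
    for lbl in labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    target = max(counts.values())
    rng = np.random.default_rng(seed)

    augmented: list[Waveform] = []
    for label in sorted(counts):
        deficit = target - counts[label]
        if deficit == 0:
            continue
        pool = [w for w in records if w.class_label == label]
        for j in range(deficit):
            source = pool[j % len(pool)]
            factor = float(rng.uniform(lo, hi))
            stretched = _stretch(source.samples, factor)
            augmented.append(
                source.replace(samples=stretched, augmented=True, ground_truth=None)
            )
    return list(records) + augmented


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    table: pd.DataFrame,
    test_fraction: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Record-level stratified train/test split.

    Test size is ``round(test_fraction * N)`` (half-up); per-class test
    counts follow the largest-remainder rule, so each class's proportion
    in the test set is within one record of its global proportion.
    Augmented records are never placed in the test set.
    """
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must lie in (0, 1)")
    n = len(table)
    class_counts = table["class_label"].value_counts()
    if (class_counts < 2).any():
        small = class_counts.index[class_counts < 2].tolist()
        raise StratificationError(f"class(es) {small} have fewer than 2 records")

    test_size = _round_half_up(test_fraction * n)
    quotas = {c: test_fraction * cnt for c, cnt in class_counts.items()}
    base = {c: math.floor(q) for c, q in quotas.items()}
    remainder = test_size - sum(base.values())
    order = sorted(quotas, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in order[:remainder]:
        base[c] += 1

    rng = np.random.default_rng(seed)
    if "augmented" in table.columns:
        aug_mask = table["augmented"].astype(bool)
    else:
        aug_mask = pd.Series(False, index=table.index)
    test_idx: list = []
    for c, k in base.items():
        eligible = table.index[
            (table["class_label"] == c) & ~aug_mask
        ].to_numpy()
        if k > eligible.size:
            raise StratificationError(
                f"class {c}: need {k} test records but only {eligible.size} "
                "non-augmented rows are available"
            )
        test_idx.extend(rng.choice(eligible, size=k, replace=False).tolist())
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()
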