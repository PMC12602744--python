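"""Shapley-value attribution for per-record predictions.

The Shapley value of feature ``i`` is the weighted average, over all
subsets ``S`` of the remaining features, of the change in the model's
output when ``i`` joins ``S``:

    phi_i = sum_{S subseteq F\\{i}} |S|! (|F|-|S|-1)! / |F|!
            * [ f_{S u {i}}(x_{S u {i}}) - f_S(x_S) ]

Two value-function realizations are provided: retraining the model on
each feature subset (the literal definition; tractable for <= ~10
features) and marginal-expectation masking over a background sample
(replace out-of-coalition features with background values and average),
the practical default for the 28-feature space.  Exact enumeration is
used up to 12 features; beyond that, permutation sampling estimates the
same quantity with per-feature standard errors.

Explanations are computed on the model's margin (pre-threshold score),
so a record's output can lie outside [0, 1]; a record whose output falls
below the baseline is oriented toward the healthy class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

MAX_EXACT_FEATURES = 12


class MarginalValueFunction:
    """f_S(x) = E_b[ model(x_S, b_{F\\S}) ] over a background sample.

    ``predict`` maps a 2-D array to a 1-D score vector; ``background`` is
    a (m, n_features) array (typically the training split or a seeded
    subsample of it).  f_empty equals the mean background prediction — the
    baseline.
    """

    def __init__(self, predict, background: np.ndarray):
        self.predict = predict
        self.background = np.asarray(background, dtype=float)
        if self.background.ndim != 2 or self.background.shape[0] < 1:
            raise ParameterError("background must be a non-empty 2-D array")
        self.n_features = self.background.shape[1]

    def __call__(self, subset: tuple[int, ...], x: np.ndarray) -> float:
        z = self.background.copy()
        if subset:
            idx = list(subset)
            z[:, idx] = np.asarray(x, dtype=float)[idx]
        return float(np.mean(self.predict(z)))


class RetrainValueFunction:
    """f_S(x) obtained by retraining the model on the features in S.

    ``model_factory()`` returns a fresh unfitted estimator with ``fit`` and
    ``predict`` methods.  f_empty is the mean training target — the
    baseline prediction of a featureless model.  Subset models are cached,
    so a full enumeration trains each of the 2^|F| models once.
    """

    def __init__(self, model_factory, X_train: np.ndarray, y_train: np.ndarray):
        self.model_factory = model_factory
        self.X = np.asarray(X_train, dtype=float)
        self.y = np.asarray(y_train, dtype=float)
        self.n_features = self.X.shape[1]
        self._cache: dict[tuple[int, ...], object] = {}

    def __call__(self, subset: tuple[int, ...], x: np.ndarray) -> float:
        subset = tuple(sorted(subset))
        if not subset:
            return float(np.mean(self.y))
        model = self._cache.get(subset)
        if model is None:
            model = self.model_factory()
            model.fit(self.X[:, list(subset)], self.y)
            self._cache[subset] = model
        xs = np.asarray(x, dtype=float)[list(subset)].reshape(1, -1)
        return float(np.asarray(model.predict(xs)).ravel()[0])


@dataclass
class ShapleyExplanation:
    """Per-feature attributions for one record."""

    baseline: float
    phi: dict[str, float]
    fx: float
    feature_names: tuple[str, ...]
    std_errors: dict[str, float] | None = field(default=None)
    mode: str = "exact"

    def efficiency_gap(self) -> float:
        return abs(sum(self.phi.values()) - (self.fx - self.baseline))


def _resolve_names(n: int, feature_names) -> tuple[str, ...]:
    if feature_names is None:
        return tuple(f"x{i}" for i in range(n))
    names = tuple(feature_names)
    if len(names) != n:
        raise ParameterError("feature_names length does not match value function")
    return names


def shapley_exact(
    vf,
    instance: np.ndarray,
    feature_names=None,
) -> ShapleyExplanation:
    """Exact Shapley values by full subset enumeration (<= 12 features)."""
    n = vf.n_features
    if n > MAX_EXACT_FEATURES:
        raise ParameterError(
            f"{n} features need 2^{n} evaluations; use shapley_sampled instead"
        )
    names = _resolve_names(n, feature_names)
    x = np.asarray(instance, dtype=float)

    values = {}
    for mask in range(1 << n):
        subset = tuple(i for i in range(n) if mask & (1 << i))
        values[mask] = vf(subset, x)

    fact = [math.factorial(k) for k in range(n + 1)]
    phi = np.zeros(n)
    for mask in range(1 << n):
        s = bin(mask).count("1")
        weight = fact[s] * fact[n - s - 1] / fact[n]
        for i in range(n):
            if mask & (1 << i):
                continue
            phi[i] += weight * (values[mask | (1 << i)] - values[mask])

    return ShapleyExplanation(
        baseline=values[0],
        phi={name: float(p) for name, p in zip(names, phi)},
        fx=values[(1 << n) - 1],
        feature_names=names,
        mode="exact",
    )


def shapley_sampled(
    vf,
    instance: np.ndarray,
    feature_names=None,
    n_permutations: int = 200,
    seed: int = 0,
) -> ShapleyExplanation:
    """Permutation-sampling Shapley estimate with per-feature standard errors.

    Each random feature ordering contributes one marginal-contribution
    sample per feature; the estimator is unbiased for the exact value and
    deterministic for a fixed seed.
    """
    if n_permutations < 10:
        raise ParameterError("n_permutations must be >= 10")
    n = vf.n_features
    names = _resolve_names(n, feature_names)
    x = np.asarray(instance, dtype=float)
    rng = np.random.default_rng(seed)

    samples = np.zeros((n_permutations, n))
    baseline = vf((), x)
    fx = vf(tuple(range(n)), x)
    for p in range(n_permutations):
        order = rng.permutation(n)
        prev_value = baseline
        members: list[int] = []
        for i in order:
            members.append(int(i))
            value = vf(tuple(members), x)
            samples[p, i] = value - prev_value
            prev_value = value

    phi = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / math.sqrt(n_permutations)
    return ShapleyExplanation(
        baseline=baseline,
        phi={name: float(v) for name, v in zip(names, phi)},
        fx=fx,
        feature_names=names,
        std_errors={name: float(s) for name, s in zip(names, se)},
        mode="sampled",
    )


@dataclass
class GlobalSummary:
    """Features ranked by mean |phi|, with signed per-record distributions."""

    ranking: list[str]
    mean_abs: dict[str, float]
    values: dict[str, np.ndarray]


def summarize_global(explanations: list[ShapleyExplanation]) -> GlobalSummary:
    """Rank features by mean absolute attribution across explanations."""
    if not explanations:
        raise ParameterError("need at least one explanation")
    universe = explanations[0].feature_names
    for expl in explanations[1:]:
        if expl.feature_names != universe:
            raise ParameterError("explanations have inconsistent feature universes")
    values = {
        name: np.array([expl.phi[name] for expl in explanations]) for name in universe
    }
    mean_abs = {name: float(np.mean(np.abs(v))) for name, v in values.items()}
    ranking = sorted(universe, key=lambda name: mean_abs[name], reverse=True)
    return GlobalSummary(ranking=ranking, mean_abs=mean_abs, values=values)


def force_record(
    expl: ShapleyExplanation,
    threshold: float | None = None,
) -> dict:
    """Local force-style report for one record.

    Orientation is ``healthy`` when the model output lies strictly below
    the threshold (default: the baseline) and ``pathological`` otherwise
    (ties break toward pathological, the cautious direction for a
    screening tool).  Contributors are listed by decreasing |phi|.
    """
    if threshold is None:
        threshold = expl.baseline
    orientation = "healthy" if expl.fx < threshold else "pathological"
    contributors = [
        {"feature": name, "phi": expl.phi[name]}
        for name in sorted(expl.phi, key=lambda k: abs(expl.phi[k]), reverse=True)
        if expl.phi[name] != 0.0
    ]
    return {
        "orientation": orientation,
        "baseline": expl.baseline,
        "fx": expl.fx,
        "top_contributors": contributors,
    }
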