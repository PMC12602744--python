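"""Shapley axioms in enumeration mode, sampling convergence, summaries."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from vocalmarkers.errors import ParameterError
from vocalmarkers.explain import (
    MarginalValueFunction,
    RetrainValueFunction,
    ShapleyExplanation,
    force_record,
    shapley_exact,
    shapley_sampled,
    summarize_global,
)


def _linear_vf(weights, background):
    w = np.asarray(weights, float)
    return MarginalValueFunction(lambda X: X @ w, np.asarray(background, float))


class TestExactAxioms:
    def test_additive_model_splits_by_coordinate(self):
        vf = _linear_vf([1.0, 1.0], np.zeros((40, 2)))
        expl = shapley_exact(vf, np.array([3.0, -1.0]))
        assert expl.phi == {"x0": pytest.approx(3.0), "x1": pytest.approx(-1.0)}
        assert expl.baseline == pytest.approx(0.0)

    def test_dummy_feature_gets_zero(self):
        rng = np.random.default_rng(0)
        vf = _linear_vf([2.0, 0.0, -1.5], rng.normal(size=(30, 3)))
        expl = shapley_exact(vf, rng.normal(size=3))
        assert expl.phi["x1"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_features_get_equal_credit(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(30, 3))
        bg[:, 1] = bg[:, 0]  # identical background marginals
        vf = MarginalValueFunction(lambda X: X[:, 0] + X[:, 1] + 0.3 * X[:, 2], bg)
        x = np.array([1.7, 1.7, -0.2])
        expl = shapley_exact(vf, x)
        assert expl.phi["x0"] == pytest.approx(expl.phi["x1"], abs=1e-12)

    def test_axioms_hold_on_fifty_random_linear_models(self):
        """For linear models with a marginal value function the Shapley
        value has a closed form phi_i = w_i (x_i - mean background_i);
        efficiency, dummy and symmetry all follow and are checked exactly."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            w = rng.normal(size=n)
            w[rng.integers(0, n)] = 0.0  # ensure one dummy feature
            bg = rng.normal(size=(25, n))
            x = rng.normal(size=n)
            expl = shapley_exact(_linear_vf(w, bg), x)
            assert expl.efficiency_gap() < 1e-6
            closed_form = w * (x - bg.mean(axis=0))
            for i in range(n):
                assert expl.phi[f"x{i}"] == pytest.approx(closed_form[i], abs=1e-9)

    def test_linearity_of_attributions(self):
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(20, 4))
        x = rng.normal(size=4)
        g = MarginalValueFunction(lambda X: X[:, 0] * X[:, 1], bg)
        h = MarginalValueFunction(lambda X: X[:, 2] - 2 * X[:, 3], bg)
        gh = MarginalValueFunction(
            lambda X: X[:, 0] * X[:, 1] + X[:, 2] - 2 * X[:, 3], bg
        )
        pg, ph, pgh = (shapley_exact(v, x).phi for v in (g, h, gh))
        for k in pgh:
            assert pgh[k] == pytest.approx(pg[k] + ph[k], abs=1e-10)

    def test_too_many_features_directed_to_sampling(self):
        vf = _linear_vf(np.ones(13), np.zeros((5, 13)))
        with pytest.raises(ParameterError, match="sampled"):
            shapley_exact(vf, np.ones(13))


class TestRetrainValueFunction:
    def test_empty_subset_is_mean_training_target(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 3.0
        vf = RetrainValueFunction(LinearRegression, X, y)
        assert vf((), X[0]) == pytest.approx(float(np.mean(y)))

    def test_enumeration_satisfies_efficiency(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        y = X @ np.array([2.0, 1.0, -1.0, 0.5])
        vf = RetrainValueFunction(LinearRegression, X, y)
        x = rng.normal(size=4)
        expl = shapley_exact(vf, x)
        assert expl.efficiency_gap() < 1e-6


class TestSampled:
    def test_agrees_with_enumeration_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        bg = rng.normal(size=(25, 8))
        w = rng.normal(size=8)
        vf = MarginalValueFunction(lambda X: X @ w + 0.5 * X[:, 0] * X[:, 1], bg)
        x = rng.normal(size=8)
        exact = shapley_exact(vf, x)
        sampled = shapley_sampled(vf, x, n_permutations=2000, seed=2)
        for name in exact.phi:
            se = max(sampled.std_errors[name], 1e-9)
            assert abs(sampled.phi[name] - exact.phi[name]) <= 3 * se

    def test_error_shrinks_with_more_permutations(self):
        rng = np.random.default_rng(13)
        bg = rng.normal(size=(20, 6))
        vf = MarginalValueFunction(
            lambda X: X[:, 0] * X[:, 1] + X[:, 2] ** 2 - X[:, 3], bg
        )
        x = rng.normal(size=6)
        exact = shapley_exact(vf, x)

        def err(n):
            # seed-averaged so the expected 1/sqrt(n) scaling dominates
            per_seed = []
            for seed in range(5):
                est = shapley_sampled(vf, x, n_permutations=n, seed=seed)
                per_seed.append(
                    np.mean([abs(est.phi[k] - exact.phi[k]) for k in exact.phi])
                )
            return float(np.mean(per_seed))

        e100, e1000, e10000 = err(100), err(1000), err(10000)
        assert e10000 < e1000 < e100

    def test_deterministic_per_seed(self):
        vf = _linear_vf([1.0, -1.0, 0.5], np.random.default_rng(0).normal(size=(15, 3)))
        x = np.array([0.5, 0.2, -0.7])
        a = shapley_sampled(vf, x, n_permutations=100, seed=9)
        b = shapley_sampled(vf, x, n_permutations=100, seed=9)
        assert a.phi == b.phi

    def test_single_permutation_rejected(self):
        vf = _linear_vf([1.0, 1.0], np.zeros((5, 2)))
        with pytest.raises(ParameterError):
            shapley_sampled(vf, np.ones(2), n_permutations=1)


class TestSummariesAndForce:
    def _expl(self, phi, baseline=0.0, fx=None):
        names = tuple(sorted(phi))
        if fx is None:
            fx = baseline + sum(phi.values())
        return ShapleyExplanation(
            baseline=baseline, phi=phi, fx=fx, feature_names=names
        )

    def test_dominant_feature_ranked_first(self):
        expls = [
            self._expl({"A": (-1.0) ** i, "B": 0.0, "C": 0.1})
            for i in range(10)
        ]
        assert summarize_global(expls).ranking[0] == "A"

    def test_single_explanation_ranking_is_abs_sort(self):
        summary = summarize_global([self._expl({"A": 0.1, "B": -2.0, "C": 0.5})])
        assert summary.ranking == ["B", "C", "A"]

    def test_designated_signal_features_occupy_top_ranks(self):
        rng = np.random.default_rng(21)
        bg = rng.normal(size=(30, 6))
        w = np.array([5.0, 4.0, 0.2, 0.1, 0.05, 0.02])
        vf = MarginalValueFunction(lambda X: X @ w, bg)
        expls = [
            shapley_exact(vf, rng.normal(size=6)) for _ in range(15)
        ]
        assert set(summarize_global(expls).ranking[:2]) == {"x0", "x1"}

    def test_inconsistent_universes_rejected(self):
        with pytest.raises(ParameterError):
            summarize_global([self._expl({"A": 1.0}), self._expl({"B": 1.0})])

    def test_force_orientation_and_tie_rule(self):
        low = self._expl({"A": -2.0}, baseline=1.0)
        assert force_record(low)["orientation"] == "healthy"
        tie = self._expl({"A": 0.0}, baseline=1.0, fx=1.0)
        assert force_record(tie)["orientation"] == "pathological"

    def test_all_zero_attributions_give_empty_contributors(self):
        expl = self._expl({"A": 0.0, "B": 0.0}, baseline=0.5)
        report = force_record(expl)
        assert report["top_contributors"] == []
        assert report["fx"] == expl.baseline
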