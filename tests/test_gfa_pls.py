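import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from qsar4d.gfa_pls import (
    GfaConfig,
    GfaPlsRegressor,
    InfeasibleModelError,
    evolve,
    fit_pls,
    lof,
    size_sweep,
)
from qsar4d.validation import adjusted, loo_q2


class TestLof:
    def test_zero_error_gives_zero_lof(self):
        assert lof(0.0, 5, 41, 1.0) == 0.0

    def test_nine_term_model_arithmetic(self):
        # (4.1/41) / (1 - 19/41)^2, with c = 10 parameters and p = 9 terms
        assert lof(4.1, 9, 41, 1.0) == pytest.approx(0.3473, abs=5e-5)

    def test_penalty_grows_with_terms(self):
        values = [lof(4.1, p, 41, 1.0) for p in range(1, 10)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_infeasible_size_rejected(self):
        with pytest.raises(InfeasibleModelError):
            lof(1.0, 20, 41, 1.0)  # c + d p = 41 = M

    def test_small_models_approach_pure_mse_scaling(self):
        # as p -> 0 the penalty tends to (1 - c/M)^-2
        got = lof(2.0, 1, 1000, 1.0)
        assert got == pytest.approx((2.0 / 1000) / (1 - 3 / 1000) ** 2, rel=1e-12)


class TestFitPls:
    def test_full_components_match_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + 0.3 * rng.normal(size=30) + 2.0
        intercept, coef, lse = fit_pls(X, y, n_components=5)
        A = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(coef, beta[1:], atol=1e-8)
        assert lse == pytest.approx(np.sum((A @ beta - y) ** 2), abs=1e-8)

    def test_univariate_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = 3.0 * x + rng.normal(size=25)
        intercept, coef, _ = fit_pls(x[:, None], y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert coef[0] == pytest.approx(slope, abs=1e-10)
        assert intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_constant_activity_yields_flat_model(self):
        X = np.random.default_rng(2).normal(size=(10, 3))
        intercept, coef, lse = fit_pls(X, np.full(10, 7.5))
        assert intercept == 7.5
        assert np.all(coef == 0.0)
        assert lse == 0.0

    def test_zero_column_gets_zero_loading(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        X[:, 1] = 0.0
        y = X[:, 0] - 2 * X[:, 2]
        _, coef, lse = fit_pls(X, y)
        assert np.isfinite(coef).all()
        assert lse == pytest.approx(0.0, abs=1e-12)

    def test_adding_descriptors_never_raises_training_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        lses = [fit_pls(X[:, : k + 1], y)[2] for k in range(6)]
        assert all(b <= a + 1e-9 for a, b in zip(lses, lses[1:]))


def _planted_pool(rng, n=30, m=12, k=3, noise=0.05):
    X = rng.uniform(0, 1, size=(n, m))
    true_idx = (1, 5, 9)
    beta = np.array([4.0, -3.0, 5.0])
    y = 7.0 + X[:, true_idx] @ beta + rng.normal(0, noise, n)
    return X, y, true_idx


class TestEvolve:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        X, y, _ = _planted_pool(rng)
        cfg = GfaConfig(population_size=20, n_crossovers=300, max_terms=3, seed=9)
        a = evolve(X, y, cfg)
        b = evolve(X, y, cfg)
        assert [c.descriptor_idx for c in a] == [c.descriptor_idx for c in b]
        assert [c.lof for c in a] == [c.lof for c in b]

    def test_single_descriptor_pool(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 1))
        y = 2.0 * x[:, 0] + 1.0
        ranked = evolve(x, y, GfaConfig(population_size=5, n_crossovers=5, max_terms=1))
        assert len(ranked) == 1
        assert ranked[0].coefficients[0] == pytest.approx(2.0, abs=1e-8)

    def test_finds_planted_subset(self):
        rng = np.random.default_rng(7)
        X, y, true_idx = _planted_pool(rng, noise=0.1)
        cfg = GfaConfig(
            population_size=30, n_crossovers=1500, max_terms=3, min_terms=3, seed=2
        )
        best = evolve(X, y, cfg)[0]
        assert set(best.descriptor_idx) == set(true_idx)

    def test_matches_exhaustive_search_on_small_pool(self):
        """On <= 12 descriptors the GA must find the global LOF optimum."""
        rng = np.random.default_rng(8)
        X, y, _ = _planted_pool(rng, m=12, noise=0.3)
        cfg = GfaConfig(
            population_size=30, n_crossovers=2000, max_terms=3, min_terms=3, seed=4
        )
        best = evolve(X, y, cfg)[0]
        exhaustive = min(
            (
                lof(fit_pls(X[:, list(s)], y)[2], 3, len(y), cfg.smoothing_d, ),
                s,
            )
            for s in itertools.combinations(range(12), 3)
        )
        assert set(best.descriptor_idx) == set(exhaustive[1])
        assert best.lof == pytest.approx(exhaustive[0], rel=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            evolve(np.empty((10, 0)), np.zeros(10), GfaConfig())

    def test_infeasible_sample_count_rejected(self):
        with pytest.raises(InfeasibleModelError):
            evolve(np.zeros((5, 4)), np.zeros(5), GfaConfig(max_terms=9))


class TestSizeSweep:
    def test_exact_term_counts(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(30, 15))
        y = X[:, 0] * 3 + X[:, 4] * -2 + rng.normal(0, 0.2, 30)
        cfg = GfaConfig(population_size=20, n_crossovers=400, seed=0)
        best = size_sweep(pd.DataFrame(X), y, cfg, sizes=(2, 3, 4))
        for size, cand in best.items():
            assert cand.n_terms == size
            assert cand.q2_adj is not None

    def test_recovers_planted_model_quality(self):
        """The sweep winner's adjusted Q2 reaches the generating model's."""
        rng = np.random.default_rng(10)
        n, m = 41, 25
        X = rng.uniform(size=(n, m))
        true_idx = (0, 3, 7, 11, 15, 19, 23)
        beta = rng.uniform(2, 5, size=7) * rng.choice([-1, 1], 7)
        y = 7.0 + X[:, true_idx] @ beta + rng.normal(0, 0.1, n)
        cfg = GfaConfig(population_size=40, n_crossovers=3000, seed=3)
        best = size_sweep(pd.DataFrame(X), y, cfg, sizes=(7,))[7]
        q2_true, _ = loo_q2(X[:, true_idx], y)
        assert best.q2_adj >= adjusted(q2_true, n, 7) - 0.05

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            size_sweep(pd.DataFrame(np.empty((20, 0))), np.zeros(20), GfaConfig())


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        est = GfaPlsRegressor(max_terms=3, n_crossovers=200, population_size=10)
        params = est.get_params()
        assert params["max_terms"] == 3
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_predict_with_dataframe_keys(self):
        rng = np.random.default_rng(11)
        X, y, true_idx = _planted_pool(rng, noise=0.05)
        frame = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
        est = GfaPlsRegressor(
            max_terms=3, min_terms=3, n_crossovers=1000, population_size=25,
            random_state=1,
        ).fit(frame, y)
        assert est.support_.sum() == 3
        assert set(np.flatnonzero(est.support_)) == set(true_idx)
        assert est.best_candidate_.descriptor_keys == tuple(
            f"g{j}" for j in sorted(true_idx)
        )
        pred = est.predict(frame)
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_mutation_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            GfaConfig(mutation_prob=1.5)
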