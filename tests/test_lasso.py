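import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kendalltau

import resq
from resq.config import FACTORS
from resq.lasso_rank import default_lambda_grid

from conftest import orthogonal_config, pipeline_frame


def make_orthonormal_design(n, p, seed):
    """Columns with X'X / n = I (the scale coordinate descent assumes)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    return q[:, :p] * np.sqrt(n)


class TestPath:
    def test_full_shrinkage_at_large_lambda(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=100)
        coefs = resq.fit_lasso_path(X, y, [1e6])
        assert np.allclose(coefs, 0.0)

    def test_zero_lambda_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        y = X @ np.array([1.0, -1.0, 0.3, 2.0]) + rng.normal(size=200)
        coefs = resq.fit_lasso_path(X, y, [0.0])[:, 0]
        yc = y - y.mean()
        ols = np.linalg.lstsq(np.column_stack([np.ones(200), X]), yc, rcond=None)[0][1:]
        assert np.allclose(coefs, ols, atol=1e-6)

    def test_orthonormal_soft_threshold_closed_form(self):
        n, p = 400, 6
        X = make_orthonormal_design(n, p, seed=2)
        rng = np.random.default_rng(3)
        beta = np.array([2.0, -1.5, 0.8, 0.3, -0.1, 0.0])
        y = X @ beta + rng.normal(size=n)
        yc = y - y.mean()
        beta_ols = X.T @ yc / n
        for lam in (0.05, 0.4, 1.0):
            coefs = resq.fit_lasso_path(X, y, [lam])[:, 0]
            expected = np.sign(beta_ols) * np.maximum(np.abs(beta_ols) - lam, 0.0)
            assert np.allclose(coefs, expected, atol=1e-8), lam

    def test_strongest_predictor_enters_first(self):
        n, p = 400, 4
        X = make_orthonormal_design(n, p, seed=4)
        beta = np.array([0.2, 1.5, 0.4, 0.0])
        y = X @ beta
        grid = default_lambda_grid(X, y - y.mean())
        path = resq.fit_lasso_path(X, y, grid)
        first_nonzero = (np.abs(path) > 1e-12).argmax(axis=1)
        active = first_nonzero[first_nonzero > 0]
        assert first_nonzero[1] == active.min()

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            resq.fit_lasso_path(np.empty((10, 0)), np.zeros(10), [0.1])


class TestOneSERule:
    def test_forced_example(self):
        lam = resq.select_lambda_1se([10, 5, 4, 6], [1, 1, 1, 1], [4, 3, 2, 1])
        assert lam == 3.0

    def test_tiny_ses_select_minimum(self):
        means = np.linspace(10, 1, 20)
        lam = resq.select_lambda_1se(means, np.full(20, 1e-12), np.linspace(5, 0.1, 20))
        assert lam == 0.1

    @given(
        means=st.lists(st.floats(0.1, 100), min_size=3, max_size=20),
        ses=st.lists(st.floats(0.0, 10), min_size=3, max_size=20),
    )
    def test_agrees_with_exhaustive_scan(self, means, ses):
        k = min(len(means), len(ses))
        means, ses = np.array(means[:k]), np.array(ses[:k])
        lams = np.linspace(5, 0.1, k)
        got = resq.select_lambda_1se(means, ses, lams)
        cutoff = means.min() + ses[means.argmin()]
        brute = max(l for l, m in zip(lams, means) if m <= cutoff)
        assert got == brute

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            resq.select_lambda_1se([np.nan, np.nan], [1, 1], [2, 1])


class TestDevianceRatio:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert resq.deviance_ratio(y, y) == 1.0

    def test_intercept_only(self):
        y = np.array([1.0, 2.0, 3.0])
        assert resq.deviance_ratio(y, np.full(3, y.mean())) == 0.0

    def test_hand_arithmetic(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        pred = np.array([0.5, 1.0, 1.5, 3.0])
        rss = 0.25 + 0.0 + 0.25 + 0.0
        rss0 = float(((y - 1.5) ** 2).sum())
        assert np.isclose(resq.deviance_ratio(y, pred), 1 - rss / rss0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            resq.deviance_ratio(np.ones(5), np.ones(5))


class TestRanking:
    def test_rank_by_absolute_value(self):
        ranks = resq.rank_factors({"a": 0.3, "b": -0.4, "c": 0.1})
        assert ranks == {"b": 1, "a": 2, "c": 3}

    def test_tie_break_by_name(self):
        ranks = resq.rank_factors({"b": 0.0, "a": 0.0, "c": 0.0})
        assert ranks == {"a": 1, "b": 2, "c": 3}


class TestStability:
    def test_single_run_frequencies_binary(self, analysis_frame):
        ranker = resq.LassoFactorRanker(random_state=0).fit(
            analysis_frame[list(FACTORS)], analysis_frame["res_c"].to_numpy()
        )
        freq = ranker.stability(runs=1)
        assert set(freq.values()) <= {0.0, 1.0}

    def test_pure_noise_factor_rarely_selected(self):
        rng = np.random.default_rng(5)
        n = 2000
        X = pd.DataFrame(
            {"signal": rng.normal(size=n), "noise": rng.normal(size=n)}
        )
        y = 2.0 * X["signal"].to_numpy() + rng.normal(size=n)
        ranker = resq.LassoFactorRanker(random_state=1).fit(X, y)
        freq = ranker.stability(runs=20)
        assert freq["signal"] == 1.0
        assert freq["noise"] < 1.0

    def test_invalid_runs(self, analysis_frame):
        ranker = resq.LassoFactorRanker(random_state=0).fit(
            analysis_frame[list(FACTORS)], analysis_frame["res_c"].to_numpy()
        )
        with pytest.raises(ValueError, match="runs"):
            ranker.stability(runs=0)


class TestWholePipelineRecovery:
    def test_rank_order_recovers_weight_order(self):
        # orthogonal factor design so joint |coefficients| mirror weights
        w = dict(resq.default_config().factor_weights)
        true_order = {f: r + 1 for r, f in enumerate(sorted(w, key=lambda k: -abs(w[k])))}
        taus = []
        for seed in range(20):
            cfg = orthogonal_config(n_participants=10000, seed=seed, factor_weights=w)
            res = pipeline_frame(cfg)
            ranker = resq.LassoFactorRanker(random_state=seed).fit(
                res[list(FACTORS)], res["res_c"].to_numpy()
            )
            ranks = ranker.rank()
            tau = kendalltau(
                [true_order[f] for f in FACTORS], [ranks[f] for f in FACTORS]
            ).statistic
            taus.append(tau)
        assert np.mean(taus) >= 0.8

    def test_cv_folds_partition_rows(self):
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=10, shuffle=True, random_state=0)
        seen = np.zeros(105, dtype=int)
        for _, va in kf.split(np.arange(105)):
            seen[va] += 1
        assert (seen == 1).all()

    def test_dominant_weights_rank_first_and_second(self):
        weights = {f: 0.3 for f in FACTORS}
        weights.update({"rec": 1.6, "pac": 1.1, "neu": -0.3})
        cfg = orthogonal_config(n_participants=10000, seed=3, factor_weights=weights)
        res = pipeline_frame(cfg)
        ranker = resq.LassoFactorRanker(random_state=3).fit(
            res[list(FACTORS)], res["res_c"].to_numpy()
        )
        ranks = ranker.rank()
        assert ranks["rec"] == 1 and ranks["pac"] == 2
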