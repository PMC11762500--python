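import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal
from scipy.special import betaln

import methalc as m
from methalc.bayesr import (
    BayesRConfig,
    ChainStore,
    _batch_means_var,
    autocorrelation,
    call_significant,
    geweke,
    precorrect,
    summarize,
)
from conftest import standardized


class TestPrecorrect:
    def test_matches_two_step_ols_oracle(self, rng):
        n, p = 100, 10
        Xm = standardized(rng, n, p) * 2 + 1.0
        cov = pd.DataFrame({"age": rng.normal(50, 10, n), "sex": rng.choice(["F", "M"], n),
                            "smoking_score": rng.standard_normal(n)})
        units = np.abs(rng.normal(8, 5, n))
        X_std, y_resid = precorrect(Xm, units, cov)

        C = np.column_stack([np.ones(n), cov["age"], (cov["sex"] == "M").astype(float),
                             cov["smoking_score"]])
        H = C @ np.linalg.solve(C.T @ C, C.T)
        y_exp = (np.eye(n) - H) @ np.log1p(units)
        y_exp = y_exp / y_exp.std()
        assert np.allclose(y_resid, y_exp, atol=1e-10)
        X_exp = (np.eye(n) - H) @ Xm.to_numpy()
        X_exp = (X_exp - X_exp.mean(0)) / X_exp.std(0)
        assert np.allclose(X_std.to_numpy(), X_exp, atol=1e-10)

    def test_columns_standardized_and_orthogonal(self, rng):
        n = 80
        Xm = standardized(rng, n, 6)
        cov = pd.DataFrame({"age": rng.normal(50, 10, n),
                            "smoking_score": rng.standard_normal(n)})
        X_std, y_resid = precorrect(Xm, np.abs(rng.normal(5, 2, n)), cov,
                                    batch=rng.integers(0, 3, n))
        assert np.allclose(X_std.mean(0), 0, atol=1e-10)
        assert np.allclose(X_std.std(0, ddof=0), 1, atol=1e-10)
        assert abs(np.asarray(y_resid) @ cov["age"].to_numpy()
                   / (np.linalg.norm(y_resid) * np.linalg.norm(cov["age"]))) < 1e-8

    def test_covariate_copy_column_dropped(self, rng):
        n = 60
        age = rng.normal(50, 10, n)
        Xm = standardized(rng, n, 4)
        Xm["cg_age"] = age  # identical to a covariate
        cov = pd.DataFrame({"age": age})
        with pytest.warns(UserWarning, match="no residual variance"):
            X_std, _ = precorrect(Xm, np.abs(rng.normal(5, 2, n)), cov)
        assert "cg_age" not in X_std.columns

    def test_no_effect_covariate_reduces_to_scaling(self, rng):
        """A covariate independent of X and y barely changes precorrection:
        the result is close to plain centering/scaling."""
        n = 400
        Xm = standardized(rng, n, 5)
        cov = pd.DataFrame({"noise": rng.standard_normal(n)})
        X_std, _ = precorrect(Xm, np.abs(rng.normal(5, 2, n)), cov)
        direct = ((Xm - Xm.mean()) / Xm.std(ddof=0)).to_numpy()
        for j in range(5):
            r = np.corrcoef(X_std.to_numpy()[:, j], direct[:, j])[0, 1]
            assert r > 0.99


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mixture_variances": (0.01, 0.001)},      # not increasing
            {"mixture_variances": (0.0, 0.01)},         # nonpositive
            {"thin": 0},
            {"pip_threshold": 1.0},
            {"draws_retained": 0},
            {"fixed_pi": (0.5, 0.5)},                   # wrong length for K=3
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BayesRConfig(**kwargs)

    def test_default_chain_accounting(self):
        cfg = BayesRConfig()
        assert cfg.burn_in == 5000 and cfg.draws_retained == 10000
        assert cfg.thin == 5 and cfg.used_iterations == 1000
        assert cfg.n_stored == 2000


class TestGibbs:
    def test_null_signal_no_calls_and_tiny_ve(self, rng):
        """With y independent of X no CpG approaches significance and the
        variance-explained draws concentrate near zero.  (At toy dimensions
        the small-variance slab is barely identified, so individual PIPs sit
        near the mixture-proportion posterior rather than at zero; the
        significance threshold and the variance component are the stable
        readouts.)"""
        X = standardized(rng, 400, 400)
        y = pd.Series(rng.standard_normal(400), index=X.index)
        y = (y - y.mean()) / y.std()
        cfg = BayesRConfig(burn_in=300, draws_retained=600, thin=1,
                           used_iterations=600, seed=1)
        post = summarize(m.gibbs_sample(X, y, cfg))
        assert post.table["pip"].max() < 0.95
        assert post.var_explained_mean < 0.15

    def test_strong_single_effect_detected(self, rng):
        X = standardized(rng, 400, 20)
        g = 0.3 * X.iloc[:, 0].to_numpy()
        y = g + rng.standard_normal(400) * np.sqrt(1 - 0.09)
        y = pd.Series((y - y.mean()) / y.std(), index=X.index)
        cfg = BayesRConfig(burn_in=300, draws_retained=600, thin=1,
                           used_iterations=600, seed=2)
        post = summarize(m.gibbs_sample(X, y, cfg))
        assert post.table["pip"].iloc[0] > 0.95
        assert post.table["mean_beta"].iloc[0] == pytest.approx(0.3, abs=0.1)

    def test_deterministic_per_seed(self, rng):
        X = standardized(rng, 100, 15)
        y = pd.Series(rng.standard_normal(100), index=X.index)
        cfg = BayesRConfig(burn_in=50, draws_retained=100, thin=1,
                           used_iterations=100, seed=9)
        c1 = m.gibbs_sample(X, y, cfg)
        c2 = m.gibbs_sample(X, y, cfg)
        assert np.array_equal(c1.betas, c2.betas)

    def test_column_permutation_equivariance(self, rng):
        """Permuting CpG columns permutes the posterior summaries exactly."""
        X = standardized(rng, 120, 12)
        g = 0.4 * X.iloc[:, 3].to_numpy()
        y = pd.Series(g + rng.standard_normal(120), index=X.index)
        cfg = BayesRConfig(burn_in=100, draws_retained=200, thin=1,
                           used_iterations=200, seed=4)
        post1 = summarize(m.gibbs_sample(X, y, cfg))
        perm = rng.permutation(X.shape[1])
        post2 = summarize(m.gibbs_sample(X.iloc[:, perm], y, cfg))
        reordered = post2.table.loc[post1.table.index]
        pd.testing.assert_frame_equal(post1.table, reordered)

    def test_non_finite_input_rejected(self, rng):
        X = standardized(rng, 30, 4)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            m.gibbs_sample(X, pd.Series(np.zeros(30), index=X.index),
                           BayesRConfig(burn_in=5, draws_retained=10, thin=1))

    def test_occupancy_conservation_and_ve_range(self, rng):
        X = standardized(rng, 150, 25)
        y = pd.Series(rng.standard_normal(150), index=X.index)
        cfg = BayesRConfig(burn_in=100, draws_retained=300, thin=1,
                           used_iterations=300, seed=6)
        post = summarize(m.gibbs_sample(X, y, cfg))
        occ = post.table[[c for c in post.table if c.startswith("occ_")]]
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert (post.var_explained_draws >= 0).all()
        assert (post.var_explained_draws <= 1.05).all()


class TestRidgeLimit:
    def test_single_component_matches_conjugate_posterior(self, rng):
        """With one slab, no spike, and fixed residual variance, the sampler
        draws from the exact Normal conjugate posterior."""
        n = 300
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        beta_true, sigma2, gamma = 0.5, 1.0, 0.25
        y = beta_true * x + rng.standard_normal(n) * np.sqrt(sigma2)
        X = pd.DataFrame({"cg0": x})
        cfg = BayesRConfig(
            mixture_variances=(gamma,), burn_in=200, draws_retained=4000, thin=1,
            used_iterations=4000, seed=3, fixed_sigma2=sigma2, fixed_pi=(0.0, 1.0),
        )
        chains = m.gibbs_sample(X, pd.Series(y, index=X.index), cfg)
        draws = chains.betas[:, 0]
        xtx = float(x @ x)
        v = 1.0 / (xtx / sigma2 + 1.0 / gamma)
        mean = v * float(x @ y) / sigma2
        mc_se = np.sqrt(v / len(draws))
        assert draws.mean() == pytest.approx(mean, abs=4 * mc_se)
        assert draws.var() == pytest.approx(v, rel=0.15)


def _bma_oracle(X, y, gamma, sigma2):
    """Exhaustive Bayesian model averaging over all 2^p subsets with analytic
    Gaussian marginal likelihoods and a Beta-Binomial subset prior (the
    marginal of Dirichlet(1,1) mixture proportions)."""
    n, p = X.shape
    log_w, subsets = [], []
    for mask in range(2**p):
        S = [j for j in range(p) if mask >> j & 1]
        cov = sigma2 * np.eye(n)
        if S:
            XS = X[:, S]
            cov = cov + gamma * XS @ XS.T
        ll = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        k = len(S)
        prior = betaln(k + 1, p - k + 1)  # integrates pi^k (1-pi)^(p-k)
        log_w.append(ll + prior)
        subsets.append(mask)
    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    pip = np.zeros(p)
    for wt, mask in zip(w, subsets):
        for j in range(p):
            if mask >> j & 1:
                pip[j] += wt
    return pip


class TestBMAOracle:
    def test_pips_match_exhaustive_model_averaging(self, rng):
        n, p = 40, 5
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        beta = np.array([0.8, 0.0, -0.6, 0.0, 0.0])
        sigma2, gamma = 1.0, 0.5
        y = X @ beta + rng.standard_normal(n) * np.sqrt(sigma2)

        oracle = _bma_oracle(X, y, gamma, sigma2)

        Xdf = pd.DataFrame(X, columns=[f"cg{j}" for j in range(p)])
        cfg = BayesRConfig(
            mixture_variances=(gamma,), burn_in=1000, draws_retained=8000, thin=1,
            used_iterations=8000, seed=5, fixed_sigma2=sigma2,
        )
        chains = m.gibbs_sample(Xdf, pd.Series(y, index=Xdf.index), cfg)
        inc = (chains.components > 0).astype(float)
        pips = inc.mean(axis=0)
        for j in range(p):
            se = np.sqrt(max(_batch_means_var(inc[:, j]), 1e-12))
            assert abs(pips[j] - oracle[j]) < max(3 * se, 0.02), (
                f"cg{j}: sampler {pips[j]:.3f} vs oracle {oracle[j]:.3f}"
            )


class TestSummarize:
    def _store(self, betas, comps):
        betas = np.asarray(betas, dtype=float)
        comps = np.asarray(comps, dtype=np.int8)
        t, p = betas.shape
        return ChainStore(
            betas=betas, components=comps, sigma2=np.ones(t),
            pi=np.tile([0.5, 0.5], (t, 1)),
            fit_var=(betas**2).sum(axis=1),  # orthonormal-design equivalent
            cpg_ids=pd.Index([f"cg{j}" for j in range(p)]),
            y_variance=1.0,
            config=BayesRConfig(mixture_variances=(0.01,), burn_in=0,
                                draws_retained=t, thin=1, used_iterations=t),
        )

    def test_hand_built_chain_counts(self):
        betas = [[0.1], [0.2], [0.0], [0.3]]
        comps = [[1], [1], [0], [1]]
        post = summarize(self._store(betas, comps))
        assert post.table.loc["cg0", "pip"] == pytest.approx(0.75)
        assert post.table.loc["cg0", "mean_beta"] == pytest.approx(0.15)
        assert post.table.loc["cg0", "occ_null"] == pytest.approx(0.25)

    def test_all_zero_draws(self):
        post = summarize(self._store(np.zeros((4, 2)), np.zeros((4, 2))))
        assert (post.table["pip"] == 0).all()
        assert (post.table["mean_beta"] == 0).all()
        assert post.var_explained_mean == 0.0

    def test_ci_ordered_and_in_range(self):
        betas = np.array([[0.1, 0.0], [0.5, 0.1], [0.2, 0.0], [0.3, 0.2]])
        comps = (betas != 0).astype(int)
        post = summarize(self._store(betas, comps))
        lo, hi = post.var_explained_ci
        assert 0 <= lo <= hi

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            summarize(self._store(np.zeros((4, 1)), np.zeros((4, 1))),
                      used_iterations=1)


class TestCallSignificant:
    def _post(self, pips):
        table = pd.DataFrame(
            {"pip": pips, "mean_beta": 0.0, "se": 0.0},
            index=[f"cg{j}" for j in range(len(pips))],
        )
        return m.BayesRPosterior(table=table, var_explained_draws=np.zeros(2),
                                 var_explained_mean=0.0, var_explained_ci=(0, 0),
                                 sum_sq_draws=np.zeros(2), sum_sq_mean=0.0,
                                 n_used=2)

    def test_strict_threshold(self):
        out = call_significant(self._post([0.96, 0.95, 0.99]), 0.95)
        assert list(out.index) == ["cg2", "cg0"]  # 0.95 excluded: strictly over

    def test_empty_when_all_zero(self):
        assert call_significant(self._post([0.0, 0.0]), 0.95).empty

    def test_threshold_zero_returns_any_occupancy(self):
        out = call_significant(self._post([0.0, 0.4, 0.2]), 0.0)
        assert list(out.index) == ["cg1", "cg2"]

    def test_ties_sorted_by_identifier(self):
        out = call_significant(self._post([0.99, 0.99, 0.5]), 0.9)
        assert list(out.index) == ["cg0", "cg1"]


class TestGeweke:
    def test_iid_chain_calibrated(self):
        rng = np.random.default_rng(17)
        z = [geweke(rng.standard_normal(10_000)) for _ in range(300)]
        frac = np.mean(np.abs(z) < 1.96)
        assert 0.90 < frac <= 1.0

    def test_mean_shift_detected(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            chain = np.concatenate(
                [rng.standard_normal(2000) + 3.0, rng.standard_normal(2000)]
            )
            assert abs(geweke(chain)) > 3.0

    def test_identical_segments_zero(self):
        seg = np.sin(np.arange(500)) + np.arange(500) % 7
        chain = np.concatenate([seg, seg])
        # halves identical -> segment means equal -> z exactly 0
        assert geweke(chain, frac_first=0.5, frac_last=0.5) == 0.0

    def test_constant_chain_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert geweke(np.ones(1000)) == 0.0

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            geweke(np.arange(50), frac_first=0.1)  # first segment < 10 draws
        with pytest.raises(ValueError):
            geweke(np.arange(1000), frac_first=0.6, frac_last=0.5)

    def test_autocorrelation_table(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        acf = autocorrelation(x, max_lag=5)
        assert acf.iloc[0] == 1.0
        assert np.abs(acf.iloc[1:]).max() < 0.05
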