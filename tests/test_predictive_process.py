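"""Predictive-process factor, Woodbury likelihood and fitting.

Oracles: the low-rank construction is compared against the dense
knot-conditional (Schur) formula evaluated with an explicit inverse, and the
Woodbury/determinant-lemma likelihood against the dense multivariate-normal
log-density.
"""

import numpy as np
import pytest
from scipy import stats as sps

import predlmm as pl
from predlmm.greml_exact import dense_fisher_se, dense_loglik
from predlmm.simulate import _blocks_from_dense


def _random_psd(n, rng, m=None):
    """Gram-matrix GRM stand-in: (1/m) W W' with iid standardized columns."""
    m = m or 3 * n
    w = rng.standard_normal((n, m))
    return w @ w.T / m


def _factor_from_dense(A, knots):
    return pl.build_pp_factor(_blocks_from_dense(A, np.asarray(knots)))


class TestBuildFactor:
    def test_matches_dense_schur_formula(self):
        """U U' + diag(d_res) equals A_BI A_II^-1 A_IB plus the residual
        diagonal computed with an explicit inverse."""
        rng = np.random.default_rng(0)
        A = _random_psd(30, rng)
        knots = np.array([2, 5, 11, 17, 23, 29])
        f = _factor_from_dense(A, knots)
        low = A[:, knots] @ np.linalg.inv(A[np.ix_(knots, knots)]) @ A[knots, :]
        expected = low + np.diag(np.diag(A) - np.diag(low))
        assert np.abs(f.dense() - expected).max() <= 1e-8

    def test_residual_diagonal_vanishes_at_knots(self):
        rng = np.random.default_rng(1)
        f = _factor_from_dense(_random_psd(40, rng), [0, 7, 13, 21, 33, 39])
        np.testing.assert_allclose(f.d_res[f.knot_indices], 0.0, atol=1e-8)
        assert (f.d_res >= 0).all()

    def test_exact_reconstruction_at_full_rank(self, small_cohort):
        A = small_cohort["grm"].values
        f = _factor_from_dense(A, np.arange(A.shape[0]))
        assert np.abs(f.dense() - A).max() <= 1e-8

    def test_diag_and_knot_block_fidelity(self, small_cohort):
        """The approximation agrees with A on the diagonal and on the
        knot x knot block."""
        A = small_cohort["grm"].values
        knots = np.array([3, 10, 31, 44, 77, 99, 110])
        f = _factor_from_dense(A, knots)
        App = f.dense()
        assert np.abs(np.diag(App) - np.diag(A)).max() <= 1e-8
        assert np.abs(App[np.ix_(knots, knots)] - A[np.ix_(knots, knots)]).max() <= 1e-8

    def test_jitter_ladder_on_singular_knot_block(self):
        """Duplicated knot individuals make A_II singular; the ladder must
        still produce a usable factor."""
        rng = np.random.default_rng(2)
        w = rng.standard_normal((20, 60))
        w[4] = w[3]  # identical genotypes -> identical GRM rows
        A = w @ w.T / 60
        f = _factor_from_dense(A, [3, 4, 10])
        assert f.jitter_used > 0
        assert np.isfinite(f.dense()).all()


class TestWoodburyLoglik:
    @pytest.mark.parametrize("reml", [True, False], ids=["reml", "ml"])
    def test_equals_dense_loglik(self, reml):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n, r = 100, 12
            A = _random_psd(n, rng)
            f = _factor_from_dense(A, rng.choice(n, r, replace=False))
            y = rng.standard_normal(n)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            par = pl.VarianceParams(h2=rng.uniform(0.05, 0.95), sigma_p2=rng.uniform(0.5, 3))
            ll_w, b_w = pl.pp_loglik(par, y, X, f, reml=reml)
            ll_d, b_d = dense_loglik(par, y, X, f.dense(), reml=reml)
            assert ll_w == pytest.approx(ll_d, abs=1e-8)
            np.testing.assert_allclose(b_w, b_d, atol=1e-8)

    def test_h2_zero_reduces_to_iid_gaussian(self):
        """At h2=0 the covariance is sigma_p^2 I: the ML log-likelihood has
        the closed iid form and GLS collapses to OLS."""
        rng = np.random.default_rng(4)
        n = 80
        f = _factor_from_dense(_random_psd(n, rng), [1, 5, 9])
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        s2 = 1.7
        ll, beta = pl.pp_loglik(pl.VarianceParams(h2=0.0, sigma_p2=s2), y, X, f, reml=False)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        ll_iid = sps.norm.logpdf(resid, scale=np.sqrt(s2)).sum()
        assert ll == pytest.approx(ll_iid, abs=1e-8)
        np.testing.assert_allclose(beta, beta_ols, atol=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 60
        A = _random_psd(n, rng)
        f = _factor_from_dense(A, [0, 11, 22, 33])
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        par = pl.VarianceParams(h2=0.4, sigma_p2=1.2)
        ll, _ = pl.pp_loglik(par, y, X, f, reml=True)
        perm = rng.permutation(n)
        f_p = pl.PPFactor(
            U=f.U[perm], d_res=f.d_res[perm], knot_indices=np.argsort(perm)[f.knot_indices]
        )
        ll_p, _ = pl.pp_loglik(par, y[perm], X[perm], f_p, reml=True)
        assert ll_p == pytest.approx(ll, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(6)
        n = 40
        f = _factor_from_dense(_random_psd(n, rng), [0, 3])
        X = np.ones((n, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            pl.pp_loglik(pl.VarianceParams(h2=0.3), rng.standard_normal(n), X, f)


class TestFit:
    def test_null_phenotype_estimates_near_zero(self):
        """Pure iid noise, independent of the genotypes, should give an
        estimate at (or hugging) the h2=0 boundary."""
        rng = np.random.default_rng(7)
        cfg = pl.CoalescentConfig(n_individuals=400, n_variants=800)
        ds = pl.simulate_genotypes(pl.simulate_bn_frequencies(cfg, rng), cfg, rng)
        stats = pl.compute_standardization(ds)
        blocks = pl.compute_grm_blocks(ds, stats, pl.select_knots_random(400, 60, 1).indices)
        f = pl.build_pp_factor(blocks)
        fit = pl.fit_predlmm(rng.standard_normal(400), None, f, compute_se=False)
        assert fit.h2_hat <= 0.05

    def test_estimate_within_unit_interval_and_consistent(self, small_cohort):
        d, stats = small_cohort["dataset"], small_cohort["stats"]
        rng = np.random.default_rng(8)
        y, _, _ = pl.simulate_phenotype_causal(
            d, stats, pl.PhenotypeSimConfig(h2_true=0.6, m_causal=40), rng
        )
        for r in (10, 40, 120):
            blocks = pl.compute_grm_blocks(d, stats, pl.select_knots_random(120, r, 2).indices)
            fit = pl.fit_predlmm(y, None, pl.build_pp_factor(blocks), compute_se=False)
            assert 0.0 <= fit.h2_hat <= 1.0
            assert fit.h2_hat == pytest.approx(
                fit.sigma_h2 / (fit.sigma_h2 + fit.sigma_e2), abs=1e-12
            )

    def test_full_rank_fit_matches_dense_greml(self, small_cohort):
        d, stats, A = small_cohort["dataset"], small_cohort["stats"], small_cohort["grm"].values
        rng = np.random.default_rng(9)
        y, _, _ = pl.simulate_phenotype_causal(
            d, stats, pl.PhenotypeSimConfig(h2_true=0.5, m_causal=40), rng
        )
        blocks = pl.compute_grm_blocks(d, stats, np.arange(d.n_samples))
        fit_pp = pl.fit_predlmm(y, None, pl.build_pp_factor(blocks), compute_se=False)
        fit_dn = pl.fit_greml_dense(y, None, A, compute_se=False)
        assert fit_pp.h2_hat == pytest.approx(fit_dn.h2_hat, abs=1e-4)

    def test_non_finite_phenotype_rejected(self, small_cohort):
        A = small_cohort["grm"].values
        f = _factor_from_dense(A, [0, 1, 2])
        y = np.zeros(A.shape[0])
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pl.fit_predlmm(y, None, f)


class TestAsymptoticSe:
    def _fitted_instance(self, seed, n=160, r=16, h2=0.6):
        rng = np.random.default_rng(seed)
        A = _random_psd(n, rng, m=n)
        f = _factor_from_dense(A, rng.choice(n, r, replace=False))
        sim = pl.PhenotypeSimConfig(h2_true=h2, model="grm_gaussian")
        y = pl.simulate_phenotype_grm(f, sim, rng)
        fit = pl.fit_predlmm(y, None, f, compute_se=False)
        return fit, f

    def test_positive_and_equal_to_dense_fisher(self):
        """The O(N r^2) trace algebra must reproduce the dense expected
        Fisher information exactly (same formula, different algebra)."""
        for seed in (10, 11, 12):
            fit, f = self._fitted_instance(seed)
            if fit.boundary_flag:
                continue
            X = np.ones((f.n_samples, 1))
            se = pl.asymptotic_se(fit, f, X, add_intercept=False)
            se_dense = dense_fisher_se(fit, f.dense(), X, reml=True, add_intercept=False)
            assert se > 0
            assert se == pytest.approx(se_dense, rel=1e-9)

    def test_boundary_fit_has_no_se(self):
        rng = np.random.default_rng(13)
        f = _factor_from_dense(_random_psd(100, rng), [0, 9, 33])
        fit = pl.fit_predlmm(rng.standard_normal(100), None, f, compute_se=False)
        assert fit.boundary_flag
        with pytest.raises(ValueError, match="boundary"):
            pl.asymptotic_se(fit, f, None)

    def test_se_shrinks_with_sample_size(self):
        """Median SE should decrease with cohort size on structured
        (coalescent) cohorts, where the knots capture the shared block
        relatedness and information accumulates across samples."""

        def instance(seed, n):
            rng = np.random.default_rng(seed)
            cfg = pl.CoalescentConfig(n_individuals=n, n_variants=800)
            ds = pl.simulate_genotypes(pl.simulate_bn_frequencies(cfg, rng), cfg, rng)
            stats = pl.compute_standardization(ds)
            kn = pl.select_knots_random(n, 24, seed)
            f = pl.build_pp_factor(pl.compute_grm_blocks(ds, stats, kn.indices))
            y = pl.simulate_phenotype_grm(
                f, pl.PhenotypeSimConfig(h2_true=0.5, model="grm_gaussian"), rng
            )
            return pl.fit_predlmm(y, None, f, compute_se=False), f

        ses = {}
        for n in (200, 800):
            vals = []
            for seed in range(40, 52):
                fit, f = instance(seed, n)
                if not fit.boundary_flag:
                    vals.append(pl.asymptotic_se(fit, f, None))
            ses[n] = np.median(vals)
        assert ses[800] < ses[200]
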