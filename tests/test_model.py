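"""FIML estimator: likelihood correctness, ascent, invariances, oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from lungmediation.coefficients import ModelSpec
from lungmediation.model import (FitError, build_group_data, fit_group_model,
                                 fit_multigroup_model, initial_values,
                                 observed_loglik, oracle_fit)
from lungmediation.synthetic import (attach_latent_oracle,
                                     default_generator_params, generate_cohort)


def scale_outcomes(coefs, factor):
    """Coefficient set matching an outcome rescale by ``factor``."""
    out = coefs.copy()
    out.c *= factor
    out.b1 *= factor
    out.b2 *= factor
    out.sigma *= factor ** 2
    return out


def scaled_table(table, factor):
    df = table.df.copy()
    for col in ("fev1_ml", "fvc_ml"):
        df[col] *= factor
    return dataclasses.replace(table, df=df)


class TestObservedLoglik:
    def test_matches_monte_carlo_integral(self, paternal_params):
        """Exact marginalisation agrees with a brute-force MC integral of
        the latent residual on a small table."""
        table, _ = generate_cohort(paternal_params, 12, seed=8)
        spec = ModelSpec(line="paternal")
        gd = build_group_data(table, spec, "son")
        cf = paternal_params.coefficients["son"]
        from lungmediation.model import _estep
        _, _, _, row_ll = _estep(gd, cf)
        rng = np.random.default_rng(0)
        n_draw = 400_000
        sigma_inv = np.linalg.inv(cf.sigma)
        sigma_det = np.linalg.det(cf.sigma)
        for i in range(gd.n):
            eps = rng.standard_normal(n_draw)
            m1s = gd.xm[i] @ cf.a + eps
            consistent = (m1s > 0) == gd.m1[i]
            mu2 = gd.xm[i] @ cf.h + cf.d * m1s
            f_m2 = stats.norm.pdf(gd.m2[i], mu2, cf.sigma_h)
            mu_y = gd.xy[i] @ cf.c.T + np.outer(m1s, cf.b1) + gd.m2[i] * cf.b2
            resid = gd.y[i] - mu_y
            q = np.einsum("ij,jk,ik->i", resid, sigma_inv, resid)
            f_y = np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(sigma_det))
            vals = consistent * f_m2 * f_y
            mc = vals.mean()
            mc_se = vals.std(ddof=1) / np.sqrt(n_draw)
            assert np.exp(row_ll[i]) == pytest.approx(mc, abs=3 * mc_se)

    def test_scale_change_of_variables(self, midsize_cohort, paternal_params):
        """mL -> dL rescale shifts the log-likelihood by the exact Jacobian
        constant when coefficients and variances are rescaled to match."""
        table, _ = midsize_cohort
        spec = ModelSpec(line="paternal")
        cf = paternal_params.coefficients["son"]
        gd = build_group_data(table, spec, "son")
        ll_ml = observed_loglik(gd, spec, "son", cf)
        gd_dl = build_group_data(scaled_table(table, 0.01), spec, "son")
        ll_dl = observed_loglik(gd_dl, spec, "son", scale_outcomes(cf, 0.01))
        jacobian = gd.n * 2 * np.log(0.01)
        assert ll_dl == pytest.approx(ll_ml - jacobian, abs=1e-5 * abs(ll_ml))

    def test_inflated_covariance_decreases_loglik(self, midsize_cohort,
                                                  paternal_spec):
        table, _ = midsize_cohort
        fit = fit_group_model(table, paternal_spec, "son")
        cf = fit.coefficients
        worse = cf.copy()
        worse.sigma = cf.sigma * 2.0
        gd = build_group_data(table, paternal_spec, "son")
        assert observed_loglik(gd, paternal_spec, "son", worse) < fit.loglik

    def test_local_maximum(self, midsize_cohort, paternal_spec):
        """Perturbing any single parameter off the fit lowers the likelihood."""
        table, _ = midsize_cohort
        fit = fit_group_model(table, paternal_spec, "daughter", tol=1e-12,
                              max_iter=3000)
        gd = build_group_data(table, paternal_spec, "daughter")
        vec = fit.coefficients.to_vector()
        rng = np.random.default_rng(3)
        for idx in rng.choice(vec.size, size=8, replace=False):
            for sign in (-1, 1):
                pert = vec.copy()
                pert[idx] += sign * 0.05 * max(abs(pert[idx]), 0.1)
                cf = type(fit.coefficients).from_vector(pert,
                                                        fit.coefficients.outcomes)
                assert observed_loglik(gd, paternal_spec, "daughter", cf) \
                    <= fit.loglik + 1e-6


class TestFitting:
    def test_ascent_over_initial_values(self, midsize_cohort, paternal_spec):
        table, _ = midsize_cohort
        gd = build_group_data(table, paternal_spec, "son")
        init = initial_values(gd, paternal_spec, "son")
        fit = fit_group_model(gd, paternal_spec, "son", init=init)
        assert fit.converged
        assert fit.loglik >= observed_loglik(gd, paternal_spec, "son", init)

    def test_row_permutation_invariance(self, midsize_cohort, paternal_spec):
        table, _ = midsize_cohort
        fit1 = fit_multigroup_model(table, paternal_spec)
        shuffled = dataclasses.replace(
            table, df=table.df.sample(frac=1.0, random_state=4)
            .reset_index(drop=True))
        fit2 = fit_multigroup_model(shuffled, paternal_spec)
        for g in ("son", "daughter"):
            np.testing.assert_allclose(fit1[g].coefficients.to_vector(),
                                       fit2[g].coefficients.to_vector(),
                                       rtol=1e-5, atol=1e-7)

    def test_scale_equivariance_of_estimates(self, midsize_cohort, paternal_spec):
        table, _ = midsize_cohort
        fit_ml = fit_group_model(table, paternal_spec, "son")
        fit_dl = fit_group_model(scaled_table(table, 0.01), paternal_spec, "son")
        cf_ml, cf_dl = fit_ml.coefficients, fit_dl.coefficients
        np.testing.assert_allclose(cf_dl.a, cf_ml.a, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(cf_dl.h, cf_ml.h, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(cf_dl.b2, 0.01 * cf_ml.b2, rtol=1e-3)
        np.testing.assert_allclose(cf_dl.c[:, 1], 0.01 * cf_ml.c[:, 1],
                                   rtol=1e-3, atol=0.05)

    def test_initial_values_deterministic(self, midsize_cohort, paternal_spec):
        table, _ = midsize_cohort
        i1 = initial_values(table, paternal_spec, "son")
        i2 = initial_values(table, paternal_spec, "son")
        np.testing.assert_array_equal(i1.to_vector(), i2.to_vector())

    def test_null_data_initial_paths_near_zero(self, null_params, paternal_spec):
        table, _ = generate_cohort(null_params, 8000, seed=13)
        init = initial_values(table, paternal_spec, "son")
        assert abs(init.a[1]) < 0.3
        assert abs(init.h[1]) < 1.5
        assert abs(init.c[0, 1]) < 120.0

    def test_degenerate_mediator_error(self, small_cohort, paternal_spec):
        table, _ = small_cohort
        df = table.df.copy()
        df["m1_overweight_prepuberty"] = False
        bad = dataclasses.replace(table, df=df)
        with pytest.raises(FitError, match="degenerate"):
            fit_group_model(bad, paternal_spec, "son")

    def test_ratio_model_scalar_covariance(self, midsize_cohort):
        table, _ = midsize_cohort
        spec = ModelSpec(line="paternal", outcome_set="ratio")
        fit = fit_group_model(table, spec, "daughter")
        assert fit.coefficients.sigma.shape == (1, 1)
        assert fit.converged

    def test_post_bronchodilator_uses_complete_pairs(self, midsize_cohort):
        table, _ = midsize_cohort
        pre = build_group_data(table, ModelSpec(line="paternal"), "son")
        post = build_group_data(
            table, ModelSpec(line="paternal", bronchodilator="post"), "son")
        assert 0 < post.n < pre.n

    def test_multigroup_errors_labelled(self, small_cohort):
        table, _ = small_cohort
        df = table.df.copy()
        df.loc[df.sex == "daughter", "m1_overweight_prepuberty"] = True
        bad = dataclasses.replace(table, df=df)
        with pytest.raises(FitError, match="daughter"):
            fit_multigroup_model(bad, ModelSpec(line="paternal"))


class TestOracleFit:
    def test_requires_latent_column(self, small_cohort, paternal_spec):
        table, _ = small_cohort
        with pytest.raises(FitError, match="m1_star"):
            oracle_fit(table, paternal_spec, "son")

    def test_noiseless_height_equation_exact(self, paternal_params,
                                             paternal_spec):
        params = dataclasses.replace(paternal_params, coefficients={
            g: cf.copy() for g, cf in paternal_params.coefficients.items()})
        for cf in params.coefficients.values():
            cf.sigma_h = 1e-8
        table, oracle = generate_cohort(params, 800, seed=14)
        extended = attach_latent_oracle(table, oracle)
        est = oracle_fit(extended, paternal_spec, "son")
        true = params.coefficients["son"]
        np.testing.assert_allclose(est.h, true.h, rtol=1e-5, atol=1e-5)
        assert est.d == pytest.approx(true.d, abs=1e-5)

    def test_agrees_with_fiml_at_moderate_n(self, midsize_cohort,
                                            paternal_spec, paternal_params):
        """Two consistent estimators of the same structural parameters."""
        table, oracle = midsize_cohort
        extended = attach_latent_oracle(table, oracle)
        fiml = fit_group_model(table, paternal_spec, "daughter").coefficients
        orc = oracle_fit(extended, paternal_spec, "daughter")
        np.testing.assert_allclose(fiml.a[1], orc.a[1], atol=0.2)
        np.testing.assert_allclose(fiml.h[1], orc.h[1], atol=1.0)
        np.testing.assert_allclose(fiml.b2, orc.b2, rtol=0.1, atol=3.0)


class TestParameterRecoveryScaling:
    def test_bias_shrinks_with_n(self, paternal_params, paternal_spec):
        """Structural-path error contracts as the cohort grows."""
        errs = {}
        for n_parents, seed in ((1000, 31), (16_000, 32)):
            table, _ = generate_cohort(paternal_params, n_parents, seed=seed)
            fit = fit_group_model(table, paternal_spec, "daughter")
            true = paternal_params.coefficients["daughter"]
            est = fit.coefficients
            errs[n_parents] = (abs(est.h[1] - true.h[1])
                               + abs(est.a[1] - true.a[1])
                               + float(np.abs(est.b2 - true.b2).sum()))
        assert errs[16_000] < errs[1000]
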