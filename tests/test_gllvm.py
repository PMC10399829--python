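import numpy as np
import pytest
from scipy import stats

from commodular.datamodel import CommunityMatrix
from commodular.gllvm import (GLLVMConfig, GLLVMFit, align_ordination, count_parameters,
                              fit_gllvm, model_aic, nb_loglik, observations_per_parameter,
                              residual_diagnostics)
from commodular.synthetic import generate_from_gllvm


class TestParameterCounting:
    @pytest.mark.parametrize("args,expected", [
        ((36, 120, 2, "fixed", "model-based"), 504),
        ((36, 120, 2, "none", "nmds-style"), 240),
        ((7, 50, 0, "none", "model-based"), 14),   # intercept + dispersion only
        ((36, 120, 0, "none", "model-based"), 72),
    ])
    def test_counts(self, args, expected):
        assert count_parameters(*args) == expected

    def test_observations_per_parameter(self):
        assert observations_per_parameter(36, 120, 504) == pytest.approx(8.571, abs=1e-3)
        assert round(observations_per_parameter(36, 120, 504), 1) == 8.6
        assert observations_per_parameter(10, 10, 100) == 1.0
        assert observations_per_parameter(36, 120, 240) == 18.0
        with pytest.raises(ValueError):
            observations_per_parameter(36, 120, 0)


def _sim_params(seed, n=200, m=30, d=2):
    rng = np.random.default_rng(seed)
    return (rng.normal(1.0, 1.0, m), rng.normal(0.0, 0.7, (m, d)),
            rng.standard_normal((n, d)), rng.normal(0.0, 0.3, n), rng.uniform(0.5, 4.0, m))


class TestFit:
    def test_intercept_only_closed_form(self):
        cm = CommunityMatrix(np.full((40, 1), 7), [f"s{i}" for i in range(40)], ["a"])
        fit = fit_gllvm(cm, GLLVMConfig(n_lv=0, row_effect="none", seed=0))
        assert fit.beta0[0] == pytest.approx(np.log(7.0), abs=1e-3)
        assert fit.mu()[0, 0] == pytest.approx(7.0, rel=1e-3)

    def test_all_zero_taxon_refused(self):
        counts = np.ones((10, 3), dtype=int)
        counts[:, 1] = 0
        cm = CommunityMatrix(counts, [f"s{i}" for i in range(10)], ["a", "b", "c"])
        with pytest.raises(ValueError, match="b"):
            fit_gllvm(cm, GLLVMConfig(seed=0))

    def test_loading_recovery_after_alignment(self):
        beta0, theta, u, alpha, phi = _sim_params(1)
        cm = generate_from_gllvm(beta0, theta, u, alpha, phi, seed=1001)
        fit = fit_gllvm(cm, GLLVMConfig(seed=1))
        _, aligned, _ = align_ordination(theta, fit.theta)
        for axis in range(2):
            r = np.corrcoef(theta[:, axis], aligned[:, axis])[0, 1]
            assert r >= 0.9

    def test_fit_improves_on_intercept_model(self, small_study):
        cm, _, _ = small_study
        full = fit_gllvm(cm, GLLVMConfig(n_lv=2, seed=0))
        null = fit_gllvm(cm, GLLVMConfig(n_lv=0, seed=0))
        assert full.loglik > null.loglik

    def test_loglik_matches_independent_summation(self, study, study_fit):
        cm, _, _ = study
        fit = study_fit
        mu = fit.mu()
        p = fit.phi[None, :] / (fit.phi[None, :] + mu)
        ll = float(stats.nbinom.logpmf(cm.counts, fit.phi[None, :], p).sum())
        assert fit.loglik == pytest.approx(ll, rel=1e-6)
        assert nb_loglik(cm.counts, mu, fit.phi) == pytest.approx(ll, rel=1e-9)

    def test_fitted_means_invariant_to_axis_rotation(self, study_fit):
        fit = study_fit
        ang = 0.7
        Q = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = GLLVMFit(alpha=fit.alpha, beta0=fit.beta0, theta=fit.theta @ Q,
                           u=fit.u @ Q, phi=fit.phi, loglik=fit.loglik,
                           converged=fit.converged, n_iter=fit.n_iter, config=fit.config)
        np.testing.assert_allclose(rotated.mu(), fit.mu(), rtol=1e-10)

    def test_canonical_form(self, study_fit):
        fit = study_fit
        # scores whitened, loadings centered and variance-ordered
        np.testing.assert_allclose(fit.u.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(np.cov(fit.u, rowvar=False, ddof=1), np.eye(2), atol=1e-6)
        np.testing.assert_allclose(fit.theta.mean(axis=0), 0.0, atol=1e-8)
        v = fit.theta.var(axis=0, ddof=1)
        assert v[0] >= v[1]

    def test_deterministic_given_seed(self, small_study):
        cm, _, _ = small_study
        f1 = fit_gllvm(cm, GLLVMConfig(seed=5))
        f2 = fit_gllvm(cm, GLLVMConfig(seed=5))
        np.testing.assert_array_equal(f1.theta, f2.theta)
        assert f1.loglik == f2.loglik

    def test_parameter_recovery_summary(self):
        """Median |beta0 error| < 0.2 and per-axis loading r >= 0.9 over 10 sims."""
        b0_errs, load_ok = [], 0
        for seed in range(10):
            beta0, theta, u, alpha, phi = _sim_params(seed, n=150, m=25)
            cm = generate_from_gllvm(beta0, theta, u, alpha, phi, seed=seed + 2000)
            fit = fit_gllvm(cm, GLLVMConfig(seed=seed))
            b0_errs.append(np.median(np.abs(fit.beta0 - beta0)))
            _, aligned, _ = align_ordination(theta, fit.theta)
            load_ok += all(np.corrcoef(theta[:, a], aligned[:, a])[0, 1] >= 0.9
                           for a in range(2))
        assert np.median(b0_errs) < 0.2
        assert load_ok >= 9

    def test_serialization_round_trip(self, tmp_path, study_fit):
        path = study_fit.to_json(tmp_path / "fit.json")
        back = GLLVMFit.from_json(path)
        np.testing.assert_allclose(back.theta, study_fit.theta)
        np.testing.assert_allclose(back.phi, study_fit.phi)
        assert back.loglik == pytest.approx(study_fit.loglik)
        assert back.config == study_fit.config


class TestResiduals:
    @pytest.fixture(scope="class")
    def truth_fit(self):
        beta0, theta, u, alpha, phi = _sim_params(4, n=120, m=20)
        cm = generate_from_gllvm(beta0, theta, u, alpha, phi, seed=44)
        fit = GLLVMFit(alpha=alpha, beta0=beta0, theta=theta, u=u, phi=phi, loglik=0.0,
                       converged=True, n_iter=0, config=GLLVMConfig(seed=0))
        return fit, cm

    def test_well_specified_residuals_are_standard_normal(self, truth_fit):
        fit, cm = truth_fit
        rejects = sum(
            stats.kstest(residual_diagnostics(fit, cm, seed=rep).residuals.ravel(),
                         "norm").pvalue < 0.01
            for rep in range(100)
        )
        assert rejects <= 5

    def test_misspecified_mean_shifts_residuals(self, truth_fit):
        fit, cm = truth_fit
        bad = GLLVMFit(alpha=fit.alpha + np.log(10), beta0=fit.beta0, theta=fit.theta,
                       u=fit.u, phi=fit.phi, loglik=0.0, converged=True, n_iter=0,
                       config=fit.config)
        res = residual_diagnostics(bad, cm, seed=0)
        assert abs(res.residuals.mean()) > 1.0

    def test_deterministic_and_shape_checked(self, truth_fit):
        fit, cm = truth_fit
        r1 = residual_diagnostics(fit, cm, seed=9).residuals
        r2 = residual_diagnostics(fit, cm, seed=9).residuals
        np.testing.assert_array_equal(r1, r2)
        wrong = CommunityMatrix(cm.counts[:, :5], cm.sample_ids, cm.taxon_ids[:5])
        with pytest.raises(ValueError, match="data is"):
            residual_diagnostics(fit, wrong)


class TestAicAndAlignment:
    def test_aic_formula(self):
        cfg = GLLVMConfig(n_lv=2, row_effect="fixed")
        fit = GLLVMFit(alpha=np.zeros(120), beta0=np.zeros(36), theta=np.zeros((36, 2)),
                       u=np.zeros((120, 2)), phi=np.ones(36), loglik=-100.0,
                       converged=True, n_iter=0, config=cfg)
        assert model_aic(fit) == -2 * (-100.0) + 2 * 504 == 1208.0

    def test_aic_prefers_two_axes_on_modular_data(self, study):
        cm, _, _ = study
        a2 = model_aic(fit_gllvm(cm, GLLVMConfig(n_lv=2, seed=0)))
        a0 = model_aic(fit_gllvm(cm, GLLVMConfig(n_lv=0, seed=0)))
        assert a2 < a0

    def test_alignment_identity_and_reflection(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(20, 2))
        R, aligned, resid = align_ordination(ref, ref)
        np.testing.assert_allclose(R, np.eye(2), atol=1e-10)
        assert resid == pytest.approx(0.0, abs=1e-10)
        R, aligned, resid = align_ordination(ref, -ref)
        np.testing.assert_allclose(R, -np.eye(2), atol=1e-10)
        assert resid == pytest.approx(0.0, abs=1e-10)

    def test_alignment_beats_degree_grid_sweep(self):
        rng = np.random.default_rng(1)
        ref, tgt = rng.normal(size=(15, 2)), rng.normal(size=(15, 2))
        _, _, resid = align_ordination(ref, tgt)
        for deg in range(360):
            a = np.deg2rad(deg)
            Q = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            assert resid <= np.linalg.norm(tgt @ Q - ref) + 1e-9

    def test_alignment_shape_mismatch(self):
        with pytest.raises(ValueError):
            align_ordination(np.zeros((5, 2)), np.zeros((4, 2)))
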