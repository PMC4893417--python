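"""Maximum-likelihood covariance-structure estimation.

Includes a self-contained brute-force reference fitter for small
two-latent factor models: it assembles the implied covariance directly
from loading/covariance blocks (no RAM algebra) and minimises the ML
discrepancy with a derivative-free/numeric-gradient optimiser, sharing
no code path with the engine under test.
"""

import numpy as np
import pytest
from scipy import optimize

from akisem import synthetic_cohort as sc
from akisem.sem_engine import (CovEdge, PathEdge, SemModelSpec, build_ram,
                               fit_indices, fit_ml, implied_covariance,
                               modification_indices, respecify,
                               saturated_spec)


def one_factor_spec(p=3):
    return SemModelSpec(
        latents=("F",), observed=tuple(f"x{i}" for i in range(p)),
        paths=tuple(PathEdge("F", f"x{i}") for i in range(p)))


def two_latent_reference_fit(s_obs, n):
    """Independent brute-force ML fit of the 2-latent, 3+3-indicator CFA.

    theta = (l1..l3, l4..l6, phi, psi1..psi6); Sigma built blockwise.
    """
    p = 6

    def sigma_of(theta):
        l = theta[:6]
        phi = theta[6]
        psi = theta[7:]
        lam = np.zeros((6, 2))
        lam[:3, 0] = l[:3]
        lam[3:, 1] = l[3:]
        ph = np.array([[1.0, phi], [phi, 1.0]])
        return lam @ ph @ lam.T + np.diag(psi)

    _, logdet_s = np.linalg.slogdet(s_obs)

    def fml(theta):
        sig = sigma_of(theta)
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            return 1e6
        return logdet + np.trace(s_obs @ np.linalg.inv(sig)) - logdet_s - p

    theta0 = np.concatenate([np.full(6, 0.5), [0.0], np.full(6, 0.5)])
    res = optimize.minimize(fml, theta0, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    f_min = fml(res.x)
    chi2 = (n - 1) * f_min
    df = p * (p + 1) // 2 - len(theta0)
    rmsea = np.sqrt(max(chi2 - df, 0) / (df * (n - 1)))
    return res.x, f_min, chi2, rmsea


def two_latent_spec():
    obs = tuple(f"x{i}" for i in range(6))
    paths = tuple(PathEdge("F1", f"x{i}") for i in range(3))
    paths += tuple(PathEdge("F2", f"x{i}") for i in range(3, 6))
    return SemModelSpec(latents=("F1", "F2"), observed=obs, paths=paths,
                        covariances=(CovEdge("F1", "F2"),))


class TestImpliedCovariance:
    def test_null_model_identity(self):
        spec = SemModelSpec(latents=(), observed=("a", "b"), paths=())
        ram = build_ram(spec)
        sigma = implied_covariance(ram, np.array([1.0, 1.0]))
        np.testing.assert_allclose(sigma, np.eye(2))

    def test_single_factor_hand_algebra(self):
        spec = one_factor_spec(2)
        ram = build_ram(spec)
        theta = np.array([0.8, 0.7, 1 - 0.64, 1 - 0.49])
        sigma = implied_covariance(ram, theta)
        np.testing.assert_allclose(
            sigma, np.array([[1.0, 0.56], [0.56, 1.0]]), atol=1e-12)

    def test_singular_i_minus_a_rejected(self):
        spec = SemModelSpec(latents=(), observed=("a", "b"),
                            paths=(PathEdge("a", "b"), PathEdge("b", "a")))
        ram = build_ram(spec)
        with pytest.raises(ValueError, match="singular"):
            implied_covariance(ram, np.array([1.0, 1.0, 0.0, 0.0]))


class TestFitMl:
    def test_zero_discrepancy_recovery(self):
        spec = one_factor_spec()
        lam = np.array([0.8, 0.7, 0.6])
        sigma0 = np.outer(lam, lam)
        np.fill_diagonal(sigma0, 1.0)
        fit = fit_ml(spec, sigma0, 500, var_order=spec.observed)
        assert fit.f_min < 1e-8
        est = fit.estimates
        for i, l in enumerate(lam):
            assert est[f"F->x{i}"] == pytest.approx(l, abs=1e-4)

    def test_saturated_model(self):
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        fit = fit_ml(saturated_spec(("a", "b")), s, 100, var_order=("a", "b"))
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0

    def test_gradient_norm_at_optimum(self, big_cohort):
        _, _, matrix = big_cohort
        r = np.corrcoef(matrix.values, rowvar=False)
        fit = fit_ml(sc.infant_aki_spec(), r, 5000, var_order=matrix.variables)
        assert fit.grad_norm < 1e-5

    def test_standardized_invariant_to_rescaling(self, small_cohort):
        _, _, matrix = small_cohort
        spec = sc.infant_aki_spec()
        x = matrix.to_frame()
        s1 = np.cov(x.to_numpy(), rowvar=False)
        x2 = x.copy()
        x2["lactate_auc"] *= 7.3  # positive rescale of one observed variable
        s2 = np.cov(x2.to_numpy(), rowvar=False)
        f1 = fit_ml(spec, s1, 200, var_order=matrix.variables, compute_se=False)
        f2 = fit_ml(spec, s2, 200, var_order=matrix.variables, compute_se=False)
        std1, std2 = f1.standardized(), f2.standardized()
        for k in std1:
            assert std1[k] == pytest.approx(std2[k], abs=1e-6)

    def test_non_pd_input_rejected(self):
        s = np.ones((3, 3))
        with pytest.raises(ValueError, match="positive-definite"):
            fit_ml(one_factor_spec(), s, 100, var_order=("x0", "x1", "x2"))

    def test_heywood_flagged(self):
        # a correlation exceeding 1 in the factor metric forces psi < 0
        r = np.array([[1.0, 0.8, 0.6],
                      [0.8, 1.0, 0.3],
                      [0.6, 0.3, 1.0]])
        with pytest.warns(UserWarning, match="Heywood"):
            fit = fit_ml(one_factor_spec(), r, 200, var_order=("x0", "x1", "x2"))
        assert fit.heywood


class TestFitIndices:
    def test_chi2_equal_df_gives_zero_rmsea(self):
        out = fit_indices(50.0, 50, 201, 500.0, 55, np.eye(3), np.eye(3))
        assert out["rmsea"] == 0.0

    def test_perfect_fit_indices(self):
        out = fit_indices(0.0, 5, 201, 400.0, 10, np.eye(3), np.eye(3))
        assert out["nfi"] == pytest.approx(1.0)
        assert out["gfi"] == pytest.approx(1.0)

    def test_rmsea_formula(self):
        out = fit_indices(100.0, 50, 201, 800.0, 60, np.eye(3), np.eye(3))
        assert out["rmsea"] == pytest.approx(np.sqrt(50.0 / 10000.0), rel=1e-12)

    def test_bic_negative_for_good_overidentified_fit(self):
        out = fit_indices(40.0, 56, 200, 900.0, 78, np.eye(3), np.eye(3))
        assert out["bic"] == pytest.approx(40.0 - 56 * np.log(200))
        assert out["bic"] < 0

    def test_df_zero_flagged(self):
        out = fit_indices(0.0, 0, 100, 10.0, 3, np.eye(2), np.eye(2))
        assert out["rmsea"] == 0.0 and out["rmsea_undefined"]


class TestReferenceImplementationAgreement:
    def test_estimates_chi2_rmsea_match_brute_force(self):
        """Ten random two-latent models: engine vs independent fitter."""
        rng = np.random.default_rng(12)
        spec = two_latent_spec()
        for trial in range(10):
            lam = rng.uniform(0.55, 0.9, size=6)
            phi = rng.uniform(-0.6, 0.6)
            psi = 1.0 - lam**2
            lam_m = np.zeros((6, 2))
            lam_m[:3, 0], lam_m[3:, 1] = lam[:3], lam[3:]
            sigma = lam_m @ np.array([[1, phi], [phi, 1]]) @ lam_m.T + np.diag(psi)
            x = rng.multivariate_normal(np.zeros(6), sigma, size=500)
            s = np.cov(x, rowvar=False)

            fit = fit_ml(spec, s, 500, var_order=spec.observed,
                         compute_se=False)
            ref_theta, ref_f, ref_chi2, ref_rmsea = two_latent_reference_fit(s, 500)

            # align: engine order is loadings (6), phi, then variances
            est = fit.estimates
            mine = np.array(
                [est[f"F1->x{i}"] for i in range(3)]
                + [est[f"F2->x{i}"] for i in range(3, 6)]
                + [est["F1<->F2"]]
                + [est[f"var(x{i})"] for i in range(6)])
            ref = ref_theta.copy()
            # sign indeterminacy per factor
            for block, pcol in (((0, 3), 6), ((3, 6), 6)):
                if ref[block[0]] * mine[block[0]] < 0:
                    ref[block[0]:block[1]] *= -1
                    ref[6] *= -1
            assert np.abs(mine - ref).max() < 1e-3, f"trial {trial}"
            assert fit.chi2 == pytest.approx(ref_chi2, abs=1e-3)
            assert fit.indices["rmsea"] == pytest.approx(ref_rmsea, abs=1e-3)


class TestModificationIndices:
    def test_null_candidate_small(self):
        hits = 0
        for seed in range(10):
            cfg = sc.CohortConfig(n_patients=1000, seed=400 + seed,
                                  mortality_mode="propensity")
            m = sc.simulate_indicators(sc.simulate_latents(cfg), cfg)
            r = np.corrcoef(m.values, rowvar=False)
            fit = fit_ml(sc.infant_aki_spec(), r, 1000,
                         var_order=m.variables, compute_se=False)
            mi = modification_indices(
                fit, [("cov", "crossclamp_duration", "lactate_auc")])
            hits += mi["crossclamp_duration<->lactate_auc"] < 3.84
        assert hits >= 9

    def test_chi2_drop_approximates_mi(self):
        cfg = sc.CohortConfig(n_patients=2000, seed=200,
                              mortality_mode="propensity")
        m = sc.simulate_indicators(sc.simulate_latents(cfg), cfg)
        r = np.corrcoef(m.values, rowvar=False)
        base = sc.infant_aki_spec(residual_covariances=False)
        fit = fit_ml(base, r, 2000, var_order=m.variables, compute_se=False)
        mi = modification_indices(fit, [("cov", "mortality", "dscr50_auc")])
        val = mi["mortality<->dscr50_auc"]
        from dataclasses import replace

        trial = replace(base, covariances=(CovEdge("mortality", "dscr50_auc"),))
        fit2 = fit_ml(trial, r, 2000, var_order=m.variables, compute_se=False)
        drop = fit.chi2 - fit2.chi2
        assert drop == pytest.approx(val, rel=0.3)

    def test_already_free_candidate_rejected(self, small_cohort):
        _, _, matrix = small_cohort
        r = np.corrcoef(matrix.values, rowvar=False)
        fit = fit_ml(sc.infant_aki_spec(), r, 200, var_order=matrix.variables,
                     compute_se=False)
        with pytest.raises(ValueError, match="already"):
            modification_indices(fit, [("cov", "cpb_duration", "ungal_auc")])


class TestRespecify:
    def test_empty_pool_unchanged(self, small_cohort):
        _, _, matrix = small_cohort
        r = np.corrcoef(matrix.values, rowvar=False)
        spec = sc.infant_aki_spec()
        final, log = respecify(spec, r, 200, [])
        assert final == spec and log == []

    def test_no_improvement_stops_immediately(self):
        # data generated WITHOUT arcs; the model already fits
        cfg = sc.CohortConfig(n_patients=2000, seed=77,
                              residual_correlations={},
                              mortality_mode="propensity")
        m = sc.simulate_indicators(sc.simulate_latents(cfg), cfg)
        r = np.corrcoef(m.values, rowvar=False)
        spec = sc.infant_aki_spec(residual_covariances=False)
        final, log = respecify(spec, r, 2000,
                               [("cov", "age", "ungal_auc"),
                                ("cov", "icu_days", "lactate_auc")])
        assert len(final.covariances) <= 1
        if log:
            assert not log[-1]["kept"]

    def test_detectable_arc_recovered(self):
        cfg = sc.CohortConfig(n_patients=2000, seed=88,
                              mortality_mode="propensity")
        m = sc.simulate_indicators(sc.simulate_latents(cfg), cfg)
        r = np.corrcoef(m.values, rowvar=False)
        base = sc.infant_aki_spec(residual_covariances=False)
        final, log = respecify(base, r, 2000,
                               [("cov", "mortality", "dscr50_auc"),
                                ("cov", "age", "crossclamp_duration")])
        names = {frozenset((c.a, c.b)) for c in final.covariances}
        assert frozenset(("mortality", "dscr50_auc")) in names
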