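"""Implied covariance, the variance stage, its SEs, and systemwide DWLS."""

import copy

import numpy as np
import pytest

from miivkit import (build_moment_matrix, estimate_upsilon, find_miivs,
                     fit_full_dwls, fit_function, fit_theta1, fit_theta2,
                     implied_sigma, l2o_transform, parse_model, se_theta2,
                     select_miivs, sigma_jacobians)
from miivkit.moments import MixedMoments
from miivkit.simulate import (generate_dataset, model_syntax,
                              population_moments, simulation_truth,
                              true_parameter_values)
from miivkit.sysfit import sigma_free_vector, weight_matrix


def _truth_split(model, truth=None):
    tv = true_parameter_values(model, truth)
    t1 = np.array([tv[k] for k in model.theta1_names()])
    t2 = np.array([tv[k] for k in model.theta2_names()])
    return t1, t2


@pytest.fixture(scope="module")
def sim_model():
    truth = simulation_truth()
    model = parse_model(model_syntax("correct", "high"), truth.types)
    return truth, model


class TestImpliedSigma:
    def test_cfa_reduction_without_structural_part(self):
        types = {f"y{i}": "continuous" for i in range(1, 7)}
        model = parse_model("f1 =~ y1 + y2 + y3\nf2 =~ y4 + y5 + y6", types)
        t1 = {"l_y2~f1": 0.8, "l_y3~f1": 0.7, "l_y5~f2": 0.9, "l_y6~f2": 0.6}
        t2 = {"psi_f1~~f1": 1.0, "psi_f2~~f2": 1.2, "psi_f2~~f1": 0.4}
        t2.update({f"theta_y{i}~~y{i}": 0.5 for i in range(1, 7)})
        Sigma, hey = implied_sigma(t1, t2, model)
        Lam = np.zeros((6, 2))
        Lam[:3, 0] = [1, 0.8, 0.7]
        Lam[3:, 1] = [1, 0.9, 0.6]
        Psi = np.array([[1.0, 0.4], [0.4, 1.2]])
        assert np.allclose(Sigma, Lam @ Psi @ Lam.T + 0.5 * np.eye(6), atol=1e-12)
        assert not hey

    def test_unit_diagonal_for_ordinal_indicators_at_truth(self, sim_model):
        truth, model = sim_model
        t1, t2 = _truth_split(model, truth)
        Sigma, hey = implied_sigma(t1, t2, model)
        for i, y in enumerate(model.indicators):
            if model.is_discrete(y):
                assert Sigma[i, i] == pytest.approx(1.0, abs=1e-12)
        assert not hey

    def test_heywood_flagged_when_common_part_exceeds_one(self, sim_model):
        truth, model = sim_model
        t1, t2 = _truth_split(model, truth)
        t2 = dict(zip(model.theta2_names(), t2))
        t2["psi_eta2~~eta2"] = 3.0       # ordinal-factor variance too large
        _, hey = implied_sigma(t1, t2, model)
        assert hey

    def test_underlying_sample_covariance_matches_truth(self):
        truth = simulation_truth()
        _, _, ystar = generate_dataset(400_000, 97, truth, return_underlying=True)
        S = np.cov(ystar, rowvar=False, bias=True)
        assert np.abs(S - truth.implied_cov).max() < 0.01


class TestFitFunction:
    def test_zero_at_perfect_fit_and_uls_norm(self, sim_model):
        truth, model = sim_model
        pm = population_moments(truth)
        t1, t2 = _truth_split(model, truth)
        assert fit_function(t1, t2, model, pm, "uls") == pytest.approx(0.0, abs=1e-20)
        t2b = t2 + 0.01
        Sigma, _ = implied_sigma(t1, t2b, model, order=pm.names)
        r = pm.s - sigma_free_vector(pm, Sigma)
        assert fit_function(t1, t2b, model, pm, "uls") == pytest.approx(r @ r)

    def test_dwls_is_elementwise_weighted_sum(self, sim_model):
        truth, model = sim_model
        frame, types = generate_dataset(300, 101, truth)
        mom = build_moment_matrix(frame, types)
        estimate_upsilon(frame, mom, "score_sandwich")
        t1, t2 = _truth_split(model, truth)
        Sigma, _ = implied_sigma(t1, t2, model, order=mom.names)
        r = mom.s - sigma_free_vector(mom, Sigma)
        oracle = np.sum(r ** 2 / np.diag(mom.upsilon))
        assert fit_function(t1, t2, model, mom, "dwls") == pytest.approx(oracle)

    def test_weight_requires_upsilon(self, sim_model):
        truth, model = sim_model
        pm = population_moments(truth)
        t1, t2 = _truth_split(model, truth)
        with pytest.raises(ValueError, match="Upsilon"):
            fit_function(t1, t2, model, pm, "dwls")


class TestSigmaJacobians:
    def test_matches_finite_differences(self, sim_model):
        truth, model = sim_model
        pm = population_moments(truth)
        t1, t2 = _truth_split(model, truth)
        J, J1, J2 = sigma_jacobians(t1, t2, model, pm)
        names1, names2 = model.theta1_names(), model.theta2_names()
        assert J1.shape[1] == len(names1) and J2.shape[1] == len(names2)
        h = 1e-6

        def sigma_vec(t1v, t2v):
            S, _ = implied_sigma(t1v, t2v, model, order=pm.names)
            return sigma_free_vector(pm, S)

        full = np.concatenate([t1, t2])
        for c in range(len(full)):
            xp, xm = full.copy(), full.copy()
            xp[c] += h
            xm[c] -= h
            fd = (sigma_vec(xp[:len(t1)], xp[len(t1):])
                  - sigma_vec(xm[:len(t1)], xm[len(t1):])) / (2 * h)
            scale = max(np.abs(fd).max(), 1.0)
            assert np.abs(J[:, c] - fd).max() / scale < 1e-6

    def test_discrete_diagonal_rows_excluded_from_sigma_vector(self, sim_model):
        truth, model = sim_model
        pm = population_moments(truth)
        entries = pm.free_entries()
        for i, j in entries:
            if i == j:
                assert not pm.is_discrete(pm.names[i])


class TestFitTheta2:
    def test_exact_recovery_at_population_moments(self, sim_model):
        truth, model = sim_model
        pm = population_moments(truth)
        pm.n = 1000
        t1, t2_true = _truth_split(model, truth)
        full = fit_theta2(t1, pm, model, weight="uls")
        assert full.converged
        assert np.abs(full.theta2 - t2_true).max() < 1e-6
        assert full.T == pytest.approx(0.0, abs=1e-16)
        assert full.proper

    def test_minimizer_beats_any_perturbation(self, sim_model):
        truth, model = sim_model
        frame, types = generate_dataset(500, 103, truth)
        mom = build_moment_matrix(frame, types)
        estimate_upsilon(frame, mom, "score_sandwich")
        t1, _ = _truth_split(model, truth)
        full = fit_theta2(t1, mom, model, weight="dwls")
        rng = np.random.default_rng(0)
        for _ in range(5):
            pert = full.theta2 + rng.normal(scale=0.02, size=full.theta2.shape)
            assert full.T <= fit_function(t1, pert, model, mom, "dwls") + 1e-12

    def test_proper_flag_reflects_pd_rule(self, sim_model):
        truth, model = sim_model
        frame, types = generate_dataset(800, 107, truth)
        mom = build_moment_matrix(frame, types)
        estimate_upsilon(frame, mom, "score_sandwich")
        t1, _ = _truth_split(model, truth)
        full = fit_theta2(t1, mom, model, weight="dwls")
        assert full.proper == (full.converged and full.psi_pd and full.theta_pd)


class TestSeTheta2:
    def _setup(self, n=800, seed=109):
        truth = simulation_truth()
        model = parse_model(model_syntax("correct", "high"), truth.types)
        frame, types = generate_dataset(n, seed, truth)
        mom = build_moment_matrix(frame, types)
        ups = estimate_upsilon(frame, mom, "score_sandwich")
        eqs = l2o_transform(model)
        for eq in eqs:
            find_miivs(model, eq)
            select_miivs(eq, mom, strategy="all")
        res = fit_theta1(mom, eqs, ups)
        full = fit_theta2(res.theta1, mom, model, weight="dwls")
        return model, mom, ups, res, full

    def test_uls_weight_gives_ordinary_least_squares_h(self):
        model, mom, ups, res, _ = self._setup()
        full = fit_theta2(res.theta1, mom, model, weight="uls")
        J2 = full.J2
        H = np.linalg.solve(J2.T @ J2, J2.T)
        from miivkit.sysfit import c_matrix
        C = c_matrix(full, res.K_stacked)
        oracle = H @ (np.eye(J2.shape[0]) - full.J1 @ res.K_stacked)
        assert np.allclose(C, oracle, atol=1e-10)

    def test_invariant_to_scalar_weight_multiple(self):
        model, mom, ups, res, full = self._setup()
        se_a = se_theta2(full, res.K_stacked, ups).copy()
        scaled = copy.deepcopy(full)
        scaled.W = 7.5 * scaled.W
        se_b = se_theta2(scaled, res.K_stacked, ups)
        assert np.allclose(se_a, se_b, rtol=1e-10)

    def test_no_first_stage_reduces_to_classical_delta_form(self):
        model, mom, ups, res, full = self._setup()
        K0 = np.zeros_like(res.K_stacked)
        from miivkit.sysfit import c_matrix
        C = c_matrix(full, K0)
        W, J2 = full.W, full.J2
        H = np.linalg.solve(J2.T @ W @ J2, J2.T @ W)
        assert np.allclose(C, H, atol=1e-12)


class TestFullDwls:
    def test_exact_recovery_at_population_moments(self, sim_model):
        truth, model = sim_model
        pm = population_moments(truth)
        pm.n = 1000
        full = fit_full_dwls(model, pm, weight="uls")
        t1, t2 = _truth_split(model, truth)
        assert full.converged
        assert np.abs(full.theta1 - t1).max() < 1e-6
        assert np.abs(full.theta2 - t2).max() < 1e-6

    def test_consistency_at_large_n(self, sim_model):
        truth, model = sim_model
        frame, types = generate_dataset(100_000, 113, truth)
        mom = build_moment_matrix(frame, types)
        estimate_upsilon(frame, mom, "score_sandwich")
        full = fit_full_dwls(model, mom)
        t1, t2 = _truth_split(model, truth)
        assert full.converged
        assert np.abs(np.concatenate([full.theta1, full.theta2])
                      - np.concatenate([t1, t2])).max() < 0.02

    def test_misspecification_spreads_bias_to_clean_equations(self):
        # probability limits: fit the misspecified model to the population
        # moments.  The eta5 equation is correctly specified and its MIIV
        # estimator is exactly unbiased there, yet systemwide estimation
        # shifts its coefficients; the directly misspecified eta4 equation
        # carries large bias.
        truth = simulation_truth()
        pm = population_moments(truth)
        pm.n = 1000
        model_m = parse_model(model_syntax("misspecified", "high"), truth.types)
        full = fit_full_dwls(model_m, pm, weight="uls")
        tv = true_parameter_values(model_m, truth)
        names = model_m.theta1_names()
        est = dict(zip(names, full.theta1))
        eta4 = [n for n in names if n.startswith("b_eta4")]
        eta5 = [n for n in names if n.startswith("b_eta5")]
        assert max(abs(est[n] - tv[n]) / abs(tv[n]) for n in eta4) > 0.5
        sys_bias = max(abs(est[n] - tv[n]) / abs(tv[n]) for n in eta5)
        assert sys_bias > 0.01
        eqs = l2o_transform(model_m)
        from miivkit import find_miivs, fit_theta1, select_miivs
        for eq in eqs:
            find_miivs(model_m, eq)
            select_miivs(eq, strategy="all")
        res = fit_theta1(pm, eqs)
        miiv = {nm: v for f in res.equations
                for nm, v in zip(f.equation.param_names, f.theta1)}
        miiv_bias = max(abs(miiv[n] - tv[n]) / abs(tv[n]) for n in eta5)
        assert miiv_bias < 1e-8 < sys_bias
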