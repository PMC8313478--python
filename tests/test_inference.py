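"""Model chi-square adjustments and the overidentification test family."""

import numpy as np
import pytest

from miivkit import (build_moment_matrix, corollary_check, estimate_upsilon,
                     find_miivs, fit_theta1, fit_theta2, l2o_transform,
                     overid_adjusted, overid_chi2, parse_model, sargan_test,
                     select_miivs, se_theta2, equation_test_report)
from miivkit.estimate import omega_matrix
from miivkit.inference import (_q_matrix, _sqrt_and_invsqrt, model_fit_tests,
                               model_degrees_of_freedom)
from miivkit.moments import MixedMoments
from miivkit.simulate import (generate_dataset, model_syntax,
                              population_moments, simulation_truth)

from conftest import EMPIRICAL_SYNTAX, EMPIRICAL_SYNTAX_CROSS, EMPIRICAL_TYPES


class TestModelDegreesOfFreedom:
    def test_mediation_model_df(self, empirical_models):
        base, cross = empirical_models
        assert model_degrees_of_freedom(base) == 50
        assert model_degrees_of_freedom(cross) == 49


class TestModelFitTests:
    def _fit(self, n=600, seed=131):
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
        return model, mom, res, full

    def test_statistics_and_reference_distributions(self):
        model, mom, res, full = self._fit()
        mt = model_fit_tests(full, mom, K_stacked=res.K_stacked)
        r = model_degrees_of_freedom(model)
        assert mt.df_mean == r
        assert mt.T_m == pytest.approx(mom.n * r * full.T / mt.trace_M)
        assert mt.T_mv == pytest.approx(mom.n * mt.trace_M / mt.trace_M2 * full.T)
        assert mt.df_mv == pytest.approx(mt.trace_M ** 2 / mt.trace_M2)
        assert 0 <= mt.p_m <= 1 and 0 <= mt.p_mv <= 1
        assert mt.T >= 0

    def test_m_matrix_eigenvalues_nonnegative(self):
        model, mom, res, full = self._fit(seed=137)
        ups_half, _ = _sqrt_and_invsqrt(mom.upsilon)
        import miivkit.sysfit as sf
        J = np.hstack([full.J1, full.J2])
        D = np.vstack([res.K_stacked, sf.c_matrix(full, res.K_stacked)])
        bracket = np.eye(J.shape[0]) - J @ D
        M = ups_half @ bracket.T @ full.W @ bracket @ ups_half
        w = np.linalg.eigvalsh((M + M.T) / 2)
        assert w.min() >= -1e-8 * w.max()


def _continuous_fit(cont_setup):
    _, _, _, eqs, moments, ups = cont_setup
    return fit_theta1(moments, eqs, ups), moments, ups


class TestEquationTests:
    def test_just_identified_equation_reported_na(self, cont_setup):
        import copy
        _, _, _, eqs, moments, ups = cont_setup
        eq = copy.deepcopy(eqs[0])
        eq.miivs = list(eq.rhs)
        res = fit_theta1(moments, [eq], ups)
        stat, df, p = sargan_test(moments, res.equations[0])
        assert np.isnan(stat) and df == 0
        stat, _, _ = overid_chi2(moments, res.equations[0], ups)
        assert np.isnan(stat)

    def test_sargan_equals_raw_data_residual_form(self, cont_setup):
        data, _, _, eqs, moments, ups = cont_setup
        res, n = fit_theta1(moments, eqs, ups), moments.n
        Xc = data.to_numpy() - data.to_numpy().mean(axis=0)
        cols = {c: i for i, c in enumerate(data.columns)}
        for f in res.equations:
            stat, df, _ = sargan_test(moments, f)
            y = Xc[:, cols[f.equation.lhs]]
            Z = Xc[:, [cols[c] for c in f.equation.rhs]]
            V = Xc[:, [cols[c] for c in f.equation.miivs]]
            e = y - Z @ f.theta1
            PV = V @ np.linalg.solve(V.T @ V, V.T)
            oracle = (e @ PV @ e) / (e @ e / n)
            assert stat == pytest.approx(oracle, abs=1e-10)
            assert df == f.df_overid

    def test_q_matrix_idempotent(self, cont_setup):
        res, moments, ups = _continuous_fit(cont_setup)
        for f in res.equations:
            Om = omega_matrix(moments, f, ups, "hat")
            half, invhalf = _sqrt_and_invsqrt(Om)
            Q = _q_matrix(moments, f, half, invhalf)
            assert np.abs(Q @ Q - Q).max() < 1e-8

    def test_classic_omega_reproduces_sargan_exactly(self, cont_setup):
        res, moments, ups = _continuous_fit(cont_setup)
        for f in res.equations:
            s0, _, _ = sargan_test(moments, f)
            sc, _, _ = overid_chi2(moments, f, ups, "classic")
            assert sc == pytest.approx(s0, abs=1e-10)

    def test_all_seven_statistics_coincide_on_normal_theory_continuous(self, cont_setup):
        # F~ = F_Sargan exactly; adjusted tilde variants likewise; the hat
        # variants differ only by the g g' term, vanishing at the population
        res, moments, ups = _continuous_fit(cont_setup)
        for f in res.equations:
            s0, _, _ = sargan_test(moments, f)
            ft, _, _ = overid_chi2(moments, f, ups, "tilde")
            fm, _, _ = overid_adjusted(moments, f, ups, "m", "tilde")
            fmv, _, _ = overid_adjusted(moments, f, ups, "mv", "tilde")
            assert ft == pytest.approx(s0, abs=1e-10)
            assert fm == pytest.approx(s0, abs=1e-8)
            assert fmv == pytest.approx(s0, abs=1e-8)

    def test_fm_equals_sargan_at_continuous_population(self):
        # Pi = Q idempotent at the population: tr(Pi) = L - K
        truth = simulation_truth()
        names = [v for v in truth.indicator_names if truth.types[v] == "continuous"]
        idx = [truth.indicator_names.index(v) for v in names]
        pm = MixedMoments(names=names, types={v: "continuous" for v in names},
                          S=truth.implied_cov[np.ix_(idx, idx)].copy(), n=800)
        model = parse_model(
            "eta1 =~ y1 + y2 + y3\neta3 =~ y7 + y8 + y9\neta5 =~ y13 + y14 + y15",
            {v: "continuous" for v in names})
        eqs = l2o_transform(model)
        for eq in eqs:
            find_miivs(model, eq)
            select_miivs(eq, strategy="all")
        from miivkit.asycov import _upsilon_normal
        ups = _upsilon_normal(pm)
        res = fit_theta1(pm, eqs, ups)
        for f in res.equations:
            from miivkit.inference import _pi_matrix
            Pi = _pi_matrix(pm, f, ups, "hat")
            assert np.trace(Pi) == pytest.approx(f.df_overid, abs=1e-8)

    def test_mv_df_recomputed_from_pi_traces(self, cont_setup):
        res, moments, ups = _continuous_fit(cont_setup)
        from miivkit.inference import _pi_matrix
        for f in res.equations:
            _, df, _ = overid_adjusted(moments, f, ups, "mv", "hat")
            Pi = _pi_matrix(moments, f, ups, "hat")
            assert df == pytest.approx(np.trace(Pi) ** 2 / np.trace(Pi @ Pi))

    def test_report_collects_all_statistics_with_bonferroni(self, cont_setup):
        res, moments, ups = _continuous_fit(cont_setup)
        report = equation_test_report(res, ups)
        assert report.n_overidentified == 3
        assert report.significance_threshold() == pytest.approx(0.05 / 3)
        frame = report.to_frame()
        assert set(frame["test"]) == {"F_sargan", "F", "F_tilde", "F_m",
                                      "F_tilde_m", "F_mv", "F_tilde_mv"}
        assert ((frame["p_value"].dropna() >= 0) & (frame["p_value"].dropna() <= 1)).all()


ORDINAL_4 = "f =~ y1 + y2 + y3 + y4"


def _ordinal_population(n=800):
    lam = np.array([0.8, 0.7, 0.65, 0.55])
    S = np.outer(lam, lam)
    np.fill_diagonal(S, 1.0)
    tau = {f"y{i}": np.array([-1.75, -1.34, -0.52, 0.71]) for i in range(1, 5)}
    names = [f"y{i}" for i in range(1, 5)]
    return MixedMoments(names=names, types={v: "ordinal" for v in names},
                        S=S, thresholds=tau, n=n)


class TestCorollary:
    def test_traces_agree_at_ordinal_population(self):
        pm = _ordinal_population()
        model = parse_model(ORDINAL_4, {v: "ordinal" for v in pm.names})
        eqs = l2o_transform(model)
        for eq in eqs:
            find_miivs(model, eq)
            select_miivs(eq, strategy="all")
        rng = np.random.default_rng(139)
        A = rng.normal(size=(len(pm.free_entries()),) * 2)
        ups = A @ A.T                      # the identity holds for any PSD Upsilon
        res = fit_theta1(pm, eqs, ups)
        for f in res.equations:
            out = corollary_check(pm, f, ups)
            assert np.abs(f.g).max() < 1e-12
            assert out["trace_delta"] == pytest.approx(out["trace_pi"], abs=1e-8)
            assert out["trace_delta2"] == pytest.approx(out["trace_pi2"], abs=1e-8)

    def test_finite_sample_trace_gap_shrinks_with_n(self):
        truth = simulation_truth()
        model = parse_model("eta2 =~ y4 + y5 + y6\neta4 =~ y10 + y11 + y12",
                            truth.types)
        gaps = []
        for n in (200, 800, 3200):
            reps = []
            for rep in range(40):
                frame, types = generate_dataset(n, 1000 * n + rep, truth)
                sub = frame[model.indicators]
                sub_types = {v: types[v] for v in model.indicators}
                mom = build_moment_matrix(sub, sub_types)
                ups = estimate_upsilon(sub, mom, "score_sandwich")
                eqs = l2o_transform(model)
                for eq in eqs:
                    find_miivs(model, eq)
                    select_miivs(eq, strategy="all")
                res = fit_theta1(mom, eqs, ups)
                f = res.equations[0]
                out = corollary_check(mom, f, ups)
                reps.append(abs(out["trace_delta"] - out["trace_pi"]))
            gaps.append(np.median(reps))
        assert gaps[0] > gaps[1] > gaps[2]


class TestMisspecifiedPower:
    def test_rejection_grows_with_n_for_contaminated_equations(self):
        # under the omitted-path model the eta3/eta4 equation tests gain
        # power with n while the clean eta5 equation stays near the level
        truth = simulation_truth()
        model = parse_model(model_syntax("misspecified", "high"), truth.types)
        eq_template = l2o_transform(model)
        for eq in eq_template:
            find_miivs(model, eq)
        rates = {}
        for n in (400, 3200):
            rej = {"y7": [], "y10": [], "y13": []}
            for rep in range(50):
                import copy
                frame, types = generate_dataset(n, 555000 + 97 * rep + n, truth)
                mom = build_moment_matrix(frame, types)
                ups = estimate_upsilon(frame, mom, "score_sandwich")
                eqs = copy.deepcopy(eq_template)
                for eq in eqs:
                    select_miivs(eq, mom, strategy="all")
                res = fit_theta1(mom, eqs, ups)
                for f in res.equations:
                    if f.equation.lhs in rej and f.theta1 is not None:
                        stat, df, p = overid_chi2(mom, f, ups, "hat")
                        rej[f.equation.lhs].append(p < 0.05)
            rates[n] = {k: np.mean(v) for k, v in rej.items()}
        assert rates[3200]["y7"] > rates[400]["y7"]
        assert rates[3200]["y10"] > rates[400]["y10"]
        assert rates[3200]["y10"] > 0.5
        assert rates[3200]["y13"] < 0.25
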