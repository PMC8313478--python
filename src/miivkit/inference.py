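"""Goodness-of-fit tests for the model and overidentification tests per equation.

The model-level statistic n T(theta-hat) is asymptotically a weighted sum
of 1-df chi-squares; the weights are the eigenvalues of the M matrix built
from the fit-function weight, the sigma jacobian, and the estimator's
influence matrices.  Satorra-Bentler mean (T_m) and mean-variance (T_mv)
adjustments refer the rescaled statistic to chi-square distributions with
df r and tr(M)^2/tr(M^2) respectively.

Per overidentified equation, the suite comprises the naive Sargan
chi-square, the generalized-Wald statistics F / F-tilde (Omega-hat or
Omega-tilde weighting with a Moore-Penrose inverse of the idempotent QQ'),
and Satorra-Bentler mean and mean-variance adjusted versions F_m, F_mv,
F~_m, F~_mv driven by the trace of the Pi matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import EquationFit, Theta1Result, omega_matrix, _eq_blocks
from .moments import MixedMoments
from .sysfit import FullFitResult, c_matrix

MP_RTOL = 1e-10


def _sqrt_and_invsqrt(M: np.ndarray):
    """Symmetric square root and pseudo-inverse square root via eigendecomposition.

    Negative eigenvalues from sampling noise are clipped at zero.
    """
    Ms = (M + M.T) / 2.0
    w, V = np.linalg.eigh(Ms)
    w = np.clip(w, 0.0, None)
    tol = MP_RTOL * max(w.max(), 1e-300)
    root = (V * np.sqrt(w)) @ V.T
    inv_w = np.where(w > tol, 1.0 / np.sqrt(np.where(w > tol, w, 1.0)), 0.0)
    inv_root = (V * inv_w) @ V.T
    return root, inv_root


# ---------------------------------------------------------------------- #
#  Model-level tests
# ---------------------------------------------------------------------- #

@dataclass
class ModelTests:
    T: float
    df_mean: float
    T_m: float
    p_m: float
    df_mv: float
    T_mv: float
    p_mv: float
    trace_M: float
    trace_M2: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("T", "T_m", "df_mean", "p_m", "T_mv", "df_mv", "p_mv")}


def model_fit_tests(full: FullFitResult, moments: MixedMoments,
                    K_stacked: np.ndarray | None = None,
                    upsilon: np.ndarray | None = None) -> ModelTests:
    """Mean-scaled and mean-variance adjusted model chi-square statistics.

    For the MIIV estimator the influence matrix stacks K (first stage) over
    C (second stage); for the systemwide estimator it is the one-step
    weighted least-squares influence (J'WJ)^-1 J'W.
    """
    if upsilon is None:
        upsilon = moments.upsilon
    if upsilon is None:
        raise ValueError("Upsilon required for model fit tests")
    J = np.hstack([full.J1, full.J2])
    W = full.W
    if full.systemwide:
        D = np.linalg.solve(J.T @ W @ J, J.T @ W)
    else:
        if K_stacked is None:
            raise ValueError("K_stacked required for the MIIV model test")
        D = np.vstack([K_stacked, c_matrix(full, K_stacked)])
    m = J.shape[0]
    bracket = np.eye(m) - J @ D
    ups_half, _ = _sqrt_and_invsqrt(upsilon)
    M = ups_half @ bracket.T @ W @ bracket @ ups_half
    trM = float(np.trace(M))
    trM2 = float(np.trace(M @ M))
    if trM <= 0:
        raise ValueError("trace of the M matrix is not positive")
    r = m - (len(full.theta1_names) + len(full.theta2_names))
    n = moments.n
    T = full.T
    T_m = n * r * T / trM
    T_mv = n * trM / trM2 * T
    df_mv = trM * trM / trM2
    return ModelTests(T=T, df_mean=float(r), T_m=T_m,
                      p_m=float(stats.chi2.sf(T_m, r)),
                      df_mv=df_mv, T_mv=T_mv,
                      p_mv=float(stats.chi2.sf(T_mv, df_mv)),
                      trace_M=trM, trace_M2=trM2)


def model_degrees_of_freedom(model, moments_or_p=None) -> int:
    """r = number of nonredundant free moment entries minus free parameters.

    Computable from the model specification alone: the free moment entries
    are p(p-1)/2 off-diagonals plus one variance per continuous indicator.
    """
    p = len(model.indicators)
    n_cont = sum(1 for y in model.indicators if not model.is_discrete(y))
    n_moments = p * (p - 1) // 2 + n_cont
    return n_moments - model.n_free_params()


# ---------------------------------------------------------------------- #
#  Equation-level tests
# ---------------------------------------------------------------------- #

def sargan_test(moments: MixedMoments, fit: EquationFit):
    """Naive Sargan chi-square in moment form; NA for just-identified equations."""
    if fit.df_overid <= 0:
        return np.nan, 0, np.nan
    S_vv = moments.block(fit.equation.miivs, fit.equation.miivs)
    stat = moments.n * fit.g @ np.linalg.solve(S_vv, fit.g) / fit.phi2
    df = fit.df_overid
    return float(stat), df, float(stats.chi2.sf(stat, df))


def _q_matrix(moments, fit, om_half, om_invhalf):
    S_vv, S_vz, *_ = _eq_blocks(moments, fit.equation)
    Vinv = np.linalg.inv(S_vv)
    P = np.linalg.inv(S_vz.T @ Vinv @ S_vz)
    L = len(fit.equation.miivs)
    return np.eye(L) - om_invhalf @ S_vz @ P @ S_vz.T @ Vinv @ om_half


def overid_chi2(moments: MixedMoments, fit: EquationFit,
                upsilon: np.ndarray | None = None, omega_variant: str = "hat"):
    """Generalized-Wald overidentification statistic F (or F-tilde).

    With the classic Omega = phi^2 S_vv the statistic equals the Sargan
    chi-square at any sample size.
    """
    if fit.df_overid <= 0:
        return np.nan, 0, np.nan
    Om = omega_matrix(moments, fit, upsilon, omega_variant)
    om_half, om_invhalf = _sqrt_and_invsqrt(Om)
    Q = _q_matrix(moments, fit, om_half, om_invhalf)
    G = np.linalg.pinv(Q @ Q.T, rcond=MP_RTOL)
    u = om_invhalf @ fit.g
    stat = moments.n * u @ G @ u
    df = fit.df_overid
    return float(stat), df, float(stats.chi2.sf(stat, df))


def _pi_matrix(moments, fit, upsilon, omega_variant):
    Om = omega_matrix(moments, fit, upsilon, omega_variant)
    om_half, _ = _sqrt_and_invsqrt(Om)
    S_vv, S_vz, *_ = _eq_blocks(moments, fit.equation)
    Vinv = np.linalg.inv(S_vv)
    P = np.linalg.inv(S_vz.T @ Vinv @ S_vz)
    R = Vinv - Vinv @ S_vz @ P @ S_vz.T @ Vinv
    return om_half @ R @ om_half / fit.phi2


def overid_adjusted(moments: MixedMoments, fit: EquationFit,
                    upsilon: np.ndarray | None = None, scale: str = "m",
                    omega_variant: str = "hat"):
    """Satorra-Bentler adjusted Sargan statistics F_m / F_mv (or tilde forms).

    The adjustment rescales the Sargan statistic by trace functions of the
    Pi matrix whose eigenvalues weight its asymptotic null distribution.
    """
    if fit.df_overid <= 0:
        return np.nan, 0.0, np.nan
    f_sargan, _, _ = sargan_test(moments, fit)
    Pi = _pi_matrix(moments, fit, upsilon, omega_variant)
    tr = float(np.trace(Pi))
    tr2 = float(np.trace(Pi @ Pi))
    if tr <= 0:
        raise ValueError("trace of the Pi matrix is not positive")
    if scale == "m":
        df = float(fit.df_overid)
        stat = df / tr * f_sargan
    elif scale == "mv":
        df = tr * tr / tr2
        stat = tr / tr2 * f_sargan
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return float(stat), df, float(stats.chi2.sf(stat, df))


def corollary_check(moments: MixedMoments, fit: EquationFit,
                    upsilon: np.ndarray | None = None) -> dict:
    """Traces of the Delta and Pi matrices (test harness for their identity).

    Delta uses the full derivative of h_j(sigma) = Sigma_vy - Sigma_vz
    gamma_j(sigma), which differs from the fixed-coefficient derivative
    behind Pi by a term proportional to the residual moment g; the traces
    agree whenever g = 0 and asymptotically with valid instruments.
    """
    if upsilon is None:
        upsilon = moments.upsilon
    S_vv, S_vz, *_ = _eq_blocks(moments, fit.equation)
    dh = fit.dg - S_vz @ fit.K
    _, vv_invhalf = _sqrt_and_invsqrt(S_vv)
    Delta = vv_invhalf @ dh @ upsilon @ dh.T @ vv_invhalf / fit.phi2
    Pi = _pi_matrix(moments, fit, upsilon, "hat")
    return {
        "trace_delta": float(np.trace(Delta)),
        "trace_pi": float(np.trace(Pi)),
        "trace_delta2": float(np.trace(Delta @ Delta)),
        "trace_pi2": float(np.trace(Pi @ Pi)),
    }


# ---------------------------------------------------------------------- #
#  Report
# ---------------------------------------------------------------------- #

_EQ_STATS = ("F_sargan", "F", "F_tilde", "F_m", "F_tilde_m", "F_mv", "F_tilde_mv")


@dataclass
class TestReport:
    """Model-level and equation-level test statistics with dfs and p-values."""

    model: ModelTests | None
    equations: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    bonferroni: bool = True

    @property
    def n_overidentified(self) -> int:
        return sum(1 for row in self.equations if row["df"] > 0)

    def significance_threshold(self) -> float:
        m = max(self.n_overidentified, 1)
        return self.alpha / m if self.bonferroni else self.alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        thr = self.significance_threshold()
        for row in self.equations:
            for stat in _EQ_STATS:
                rows.append({
                    "equation": row["equation"],
                    "test": stat,
                    "value": row[stat],
                    "df": row[f"{stat}_df"],
                    "p_value": row[f"{stat}_p"],
                    "significant": bool(row[f"{stat}_p"] < thr)
                    if np.isfinite(row[f"{stat}_p"]) else False,
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model": None if self.model is None else self.model.to_dict(),
            "equations": self.equations,
            "alpha": self.alpha,
            "bonferroni": self.bonferroni,
            "significance_threshold": self.significance_threshold(),
        }


def equation_test_report(result: Theta1Result, upsilon: np.ndarray | None = None,
                         alpha: float = 0.05, bonferroni: bool = True,
                         model_tests: ModelTests | None = None) -> TestReport:
    """All seven overidentification statistics for every estimable equation."""
    if upsilon is None:
        upsilon = result.moments.upsilon
    rows = []
    for fit in result.equations:
        if fit.theta1 is None:
            continue
        row = {"equation": fit.equation.lhs, "df": fit.df_overid}
        stats_def = {
            "F_sargan": lambda: sargan_test(result.moments, fit),
            "F": lambda: overid_chi2(result.moments, fit, upsilon, "hat"),
            "F_tilde": lambda: overid_chi2(result.moments, fit, upsilon, "tilde"),
            "F_m": lambda: overid_adjusted(result.moments, fit, upsilon, "m", "hat"),
            "F_tilde_m": lambda: overid_adjusted(result.moments, fit, upsilon, "m", "tilde"),
            "F_mv": lambda: overid_adjusted(result.moments, fit, upsilon, "mv", "hat"),
            "F_tilde_mv": lambda: overid_adjusted(result.moments, fit, upsilon, "mv", "tilde"),
        }
        for name, func in stats_def.items():
            try:
                stat, df, p = func()
            except (np.linalg.LinAlgError, ValueError):
                stat, df, p = np.nan, np.nan, np.nan
            row[name], row[f"{name}_df"], row[f"{name}_p"] = stat, df, p
        rows.append(row)
    return TestReport(model=model_tests, equations=rows,
                      alpha=alpha, bonferroni=bonferroni)
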