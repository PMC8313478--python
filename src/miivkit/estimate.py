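"""Equation-by-equation 2SLS estimation of loadings and latent regressions.

For equation j with regressors z, instruments v and dependent variable y,
the coefficient functional is

    gamma_j(s) = (S_vz' S_vv^-1 S_vz)^-1 S_vz' S_vv^-1 S_vy,

a closed form in moment-matrix blocks; no iteration is involved.  Two
standard-error estimators are provided: the *general* delta-method form
K_j Upsilon K_j' / n, valid even with invalid instruments, and the *valid*
sandwich built from an estimate of Omega_j, the asymptotic covariance of
the instrument-residual moment vector g_j = S_vy - S_vz theta_hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Equation
from .moments import MixedMoments

RCOND_SINGULAR = 1e-12


class SingularMomentBlockError(np.linalg.LinAlgError):
    pass


def _solve_psd(A, b):
    if 1.0 / np.linalg.cond(A) < RCOND_SINGULAR:
        raise SingularMomentBlockError("moment block numerically singular")
    return np.linalg.solve(A, b)


@dataclass
class EquationFit:
    """2SLS result for a single L2O equation."""

    equation: Equation
    theta1: np.ndarray | None = None
    g: np.ndarray | None = None            # S_vy - S_vz theta_hat
    phi2: float | None = None              # residual variance estimate
    K: np.ndarray | None = None            # d gamma / d sigma', (K_j, len(s))
    dg: np.ndarray | None = None           # d g / d sigma' at fixed theta, (L_j, len(s))
    se_general: np.ndarray | None = None
    se_valid: np.ndarray | None = None
    omega_variant: str | None = None
    flagged: bool = False
    message: str = ""

    @property
    def df_overid(self) -> int:
        return self.equation.n_miivs - self.equation.n_regressors


@dataclass
class Theta1Result:
    """Stacked equation-by-equation estimates with jacobians and SEs."""

    equations: list[EquationFit]
    moments: MixedMoments
    param_names: list[str] = field(default_factory=list)

    @property
    def theta1(self) -> np.ndarray:
        return np.concatenate([f.theta1 for f in self.equations if f.theta1 is not None])

    @property
    def K_stacked(self) -> np.ndarray:
        return np.vstack([f.K for f in self.equations if f.K is not None])

    def to_records(self) -> list[dict]:
        out = []
        for f in self.equations:
            for i, name in enumerate(f.equation.param_names):
                out.append({
                    "equation": f.equation.lhs,
                    "parameter": name,
                    "estimate": None if f.theta1 is None else float(f.theta1[i]),
                    "se_general": None if f.se_general is None else float(f.se_general[i]),
                    "se_valid": None if f.se_valid is None else float(f.se_valid[i]),
                    "miivs": list(f.equation.miivs or []),
                    "flagged": f.flagged,
                })
        return out


# ---------------------------------------------------------------------- #

def _entry_derivative(rows, cols, a, b):
    """0/1 selection derivative of S[rows, cols] with respect to sigma_(a,b)."""
    D = np.zeros((len(rows), len(cols)))
    for m, rm in enumerate(rows):
        for l, cl in enumerate(cols):
            if (rm == a and cl == b) or (rm == b and cl == a):
                D[m, l] = 1.0
    return D


def _eq_blocks(moments: MixedMoments, eq: Equation):
    v, z, y = eq.miivs, eq.rhs, eq.lhs
    if v is None:
        raise ValueError(f"no MIIVs selected for equation {eq.lhs!r}")
    S_vv = moments.block(v, v)
    S_vz = moments.block(v, z)
    S_vy = moments.block(v, [y])[:, 0]
    S_zz = moments.block(z, z)
    S_zy = moments.block(z, [y])[:, 0]
    S_yy = moments.scalar(y, y)
    return S_vv, S_vz, S_vy, S_zz, S_zy, S_yy


def fit_theta1(moments: MixedMoments, equations: list[Equation],
               upsilon: np.ndarray | None = None,
               omega_variant: str = "hat") -> Theta1Result:
    """MIIV point estimates for every equation, with SEs when Upsilon is given.

    Estimation is equation-by-equation and closed-form; a singular moment
    block flags the affected equation and leaves the others untouched.  The
    projection identity ``S_vz' S_vv^-1 g = 0`` holds on every successful
    fit regardless of instrument validity.
    """
    if upsilon is None:
        upsilon = moments.upsilon
    fits = []
    for eq in equations:
        fit = EquationFit(equation=eq)
        try:
            S_vv, S_vz, S_vy, S_zz, S_zy, S_yy = _eq_blocks(moments, eq)
            VinvZ = _solve_psd(S_vv, S_vz)
            A = S_vz.T @ VinvZ
            theta = _solve_psd(A, VinvZ.T @ S_vy)
            fit.theta1 = theta
            fit.g = S_vy - S_vz @ theta
            fit.phi2 = float(S_yy - 2 * theta @ S_zy + theta @ S_zz @ theta)
            fit.K, fit.dg = kappa_jacobian(moments, eq, theta, return_dg=True)
            if upsilon is not None:
                se_theta1_single(fit, moments, upsilon, omega_variant)
        except np.linalg.LinAlgError as exc:
            fit.flagged = True
            fit.message = str(exc)
        fits.append(fit)
    names = [n for eq in equations for n in eq.param_names]
    return Theta1Result(equations=fits, moments=moments, param_names=names)


def kappa_jacobian(moments: MixedMoments, eq: Equation, theta1_hat: np.ndarray,
                   return_dg: bool = False):
    """Analytic derivative of gamma_j(s) with respect to each free moment entry.

    The derivative of any S block with respect to a free entry sigma_i is a
    0/1 selection matrix; identification-fixed discrete diagonals carry no
    free entry and hence no derivative.
    """
    v, z, y = eq.miivs, eq.rhs, eq.lhs
    S_vv, S_vz, S_vy, *_ = _eq_blocks(moments, eq)
    Vinv = np.linalg.inv(S_vv)
    VinvZ = Vinv @ S_vz
    P = np.linalg.inv(S_vz.T @ VinvZ)
    W1 = P @ VinvZ.T                      # (K, L)
    g = S_vy - S_vz @ theta1_hat
    entries = moments.free_entries()
    Kmat = np.zeros((len(z), len(entries)))
    Dg = np.zeros((len(v), len(entries)))
    yl = [y]
    for kidx, (i, j) in enumerate(entries):
        a, b = moments.names[i], moments.names[j]
        active = {a, b}
        if not (active & set(v) or active & set(z) or y in active):
            continue
        dSvv = _entry_derivative(v, v, a, b)
        dSvz = _entry_derivative(v, z, a, b)
        dSvy = _entry_derivative(v, yl, a, b)[:, 0]
        dg_k = dSvy - dSvz @ theta1_hat
        Dg[:, kidx] = dg_k
        term1 = P @ (dSvz.T @ (Vinv @ g)) - W1 @ (dSvv @ (Vinv @ g))
        term2 = W1 @ dg_k
        Kmat[:, kidx] = term1 + term2
    if return_dg:
        return Kmat, Dg
    return Kmat


def omega_matrix(moments: MixedMoments, fit: EquationFit,
                 upsilon: np.ndarray | None = None,
                 variant: str = "hat") -> np.ndarray:
    """Estimate Omega_j, the asymptotic covariance of sqrt(n) g_j.

    ``hat`` is the delta-method form (dg/dsigma) Upsilon (dg/dsigma)';
    ``tilde`` subtracts the residual-moment outer product g g'; ``classic``
    is phi^2 S_vv, the homoskedastic 2SLS form.
    """
    if variant == "classic":
        S_vv = moments.block(fit.equation.miivs, fit.equation.miivs)
        return fit.phi2 * S_vv
    if upsilon is None:
        upsilon = moments.upsilon
    if upsilon is None:
        raise ValueError("Upsilon required for omega variants 'hat' and 'tilde'")
    hat = fit.dg @ upsilon @ fit.dg.T
    if variant == "hat":
        return hat
    if variant == "tilde":
        tilde = hat - np.outer(fit.g, fit.g)
        w = np.linalg.eigvalsh((tilde + tilde.T) / 2)
        if w.min() < -1e-8 * max(w.max(), 1e-300):
            raise np.linalg.LinAlgError(
                "Omega-tilde is indefinite; use the 'hat' variant")
        return tilde
    raise ValueError(f"unknown omega variant {variant!r}")


def se_theta1_single(fit: EquationFit, moments: MixedMoments,
                     upsilon: np.ndarray, omega_variant: str = "hat") -> None:
    """Fill both SE estimators on one equation fit (in place)."""
    eq = fit.equation
    S_vv, S_vz, *_ = _eq_blocks(moments, eq)
    cov_general = fit.K @ upsilon @ fit.K.T
    fit.se_general = _safe_sqrt_diag(cov_general / moments.n, fit)
    Om = omega_matrix(moments, fit, upsilon, omega_variant)
    Vinv = np.linalg.inv(S_vv)
    P = np.linalg.inv(S_vz.T @ Vinv @ S_vz)
    W1 = P @ S_vz.T @ Vinv
    cov_valid = W1 @ Om @ W1.T
    fit.se_valid = _safe_sqrt_diag(cov_valid / moments.n, fit)
    fit.omega_variant = omega_variant


def _safe_sqrt_diag(cov, fit):
    d = np.diag(cov).copy()
    if (d <= 0).any():
        fit.flagged = True
        fit.message = (fit.message + "; " if fit.message else "") + "nonpositive SE variance"
        d = np.maximum(d, 0.0)
    return np.sqrt(d)


def se_theta1(result: Theta1Result, upsilon: np.ndarray | None = None,
              method: str = "general", omega_variant: str = "hat") -> np.ndarray:
    """Stacked SEs for theta1 by the requested method ('general' or 'valid')."""
    if upsilon is None:
        upsilon = result.moments.upsilon
    out = []
    for fit in result.equations:
        if fit.theta1 is None:
            continue
        se_theta1_single(fit, result.moments, upsilon, omega_variant)
        out.append(fit.se_general if method == "general" else fit.se_valid)
    if method not in ("general", "valid"):
        raise ValueError(f"unknown SE method {method!r}")
    return np.concatenate(out)
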