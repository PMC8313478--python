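"""Implied-moment machinery and second-stage variance estimation.

The implied covariance of the underlying variables is

    Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda' + Theta,

with the Theta diagonal of every ordinal/binary indicator solved so the
corresponding Sigma diagonal is 1 (identification).  Given the first-stage
estimates theta1 (loadings and regressions), the free variance parameters
theta2 (Psi and Theta entries) minimize the weighted least-squares fit
function T = (s - sigma(theta))' W (s - sigma(theta)); with theta1 held
fixed, sigma is linear in theta2, so the minimizer is the exact generalized
least-squares solution and the second stage cannot fail to converge.  The
systemwide DWLS estimator minimizes the same fit function over the full
theta and serves as a comparison arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import ModelSpec
from .moments import MixedMoments

PD_EPS = 1e-8


class HeywoodWarning(UserWarning):
    pass


# ---------------------------------------------------------------------- #
#  Implied moments
# ---------------------------------------------------------------------- #

def _assemble_full(model: ModelSpec, theta1, theta2):
    """Numeric (Lambda, B, Psi, Theta) with discrete Theta diagonals solved."""
    Lam, B, Psi, Th = model.assemble(theta1, theta2)
    m = B.shape[0]
    A = np.linalg.inv(np.eye(m) - B)
    Phi = A @ Psi @ A.T
    common = Lam @ Phi @ Lam.T
    heywood = False
    for i, y in enumerate(model.indicators):
        if model.is_discrete(y):
            Th[i, i] = 1.0 - common[i, i]
            if Th[i, i] <= 0:
                heywood = True
    return Lam, B, Psi, Th, Phi, common, heywood


def implied_sigma(theta1, theta2, model: ModelSpec, order: list[str] | None = None):
    """Implied covariance matrix Sigma(theta) and a Heywood flag.

    ``order`` permutes the rows/columns to a data-column ordering.
    """
    Lam, B, Psi, Th, Phi, common, heywood = _assemble_full(model, theta1, theta2)
    Sigma = common + Th
    if order is not None:
        perm = [model.indicators.index(v) for v in order]
        Sigma = Sigma[np.ix_(perm, perm)]
    return Sigma, heywood


def sigma_free_vector(moments: MixedMoments, Sigma_ordered: np.ndarray) -> np.ndarray:
    return np.array([Sigma_ordered[i, j] for i, j in moments.free_entries()])


def weight_matrix(moments: MixedMoments, spec: str) -> np.ndarray:
    """W for the fit function: uls = I, dwls = diag(Upsilon)^-1, wls = Upsilon^-1."""
    m = len(moments.free_entries())
    if spec == "uls":
        return np.eye(m)
    if moments.upsilon is None:
        raise ValueError(f"weight {spec!r} requires an estimated Upsilon")
    if spec == "dwls":
        return np.diag(1.0 / np.diag(moments.upsilon))
    if spec == "wls":
        return np.linalg.inv(moments.upsilon)
    raise ValueError(f"unknown weight spec {spec!r}")


def fit_function(theta1, theta2, model: ModelSpec, moments: MixedMoments,
                 W: np.ndarray | str = "uls") -> float:
    """T = (s - sigma(theta))' W (s - sigma(theta))."""
    if isinstance(W, str):
        W = weight_matrix(moments, W)
    Sigma, _ = implied_sigma(theta1, theta2, model, order=moments.names)
    r = moments.s - sigma_free_vector(moments, Sigma)
    return float(r @ W @ r)


# ---------------------------------------------------------------------- #
#  Jacobians
# ---------------------------------------------------------------------- #

def sigma_jacobians(theta1, theta2, model: ModelSpec, moments: MixedMoments):
    """Analytic J1 = d sigma / d theta1', J2 = d sigma / d theta2'.

    Rows follow the free-entry order of the moment matrix.  The solved
    discrete Theta diagonals only feed entries excluded from s, so no chain
    term survives the constraint substitution.
    """
    Lam, B, Psi, Th, Phi, common, _ = _assemble_full(model, theta1, theta2)
    p, m = Lam.shape
    A = np.linalg.inv(np.eye(m) - B)
    perm = [model.indicators.index(v) for v in moments.names]
    entries = moments.free_entries()
    yi = {y: i for i, y in enumerate(model.indicators)}
    fi = {f: i for i, f in enumerate(model.factors)}

    def extract(dSigma):
        dS = dSigma[np.ix_(perm, perm)]
        return np.array([dS[i, j] for i, j in entries])

    cols1 = []
    for name in model.theta1_names():
        if name.startswith("l_"):
            y, f = name[2:].split("~")
            E = np.zeros((p, m))
            E[yi[y], fi[f]] = 1.0
            G = E @ Phi @ Lam.T
            cols1.append(extract(G + G.T))
        else:
            dv, iv = name[2:].split("~")
            dB = np.zeros((m, m))
            dB[fi[dv], fi[iv]] = 1.0
            dA = A @ dB @ A
            G = Lam @ (dA @ Psi @ A.T) @ Lam.T
            cols1.append(extract(G + G.T))
    cols2 = []
    for a, b in model.psi_entries():
        E = np.zeros((m, m))
        E[fi[a], fi[b]] = 1.0
        if a != b:
            E[fi[b], fi[a]] = 1.0
        cols2.append(extract(Lam @ A @ E @ A.T @ Lam.T))
    for a, b in model.theta_entries():
        E = np.zeros((p, p))
        E[yi[a], yi[b]] = 1.0
        if a != b:
            E[yi[b], yi[a]] = 1.0
        cols2.append(extract(E))
    J1 = np.column_stack(cols1) if cols1 else np.zeros((len(entries), 0))
    J2 = np.column_stack(cols2) if cols2 else np.zeros((len(entries), 0))
    return np.hstack([J1, J2]), J1, J2


# ---------------------------------------------------------------------- #
#  Results container
# ---------------------------------------------------------------------- #

@dataclass
class FullFitResult:
    model: ModelSpec
    moments: MixedMoments
    theta1: np.ndarray
    theta2: np.ndarray | None
    weight_spec: str
    W: np.ndarray
    systemwide: bool = False
    converged: bool = True
    T: float | None = None
    heywood: bool = False
    psi_pd: bool = False
    theta_pd: bool = False
    se2: np.ndarray | None = None
    message: str = ""
    J1: np.ndarray | None = None
    J2: np.ndarray | None = None

    @property
    def proper(self) -> bool:
        """Converged with positive-definite Psi-hat and Theta-hat."""
        return bool(self.converged and self.psi_pd and self.theta_pd)

    @property
    def theta1_names(self):
        return self.model.theta1_names()

    @property
    def theta2_names(self):
        return self.model.theta2_names()

    def to_dict(self) -> dict:
        return {
            "theta1": dict(zip(self.theta1_names, map(float, self.theta1))),
            "theta2": None if self.theta2 is None else dict(
                zip(self.theta2_names, map(float, self.theta2))),
            "se_theta2": None if self.se2 is None else dict(
                zip(self.theta2_names, map(float, self.se2))),
            "weight": self.weight_spec,
            "systemwide": self.systemwide,
            "converged": self.converged,
            "proper": self.proper,
            "heywood": self.heywood,
            "fit_value": self.T,
        }


def _pd_flags(model: ModelSpec, theta1, theta2):
    Lam, B, Psi, Th, Phi, common, heywood = _assemble_full(model, theta1, theta2)
    psi_pd = bool(np.linalg.eigvalsh((Psi + Psi.T) / 2).min() > PD_EPS)
    if np.allclose(Th, np.diag(np.diag(Th))):
        theta_pd = bool(np.diag(Th).min() > 0)
    else:
        theta_pd = bool(np.linalg.eigvalsh((Th + Th.T) / 2).min() > PD_EPS)
    phi_pd = bool(np.linalg.eigvalsh((Phi + Phi.T) / 2).min() > PD_EPS)
    return psi_pd and phi_pd, theta_pd, heywood


# ---------------------------------------------------------------------- #
#  Second stage: theta2 given theta1
# ---------------------------------------------------------------------- #

def fit_theta2(theta1, moments: MixedMoments, model: ModelSpec,
               weight: str = "dwls") -> FullFitResult:
    """Exact weighted least-squares solution for the variance parameters.

    With Lambda and B fixed at theta1, sigma(theta) is linear and
    homogeneous in theta2, so the fit-function minimizer is the closed-form
    GLS estimate; variance parameters are left unconstrained and improper
    (non-positive-definite) solutions are flagged rather than prevented.
    """
    W = weight_matrix(moments, weight)
    J, J1, J2 = sigma_jacobians(theta1, np.zeros(len(model.theta2_names())),
                                model, moments)
    res = FullFitResult(model=model, moments=moments,
                        theta1=np.asarray(theta1, float), theta2=None,
                        weight_spec=weight, W=W, J1=J1, J2=J2)
    try:
        A = J2.T @ W @ J2
        theta2 = np.linalg.solve(A, J2.T @ W @ moments.s)
    except np.linalg.LinAlgError as exc:
        res.converged = False
        res.message = f"second stage failed: {exc}"
        return res
    res.theta2 = theta2
    res.T = fit_function(res.theta1, theta2, model, moments, W)
    res.psi_pd, res.theta_pd, res.heywood = _pd_flags(model, res.theta1, theta2)
    _, res.J1, res.J2 = sigma_jacobians(res.theta1, theta2, model, moments)
    return res


def se_theta2(full: FullFitResult, K_stacked: np.ndarray,
              upsilon: np.ndarray | None = None) -> np.ndarray:
    """Delta-method SEs of theta2 accounting for the estimated first stage.

    C = H (I - J1 K), H = (J2' W J2)^-1 J2' W; SEs are sqrt(diag(C Ups C')/n).
    With K = 0 (theta1 known) C reduces to the classical least-squares form.
    """
    if not full.converged or full.theta2 is None:
        raise ValueError("second stage did not converge; no SEs available")
    if upsilon is None:
        upsilon = full.moments.upsilon
    if upsilon is None:
        raise ValueError("Upsilon required for theta2 standard errors")
    W, J1, J2 = full.W, full.J1, full.J2
    H = np.linalg.solve(J2.T @ W @ J2, J2.T @ W)
    C = H @ (np.eye(J1.shape[0]) - J1 @ K_stacked)
    cov = C @ upsilon @ C.T / full.moments.n
    full.se2 = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return full.se2


def c_matrix(full: FullFitResult, K_stacked: np.ndarray) -> np.ndarray:
    W, J1, J2 = full.W, full.J1, full.J2
    H = np.linalg.solve(J2.T @ W @ J2, J2.T @ W)
    return H @ (np.eye(J1.shape[0]) - J1 @ K_stacked)


# ---------------------------------------------------------------------- #
#  Systemwide DWLS comparison estimator
# ---------------------------------------------------------------------- #

def _start_values(model: ModelSpec, moments: MixedMoments):
    """Cheap scale-aware starting point for the systemwide optimizer."""
    t1 = {}
    for name in model.theta1_names():
        if name.startswith("l_"):
            y, f = name[2:].split("~")
            s_f = model.scaling[f]
            t1[name] = moments.scalar(y, s_f) / max(moments.scalar(s_f, s_f), 1e-8)
        else:
            t1[name] = 0.0
    for f in model.endogenous_factors:
        z = [model.scaling[p] for p in model.regressions[f]]
        try:
            b = np.linalg.solve(moments.block(z, z),
                                moments.block(z, [model.scaling[f]])[:, 0])
        except np.linalg.LinAlgError:
            b = np.zeros(len(z))
        for pred, val in zip(model.regressions[f], b):
            t1[f"b_{f}~{pred}"] = float(val)
    t2 = {}
    for a, b in model.psi_entries():
        key = f"psi_{a}~~{b}"
        sa, sb = model.scaling[a], model.scaling[b]
        if a == b:
            t2[key] = 0.5 * moments.scalar(sa, sa)
        elif a in model.exogenous_factors and b in model.exogenous_factors:
            t2[key] = moments.scalar(sa, sb)
        else:
            t2[key] = 0.0
    t2_tmp = dict(t2)
    for a, b in model.theta_entries():
        t2_tmp[f"theta_{a}~~{b}"] = 0.0
    Sigma0, _ = implied_sigma(t1, t2_tmp, model, order=moments.names)
    for a, b in model.theta_entries():
        key = f"theta_{a}~~{b}"
        if a == b:
            i = moments.names.index(a)
            t2[key] = max(0.05, moments.scalar(a, a) - Sigma0[i, i])
        else:
            t2[key] = 0.0
    x1 = np.array([t1[n] for n in model.theta1_names()])
    x2 = np.array([t2[n] for n in model.theta2_names()])
    return np.concatenate([x1, x2])


def fit_full_dwls(model: ModelSpec, moments: MixedMoments,
                  weight: str = "dwls", max_nfev: int = 500) -> FullFitResult:
    """Systemwide weighted least squares over the entire parameter vector.

    Minimizes the fit function with the chosen weight (default: inverse
    diagonal of Upsilon) by trust-region least squares with the analytic
    jacobian.  Variance parameters are unconstrained; improper solutions
    (non-PD Psi-hat or Theta-hat) are flagged, not prevented.
    """
    W = weight_matrix(moments, weight)
    if weight in ("uls", "dwls"):
        Wh = np.diag(np.sqrt(np.diag(W)))
    else:
        Wh = np.linalg.cholesky(W).T    # W = Wh' Wh so r'Wr = |Wh r|^2
    n1 = len(model.theta1_names())
    s_vec = moments.s

    def split(x):
        return x[:n1], x[n1:]

    def resid(x):
        t1, t2 = split(x)
        Sigma, _ = implied_sigma(t1, t2, model, order=moments.names)
        return Wh @ (s_vec - sigma_free_vector(moments, Sigma))

    def jac(x):
        t1, t2 = split(x)
        J, _, _ = sigma_jacobians(t1, t2, model, moments)
        return -Wh @ J

    x0 = _start_values(model, moments)
    sol = optimize.least_squares(resid, x0, jac=jac, method="trf",
                                 max_nfev=max_nfev, xtol=1e-12, ftol=1e-12,
                                 gtol=1e-10)
    t1, t2 = split(sol.x)
    res = FullFitResult(model=model, moments=moments, theta1=t1, theta2=t2,
                        weight_spec=weight, W=W, systemwide=True)
    res.converged = bool(sol.success and np.isfinite(sol.cost))
    res.T = float(2 * sol.cost)
    res.psi_pd, res.theta_pd, res.heywood = _pd_flags(model, t1, t2)
    _, res.J1, res.J2 = sigma_jacobians(t1, t2, model, moments)
    if not res.converged:
        res.message = sol.message
    return res
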