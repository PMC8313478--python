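"""Asymptotic covariance (Upsilon) of the free moment-matrix entries.

Upsilon is the asymptotic covariance of sqrt(n) (s - sigma).  Four
estimators are available:

* ``normal``   -- normal-theory 2 D+ (S (x) S) D+' (all-continuous data),
* ``adf``      -- centered fourth-moment (distribution-free) estimator
  (all-continuous data),
* ``score_sandwich`` -- sandwich built from the stacked per-observation
  influence functions of the two-step pairwise estimators (Pearson,
  polychoric, polyserial), including the propagation of estimated
  thresholds, means, and standard deviations,
* ``bootstrap`` -- nonparametric bootstrap of the whole moment vector.

The default resolves to ``score_sandwich`` when any variable is discrete
and ``normal`` otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .moments import MixedMoments, build_moment_matrix, cell_probabilities

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI

_FD_RHO = 1e-4
_FD_NU = 1e-4


def estimate_upsilon(data: pd.DataFrame, moments: MixedMoments,
                     method: str = "auto", B: int = 400,
                     seed: int | None = None) -> np.ndarray:
    """Estimate Upsilon and attach it to ``moments``."""
    if method == "auto":
        any_disc = any(moments.is_discrete(v) for v in moments.names)
        method = "score_sandwich" if any_disc else "normal"
    if method in ("normal", "adf"):
        if any(moments.is_discrete(v) for v in moments.names):
            raise ValueError(f"method {method!r} requires all-continuous data")
    if method == "normal":
        ups = _upsilon_normal(moments)
    elif method == "adf":
        ups = _upsilon_adf(data, moments)
    elif method == "score_sandwich":
        ups = _upsilon_sandwich(data, moments)
    elif method == "bootstrap":
        if B < 50:
            raise ValueError("bootstrap requires B >= 50")
        ups = _upsilon_bootstrap(data, moments, B, seed)
    else:
        raise ValueError(f"unknown Upsilon method {method!r}")
    ups = _finalize(ups)
    moments.upsilon = ups
    moments.upsilon_method = method
    return ups


def _finalize(ups: np.ndarray) -> np.ndarray:
    ups = (ups + ups.T) / 2.0
    w, V = np.linalg.eigh(ups)
    lam_max = max(w.max(), 1e-300)
    if w.min() < -1e-8 * lam_max:
        raise np.linalg.LinAlgError(
            f"Upsilon indefinite (min eigenvalue {w.min():.3e})")
    if w.min() < 0:
        ups = (V * np.clip(w, 0.0, None)) @ V.T
        ups = (ups + ups.T) / 2.0
    return ups


# ---------------------------------------------------------------------- #
#  Closed forms for continuous data
# ---------------------------------------------------------------------- #

def _upsilon_normal(moments: MixedMoments) -> np.ndarray:
    """Normal-theory form: Ups[ij,kl] = S_ik S_jl + S_il S_jk."""
    entries = moments.free_entries()
    S = moments.S
    m = len(entries)
    ups = np.empty((m, m))
    for a, (i, j) in enumerate(entries):
        for b, (k, l) in enumerate(entries):
            ups[a, b] = S[i, k] * S[j, l] + S[i, l] * S[j, k]
    return ups


def _centered_columns(data: pd.DataFrame, moments: MixedMoments) -> np.ndarray:
    clean = data.dropna()
    if len(clean) != moments.n:
        raise ValueError("data rows after listwise deletion do not match moments.n")
    X = clean[moments.names].to_numpy(dtype=float)
    return X - X.mean(axis=0)


def _upsilon_adf(data: pd.DataFrame, moments: MixedMoments) -> np.ndarray:
    Xc = _centered_columns(data, moments)
    entries = moments.free_entries()
    W = np.column_stack([Xc[:, i] * Xc[:, j] for i, j in entries])
    Wc = W - W.mean(axis=0)
    return Wc.T @ Wc / moments.n


# ---------------------------------------------------------------------- #
#  Score sandwich for mixed data
# ---------------------------------------------------------------------- #

def _threshold_influence(codes: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Influence functions of marginal thresholds, one column per threshold."""
    F = special.ndtr(tau)
    phi = _phi(tau)
    cols = [((codes <= c).astype(float) - F[c]) / phi[c] for c in range(len(tau))]
    return np.column_stack(cols)


def _polychoric_influence(codes_a, codes_b, tau_a, tau_b, rho,
                          if_tau_a, if_tau_b) -> np.ndarray:
    """Per-observation influence of the two-step polychoric correlation."""
    tab = np.zeros((len(tau_a) + 1, len(tau_b) + 1))
    np.add.at(tab, (codes_a, codes_b), 1.0)
    w = tab / tab.sum()
    h = _FD_RHO

    def lgrid(r, ta, tb):
        return np.log(cell_probabilities(ta, tb, r))

    L = {d: lgrid(rho + d * h, tau_a, tau_b) for d in (-2, -1, 0, 1, 2)}
    u_cell = (L[1] - L[-1]) / (2 * h)
    H_rr = float((w * (L[2] - 2 * L[0] + L[-2]) / (4 * h * h)).sum())

    def cross(ta, tb):
        up = lgrid(rho + h, ta, tb)
        dn = lgrid(rho - h, ta, tb)
        return (w * (up - dn) / (2 * h)).sum()

    H_nu = []
    for k in range(len(tau_a)):
        ta_p, ta_m = tau_a.copy(), tau_a.copy()
        ta_p[k] += _FD_NU
        ta_m[k] -= _FD_NU
        H_nu.append((cross(ta_p, tau_b) - cross(ta_m, tau_b)) / (2 * _FD_NU))
    for k in range(len(tau_b)):
        tb_p, tb_m = tau_b.copy(), tau_b.copy()
        tb_p[k] += _FD_NU
        tb_m[k] -= _FD_NU
        H_nu.append((cross(tau_a, tb_p) - cross(tau_a, tb_m)) / (2 * _FD_NU))

    u_obs = u_cell[codes_a, codes_b]
    nuis = np.hstack([if_tau_a, if_tau_b])
    return -(u_obs + nuis @ np.asarray(H_nu)) / H_rr


def _polyserial_score(x, codes, rho, mu, sd, tau):
    """Analytic per-observation score of the conditional likelihood wrt rho."""
    z = (x - mu) / sd
    cut = np.concatenate([[-np.inf], tau, [np.inf]])
    a_up, a_lo = cut[codes + 1], cut[codes]
    d = np.sqrt(1.0 - rho * rho)
    U = (a_up - rho * z) / d
    L = (a_lo - rho * z) / d
    P = np.clip(special.ndtr(U) - special.ndtr(L), 1e-300, None)

    def term(a, t):
        fin = np.isfinite(a)
        out = np.zeros_like(z)
        dT = (-z[fin]) / d + (a[fin] - rho * z[fin]) * rho / d**3
        out[fin] = _phi(t[fin]) * dT
        return out

    return (term(a_up, U) - term(a_lo, L)) / P


def _polyserial_influence(x, codes, rho, mu, sd, tau, if_tau) -> np.ndarray:
    """Per-observation influence of the two-step polyserial correlation."""
    h = _FD_RHO

    def mean_u(r=rho, m=mu, s=sd, t=tau):
        return _polyserial_score(x, codes, r, m, s, t).mean()

    u = _polyserial_score(x, codes, rho, mu, sd, tau)
    H_rr = (mean_u(r=rho + h) - mean_u(r=rho - h)) / (2 * h)
    scale = max(sd, 1.0)
    H_mu = (mean_u(m=mu + _FD_NU * scale) - mean_u(m=mu - _FD_NU * scale)) / (2 * _FD_NU * scale)
    H_sd = (mean_u(s=sd + _FD_NU * scale) - mean_u(s=sd - _FD_NU * scale)) / (2 * _FD_NU * scale)
    H_tau = []
    for k in range(len(tau)):
        tp, tm = tau.copy(), tau.copy()
        tp[k] += _FD_NU
        tm[k] -= _FD_NU
        H_tau.append((mean_u(t=tp) - mean_u(t=tm)) / (2 * _FD_NU))
    if_mu = x - mu
    if_sd = ((x - mu) ** 2 - sd * sd) / (2 * sd)
    corr = H_mu * if_mu + H_sd * if_sd + if_tau @ np.asarray(H_tau)
    return -(u + corr) / H_rr, if_sd


def _upsilon_sandwich(data: pd.DataFrame, moments: MixedMoments) -> np.ndarray:
    clean = data.dropna()
    if len(clean) != moments.n:
        raise ValueError("data rows after listwise deletion do not match moments.n")
    n = moments.n
    names = moments.names
    disc = {v: moments.is_discrete(v) for v in names}
    codes, if_tau, xc, sds = {}, {}, {}, {}
    for v in names:
        col = clean[v].to_numpy()
        if disc[v]:
            _, cd = np.unique(col, return_inverse=True)
            codes[v] = cd
            if_tau[v] = _threshold_influence(cd, moments.thresholds[v])
        else:
            col = np.asarray(col, dtype=float)
            xc[v] = col - col.mean()
            sds[v] = np.sqrt(xc[v] @ xc[v] / n)

    entries = moments.free_entries()
    IF = np.empty((n, len(entries)))
    for k, (i, j) in enumerate(entries):
        a, b = names[i], names[j]
        s_ij = moments.S[i, j]
        if not disc[a] and not disc[b]:
            IF[:, k] = xc[a] * xc[b] - s_ij
        elif disc[a] and disc[b]:
            IF[:, k] = _polychoric_influence(
                codes[a], codes[b], moments.thresholds[a], moments.thresholds[b],
                s_ij, if_tau[a], if_tau[b])
        else:
            cont, dv = (a, b) if not disc[a] else (b, a)
            x = clean[cont].to_numpy(dtype=float)
            mu, sd = x.mean(), sds[cont]
            rho = s_ij / sd
            if_rho, if_sd = _polyserial_influence(
                x, codes[dv], rho, mu, sd, moments.thresholds[dv], if_tau[dv])
            IF[:, k] = sd * if_rho + rho * if_sd
    IFc = IF - IF.mean(axis=0)
    return IFc.T @ IFc / n


def _upsilon_bootstrap(data: pd.DataFrame, moments: MixedMoments,
                       B: int, seed: int | None) -> np.ndarray:
    clean = data.dropna().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(clean)
    draws = np.empty((B, len(moments.free_entries())))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        mom_b = build_moment_matrix(clean.iloc[idx], moments.types)
        draws[b] = mom_b.s
    return n * np.cov(draws, rowvar=False)
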