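"""Population model, data generation, and the Monte Carlo study runner.

The study design uses five latent variables (two correlated exogenous, three
endogenous in a recursive standardized structural model), each measured by
three indicators with standardized loadings 0.8, 0.65, and 0.5.  Indicators
of two factors are ordinal with five categories whose population response
probabilities are 0.04/0.05/0.21/0.46/0.24; the remaining indicators are
continuous with unit total variance.  The numeric population values live in
``data/sim_truth.json`` so that the single point of truth is auditable.

Conditions vary the hypothesized model (correct, or misspecified by fixing
the eta3->eta4 path to zero), the sample size, the scaling indicator (the
loading-0.8 "high R^2" or the loading-0.5 "low R^2" indicator), and the
estimator (MIIV with one extra instrument, MIIV with all instruments, or
systemwide DWLS).  Outcome measures follow the study conventions: percent
proper solutions (converged with positive-definite covariance matrices),
median relative bias, SE accuracy against the interquartile-trimmed Monte
Carlo standard deviation, and 0.05-level rejection rates of all tests.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .asycov import estimate_upsilon
from .inference import equation_test_report, model_fit_tests
from .model import (ModelSpec, find_miivs, l2o_transform, parse_model,
                    select_miivs, shea_partial_r2)
from .moments import MixedMoments, build_moment_matrix, estimate_thresholds
from .estimate import fit_theta1
from .sysfit import fit_full_dwls, fit_theta2, se_theta2


def _truth_config() -> dict:
    with resources.files("miivkit").joinpath("data/sim_truth.json").open() as fh:
        return json.load(fh)


@dataclass
class SimTruth:
    """Population matrices of the data-generating process."""

    factor_names: list[str]
    indicator_names: list[str]
    Lambda: np.ndarray
    B: np.ndarray
    Psi: np.ndarray                 # exogenous (co)variances and zeta variances
    theta_diag: np.ndarray          # indicator error variances
    types: dict[str, str]
    thresholds: np.ndarray          # shared cut points of the ordinal indicators
    loadings: list[float]

    @property
    def latent_cov(self) -> np.ndarray:
        A = np.linalg.inv(np.eye(len(self.factor_names)) - self.B)
        return A @ self.Psi @ A.T

    @property
    def implied_cov(self) -> np.ndarray:
        return self.Lambda @ self.latent_cov @ self.Lambda.T + np.diag(self.theta_diag)


def simulation_truth() -> SimTruth:
    """Build the population model from the versioned truth configuration.

    Structural coefficients are standardized; the residual variance of each
    endogenous latent variable is solved so that all latent variances are 1.
    """
    cfg = _truth_config()
    factors = ["eta1", "eta2", "eta3", "eta4", "eta5"]
    fi = {f: i for i, f in enumerate(factors)}
    m = len(factors)
    B = np.zeros((m, m))
    for dv, preds in cfg["structural"].items():
        for iv, val in preds.items():
            B[fi[dv], fi[iv]] = val
    r = cfg["exogenous_correlation"]
    Psi = np.zeros((m, m))
    Psi[0, 0] = Psi[1, 1] = 1.0
    Psi[0, 1] = Psi[1, 0] = r
    # solve zeta variances for unit latent variances, factor by factor
    Phi = np.zeros((m, m))
    Phi[:2, :2] = [[1.0, r], [r, 1.0]]
    for i in range(2, m):
        b = B[i, :i]
        var_pred = b @ Phi[:i, :i] @ b
        psi_i = 1.0 - var_pred
        if psi_i <= 0:
            raise ValueError("structural coefficients imply nonpositive zeta variance")
        Psi[i, i] = psi_i
        Phi[i, :i] = b @ Phi[:i, :i]
        Phi[:i, i] = Phi[i, :i]
        Phi[i, i] = 1.0
    loadings = list(cfg["loadings"])
    p = 3 * m
    names = [f"y{k + 1}" for k in range(p)]
    Lam = np.zeros((p, m))
    theta_diag = np.zeros(p)
    for j in range(m):
        for k in range(3):
            lam = loadings[k]
            Lam[3 * j + k, j] = lam
            theta_diag[3 * j + k] = 1.0 - lam ** 2
    ordinal = {f for f in cfg["ordinal_factors"]}
    types = {}
    for j, f in enumerate(factors):
        for k in range(3):
            types[names[3 * j + k]] = "ordinal" if f in ordinal else "continuous"
    probs = np.asarray(cfg["category_probabilities"])
    thresholds = estimate_thresholds(probs)
    return SimTruth(factor_names=factors, indicator_names=names, Lambda=Lam,
                    B=B, Psi=Psi, theta_diag=theta_diag, types=types,
                    thresholds=thresholds, loadings=loadings)


# ---------------------------------------------------------------------- #
#  Hypothesized models
# ---------------------------------------------------------------------- #

def model_syntax(variant: str = "correct", scaling: str = "high") -> str:
    """Model text for the fitted model; scaling indicator listed first."""
    if scaling not in ("high", "low"):
        raise ValueError("scaling must be 'high' or 'low'")
    lines = []
    for j in range(5):
        base = 3 * j
        inds = [f"y{base + 1}", f"y{base + 2}", f"y{base + 3}"]
        if scaling == "low":
            inds = [inds[2], inds[0], inds[1]]
        lines.append(f"eta{j + 1} =~ " + " + ".join(inds))
    lines.append("eta3 ~ eta1 + eta2")
    if variant == "correct":
        lines.append("eta4 ~ eta1 + eta2 + eta3")
    elif variant == "misspecified":
        lines.append("eta4 ~ eta1 + eta2")
    else:
        raise ValueError("variant must be 'correct' or 'misspecified'")
    lines.append("eta5 ~ eta1 + eta2 + eta3 + eta4")
    return "\n".join(lines)


def true_parameter_values(model: ModelSpec, truth: SimTruth | None = None) -> dict[str, float]:
    """Population value of every free parameter under the fitted scaling.

    Fixing the scaling loading at 1 rescales each latent variable by its
    scaling indicator's standardized loading; free loadings, regression
    coefficients, and (co)variances transform accordingly.
    """
    truth = truth or simulation_truth()
    yi = {y: i for i, y in enumerate(truth.indicator_names)}
    fi = {f: i for i, f in enumerate(truth.factor_names)}
    lam_s = {f: truth.Lambda[yi[model.scaling[f]], fi[f]] for f in model.factors}
    vals: dict[str, float] = {}
    for name in model.theta1_names():
        if name.startswith("l_"):
            y, f = name[2:].split("~")
            vals[name] = truth.Lambda[yi[y], fi[f]] / lam_s[f]
        else:
            dv, iv = name[2:].split("~")
            vals[name] = truth.B[fi[dv], fi[iv]] * lam_s[dv] / lam_s[iv]
    for a, b in model.psi_entries():
        vals[f"psi_{a}~~{b}"] = truth.Psi[fi[a], fi[b]] * lam_s[a] * lam_s[b]
    for a, b in model.theta_entries():
        vals[f"theta_{a}~~{b}"] = truth.theta_diag[yi[a]] if a == b else 0.0
    return vals


def population_moments(truth: SimTruth | None = None) -> MixedMoments:
    """MixedMoments at the population implied covariance (n left at 0)."""
    truth = truth or simulation_truth()
    thr = {v: truth.thresholds for v in truth.indicator_names
           if truth.types[v] == "ordinal"}
    return MixedMoments(names=truth.indicator_names, types=dict(truth.types),
                        S=truth.implied_cov.copy(), thresholds=thr, n=0)


# ---------------------------------------------------------------------- #
#  Data generation
# ---------------------------------------------------------------------- #

def generate_dataset(n: int, seed: int, truth: SimTruth | None = None,
                     return_underlying: bool = False):
    """Draw a typed sample from the population model.

    Ordinal indicators are produced by cutting the standard-normal
    underlying variables at the population thresholds, coded 1..5.
    """
    truth = truth or simulation_truth()
    rng = np.random.default_rng(seed)
    m = len(truth.factor_names)
    zeta = rng.multivariate_normal(np.zeros(m), truth.Psi, size=n,
                                   method="cholesky")
    eta = np.linalg.solve(np.eye(m) - truth.B, zeta.T).T
    eps = rng.normal(size=(n, len(truth.indicator_names))) * np.sqrt(truth.theta_diag)
    ystar = eta @ truth.Lambda.T + eps
    data = {}
    for k, name in enumerate(truth.indicator_names):
        if truth.types[name] == "ordinal":
            data[name] = np.digitize(ystar[:, k], truth.thresholds) + 1
        else:
            data[name] = ystar[:, k]
    frame = pd.DataFrame(data)
    if return_underlying:
        return frame, dict(truth.types), ystar
    return frame, dict(truth.types)


# ---------------------------------------------------------------------- #
#  Outcome measures
# ---------------------------------------------------------------------- #

def summarize_bias(estimates: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """100 x median relative bias per parameter; zero-truth parameters -> NaN."""
    estimates = np.atleast_2d(np.asarray(estimates, float))
    truth = np.asarray(truth, float)
    out = np.full(truth.shape, np.nan)
    nz = truth != 0
    if (~nz).any():
        warnings.warn("parameters with zero population value excluded from "
                      "relative bias", stacklevel=2)
    out[nz] = 100.0 * np.median((estimates[:, nz] - truth[nz]) / truth[nz], axis=0)
    return out


def summarize_se_bias(estimates: np.ndarray, ses: np.ndarray):
    """SE relative bias against the trimmed Monte Carlo SD.

    Estimates outside [Q1 - 3 IQR, Q3 + 3 IQR] are trimmed; the SD of the
    survivors is the pseudo-true SE.  Returns (per-parameter 100 x median
    relative bias, per-parameter trimmed fraction).
    """
    estimates = np.atleast_2d(np.asarray(estimates, float))
    ses = np.atleast_2d(np.asarray(ses, float))
    R, P = estimates.shape
    if R < 10:
        raise ValueError("need at least 10 proper replications")
    bias = np.empty(P)
    frac = np.empty(P)
    for j in range(P):
        col = estimates[:, j]
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        keep = (col >= q1 - 3 * iqr) & (col <= q3 + 3 * iqr)
        if not keep.any():
            raise ValueError("all replications trimmed")
        pseudo = col[keep].std(ddof=1)
        bias[j] = 100.0 * np.median((ses[keep, j] - pseudo) / pseudo)
        frac[j] = 1.0 - keep.mean()
    return bias, frac


# ---------------------------------------------------------------------- #
#  Study runner
# ---------------------------------------------------------------------- #

@dataclass
class SimCondition:
    model_variant: str = "correct"        # correct | misspecified
    n: int = 200
    scaling: str = "high"                 # high | low
    estimator: str = "MIIV1"              # MIIV1 | MIIVall | DWLS
    replications: int = 100
    base_seed: int = 1

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.estimator not in ("MIIV1", "MIIVall", "DWLS"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class SimSummary:
    condition: SimCondition
    param_names: list[str]
    truth: np.ndarray
    pct_proper: float
    n_proper: int
    n_converged: int
    rel_bias: np.ndarray
    group_abs_bias: dict[str, float]
    se_bias: dict[str, np.ndarray] = field(default_factory=dict)
    trimmed_fraction: dict[str, float] = field(default_factory=dict)
    model_rejection: dict[str, float] = field(default_factory=dict)
    equation_rejection: dict[str, dict[str, float]] = field(default_factory=dict)
    estimates: np.ndarray | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [None if not np.isfinite(v) else float(v)
                                           for v in np.ravel(a)]
        return {
            "condition": vars(self.condition),
            "pct_proper": self.pct_proper,
            "n_proper": self.n_proper,
            "n_converged": self.n_converged,
            "param_names": self.param_names,
            "truth": arr(self.truth),
            "rel_bias": arr(self.rel_bias),
            "group_abs_bias": {k: float(v) for k, v in self.group_abs_bias.items()},
            "se_bias": {k: arr(v) for k, v in self.se_bias.items()},
            "trimmed_fraction": {k: float(v) for k, v in self.trimmed_fraction.items()},
            "model_rejection": {k: float(v) for k, v in self.model_rejection.items()},
            "equation_rejection": {k: {s: float(r) for s, r in v.items()}
                                   for k, v in self.equation_rejection.items()},
        }


_GROUPS = {"l_": "Lambda", "b_": "B", "psi_": "Psi", "theta_": "Theta"}
_EQ_STATS = ("F_sargan", "F", "F_tilde", "F_m", "F_tilde_m", "F_mv", "F_tilde_mv")


def _group_of(name: str) -> str:
    for prefix, grp in _GROUPS.items():
        if name.startswith(prefix):
            return grp
    return "other"


def prepare_condition(cond: SimCondition):
    """Parse the hypothesized model and precompute structural MIIV candidates."""
    truth = simulation_truth()
    model = parse_model(model_syntax(cond.model_variant, cond.scaling), truth.types)
    equations = l2o_transform(model)
    for eq in equations:
        find_miivs(model, eq)
    truth_vals = true_parameter_values(model, truth)
    return truth, model, equations, truth_vals


def run_condition(cond: SimCondition, keep_replications: bool = False) -> SimSummary:
    """Run one Monte Carlo cell and aggregate the outcome measures.

    Improper replications (non-convergence or non-PD covariance estimates)
    are excluded from bias and model-test aggregation; equation
    overidentification tests need only the closed-form first stage and are
    aggregated over all converged replications.
    """
    truth, model, eq_template, truth_vals = prepare_condition(cond)
    names = model.theta1_names() + model.theta2_names()
    truth_vec = np.array([truth_vals[nm] for nm in names])
    n1 = len(model.theta1_names())
    ests, ses_gen, ses_val, ses_t2 = [], [], [], []
    proper_flags, converged_flags = [], []
    model_rej = {"T_m": [], "T_mv": []}
    eq_rej: dict[str, dict[str, list[bool]]] = {}
    for rep in range(cond.replications):
        seed = cond.base_seed + rep
        frame, types = generate_dataset(cond.n, seed, truth)
        try:
            mom = build_moment_matrix(frame, types)
            ups = estimate_upsilon(frame, mom, "score_sandwich")
        except (ValueError, np.linalg.LinAlgError):
            converged_flags.append(False)
            proper_flags.append(False)
            continue
        if cond.estimator == "DWLS":
            full = fit_full_dwls(model, mom)
            converged_flags.append(full.converged)
            proper_flags.append(full.proper)
            if full.proper:
                ests.append(np.concatenate([full.theta1, full.theta2]))
                try:
                    mt = model_fit_tests(full, mom)
                    model_rej["T_m"].append(mt.p_m < 0.05)
                    model_rej["T_mv"].append(mt.p_mv < 0.05)
                except (ValueError, np.linalg.LinAlgError):
                    pass
            continue
        equations = copy.deepcopy(eq_template)
        strategy = "all" if cond.estimator == "MIIVall" else "n_extra"
        for eq in equations:
            select_miivs(eq, mom, strategy=strategy, n_extra=1)
        t1res = fit_theta1(mom, equations, ups)
        if any(f.theta1 is None for f in t1res.equations):
            converged_flags.append(False)
            proper_flags.append(False)
            continue
        converged_flags.append(True)
        report = equation_test_report(t1res, ups)
        for row in report.equations:
            if row["df"] <= 0:
                continue
            slot = eq_rej.setdefault(row["equation"],
                                     {s: [] for s in _EQ_STATS})
            for s in _EQ_STATS:
                p = row[f"{s}_p"]
                if np.isfinite(p):
                    slot[s].append(p < 0.05)
        full = fit_theta2(t1res.theta1, mom, model, weight="dwls")
        proper = full.converged and full.proper
        proper_flags.append(proper)
        if not proper:
            continue
        se2 = se_theta2(full, t1res.K_stacked, ups)
        ests.append(np.concatenate([full.theta1, full.theta2]))
        ses_gen.append(np.concatenate(
            [np.concatenate([f.se_general for f in t1res.equations]), se2]))
        ses_val.append(np.concatenate(
            [np.concatenate([f.se_valid for f in t1res.equations]), se2]))
        try:
            mt = model_fit_tests(full, mom, K_stacked=t1res.K_stacked)
            model_rej["T_m"].append(mt.p_m < 0.05)
            model_rej["T_mv"].append(mt.p_mv < 0.05)
        except (ValueError, np.linalg.LinAlgError):
            pass

    n_proper = sum(proper_flags)
    est_arr = np.array(ests) if ests else np.empty((0, len(names)))
    rel_bias = (summarize_bias(est_arr, truth_vec) if len(ests)
                else np.full(len(names), np.nan))
    groups: dict[str, list[float]] = {}
    for nm, rb in zip(names, rel_bias):
        if np.isfinite(rb):
            groups.setdefault(_group_of(nm), []).append(abs(rb))
    group_abs = {g: float(np.mean(v)) for g, v in groups.items()}
    se_bias, trim_frac = {}, {}
    if cond.estimator != "DWLS" and len(ests) >= 10:
        for label, ses in (("general", ses_gen), ("valid", ses_val)):
            b, f = summarize_se_bias(est_arr, np.array(ses))
            se_bias[label] = b
            trim_frac[label] = float(np.mean(f))
    summary = SimSummary(
        condition=cond, param_names=names, truth=truth_vec,
        pct_proper=100.0 * n_proper / cond.replications,
        n_proper=n_proper, n_converged=sum(converged_flags),
        rel_bias=rel_bias, group_abs_bias=group_abs,
        se_bias=se_bias, trimmed_fraction=trim_frac,
        model_rejection={k: float(np.mean(v)) if v else np.nan
                         for k, v in model_rej.items()},
        equation_rejection={eq: {s: float(np.mean(v)) if v else np.nan
                                 for s, v in slots.items()}
                            for eq, slots in eq_rej.items()},
        estimates=est_arr if keep_replications else None,
    )
    return summary
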