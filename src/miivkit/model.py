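"""Model representation, L2O transformation, and instrument search.

A structural equation model

    y* = Lambda eta + eps,      eta = B eta + zeta

is specified in a lavaan-like text syntax.  Every latent variable is given a
metric by fixing one loading to 1 (the *scaling indicator*).  Substituting
``eta_f = y*_{s(f)} - eps_{s(f)}`` rewrites the system as regressions among
observed (or underlying) variables only — the latent-to-observed (L2O)
transformation.  Each transformed equation carries a composite error that is
a known linear form in (eps, zeta), from which model-implied instrumental
variables (MIIVs) are found: observed variables whose model-implied
covariance with the composite error is structurally zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

VALID_TYPES = ("continuous", "ordinal", "binary")


class ModelSyntaxError(ValueError):
    """Raised when the model text cannot be parsed into a valid model."""


class UnderIdentifiedEquationError(ValueError):
    """Raised when an equation has fewer candidate MIIVs than regressors."""


@dataclass
class Equation:
    """One row of the L2O-transformed system.

    The composite error is stored symbolically: ``eps_terms`` maps an
    indicator name to a coefficient spec, ``zeta_terms`` maps a factor name
    likewise.  A spec is either a float (known coefficient) or a parameter
    name whose drawn/estimated value enters with a minus sign.
    """

    index: int
    kind: str                      # "measurement" | "latent"
    lhs: str                       # observed (or underlying) dependent variable
    rhs: list[str]                 # scaling indicators acting as regressors
    param_names: list[str]         # free theta1 parameters, aligned with rhs
    eps_terms: dict[str, object] = field(default_factory=dict)
    zeta_terms: dict[str, object] = field(default_factory=dict)
    miiv_candidates: list[str] | None = None
    miivs: list[str] | None = None

    @property
    def n_regressors(self) -> int:
        return len(self.rhs)

    @property
    def n_miivs(self) -> int:
        return len(self.miivs) if self.miivs is not None else 0


@dataclass
class ModelSpec:
    """Pattern matrices and variable metadata of a SEM model.

    Free entries of Lambda and B form ``theta1``; free entries of Psi and
    Theta form ``theta2``.  Diagonal Theta entries of ordinal/binary
    indicators are identification-constrained (the implied variance of the
    underlying variable is fixed at 1) and are excluded from theta2.
    """

    factors: list[str]
    indicators: list[str]
    loadings: dict[str, dict[str, float | None]]   # indicator -> factor -> fixed value or None (free)
    scaling: dict[str, str]                        # factor -> scaling indicator
    regressions: dict[str, list[str]]              # endogenous factor -> predictors
    error_covs: list[tuple[str, str]] = field(default_factory=list)
    factor_covs: list[tuple[str, str]] = field(default_factory=list)
    var_types: dict[str, str] = field(default_factory=dict)
    n_categories: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.indicators:
            self.var_types.setdefault(name, "continuous")
            t = self.var_types[name]
            if t not in VALID_TYPES:
                raise ModelSyntaxError(f"unknown variable type {t!r} for {name!r}")
            if t == "binary":
                self.n_categories.setdefault(name, 2)
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        for f in self.factors:
            inds = [y for y in self.indicators if f in self.loadings.get(y, {})]
            if not inds:
                raise ModelSyntaxError(f"factor {f!r} has no indicators")
            fixed_one = [y for y in inds if self.loadings[y][f] == 1.0]
            if len(fixed_one) != 1:
                raise ModelSyntaxError(
                    f"factor {f!r} must have exactly one scaling indicator, found {fixed_one}")
            if self.scaling[f] != fixed_one[0]:
                raise ModelSyntaxError(f"inconsistent scaling indicator for {f!r}")
            extra = [g for g in self.loadings[self.scaling[f]] if g != f]
            if extra:
                raise ModelSyntaxError(
                    f"scaling indicator {self.scaling[f]!r} of {f!r} may not load on {extra}")
        for dv, ivs in self.regressions.items():
            if dv not in self.factors:
                raise ModelSyntaxError(f"unknown latent variable {dv!r} in regression")
            for iv in ivs:
                if iv not in self.factors:
                    raise ModelSyntaxError(f"unknown latent variable {iv!r} in regression")
            if dv in ivs:
                raise ModelSyntaxError(f"{dv!r} cannot be regressed on itself")

    # ------------------------------------------------------------------ #
    @property
    def endogenous_factors(self) -> list[str]:
        return [f for f in self.factors if f in self.regressions]

    @property
    def exogenous_factors(self) -> list[str]:
        return [f for f in self.factors if f not in self.regressions]

    def is_discrete(self, name: str) -> bool:
        return self.var_types.get(name, "continuous") in ("ordinal", "binary")

    # -- parameter bookkeeping ----------------------------------------- #
    def theta1_names(self) -> list[str]:
        names: list[str] = []
        for eq in l2o_transform(self):
            names.extend(eq.param_names)
        return names

    def psi_entries(self) -> list[tuple[str, str]]:
        """Free (co)variance entries of Psi, variances first."""
        entries = [(f, f) for f in self.factors]
        exo = self.exogenous_factors
        for j, b in enumerate(exo):
            for a in exo[j + 1:]:
                entries.append((a, b))
        for a, b in self.factor_covs:
            if (a, b) not in entries and (b, a) not in entries:
                entries.append((a, b))
        return entries

    def theta_entries(self) -> list[tuple[str, str]]:
        """Free entries of Theta: continuous diagonals plus declared covariances."""
        entries = [(y, y) for y in self.indicators if not self.is_discrete(y)]
        entries.extend(self.error_covs)
        return entries

    def theta2_names(self) -> list[str]:
        names = [f"psi_{a}~~{b}" for a, b in self.psi_entries()]
        names += [f"theta_{a}~~{b}" for a, b in self.theta_entries()]
        return names

    def n_free_params(self) -> int:
        return len(self.theta1_names()) + len(self.theta2_names())

    # -- matrix assembly ------------------------------------------------ #
    def assemble(self, theta1: Mapping[str, float] | Sequence[float],
                 theta2: Mapping[str, float] | Sequence[float]):
        """Build numeric (Lambda, B, Psi, Theta) from free-parameter values.

        Diagonal Theta entries of discrete indicators are returned as NaN;
        they are solved downstream from the unit-variance restriction.
        """
        t1 = self._as_map(theta1, self.theta1_names())
        t2 = self._as_map(theta2, self.theta2_names())
        p, m = len(self.indicators), len(self.factors)
        yi = {y: i for i, y in enumerate(self.indicators)}
        fi = {f: i for i, f in enumerate(self.factors)}
        Lam = np.zeros((p, m))
        for y, facs in self.loadings.items():
            for f, val in facs.items():
                if val is not None:
                    Lam[yi[y], fi[f]] = val
                else:
                    Lam[yi[y], fi[f]] = t1[f"l_{y}~{f}"]
        B = np.zeros((m, m))
        for dv, ivs in self.regressions.items():
            for iv in ivs:
                B[fi[dv], fi[iv]] = t1[f"b_{dv}~{iv}"]
        Psi = np.zeros((m, m))
        for a, b in self.psi_entries():
            Psi[fi[a], fi[b]] = Psi[fi[b], fi[a]] = t2[f"psi_{a}~~{b}"]
        Th = np.zeros((p, p))
        for y in self.indicators:
            if self.is_discrete(y):
                Th[yi[y], yi[y]] = np.nan
        for a, b in self.theta_entries():
            Th[yi[a], yi[b]] = Th[yi[b], yi[a]] = t2[f"theta_{a}~~{b}"]
        return Lam, B, Psi, Th

    @staticmethod
    def _as_map(values, names):
        if isinstance(values, Mapping):
            return values
        values = np.asarray(values, dtype=float)
        if values.shape != (len(names),):
            raise ValueError(f"expected {len(names)} parameter values, got {values.shape}")
        return dict(zip(names, values))


# ---------------------------------------------------------------------- #
#  Parser
# ---------------------------------------------------------------------- #

def parse_model(spec_text: str, types: Mapping[str, str] | None = None,
                n_categories: Mapping[str, int] | None = None) -> ModelSpec:
    """Parse lavaan-style model syntax into a validated :class:`ModelSpec`.

    Measurement lines use ``factor =~ y1 + y2 + y3`` (first indicator is the
    scaling indicator unless another carries a ``1*`` prefix), latent
    regressions use ``lv ~ lv1 + lv2``, and ``a ~~ b`` frees a covariance
    (between indicator errors or between latent variables).
    """
    factors: list[str] = []
    indicators: list[str] = []
    loadings: dict[str, dict[str, float | None]] = {}
    scaling: dict[str, str] = {}
    regressions: dict[str, list[str]] = {}
    cov_lines: list[tuple[str, str]] = []

    for raw in spec_text.replace(";", "\n").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = (part.strip() for part in line.split("=~", 1))
            if not lhs:
                raise ModelSyntaxError(f"missing factor name in line {raw!r}")
            if lhs not in factors:
                factors.append(lhs)
            fixed_scaling = None
            listed: list[str] = []
            for term in rhs.split("+"):
                term = term.strip()
                if not term:
                    raise ModelSyntaxError(f"empty indicator in line {raw!r}")
                fixed = None
                if "*" in term:
                    coef, term = (t.strip() for t in term.split("*", 1))
                    fixed = float(coef)
                if term not in indicators:
                    indicators.append(term)
                loadings.setdefault(term, {})
                if lhs in loadings[term]:
                    raise ModelSyntaxError(f"duplicate loading of {term!r} on {lhs!r}")
                loadings[term][lhs] = fixed
                listed.append(term)
                if fixed == 1.0:
                    if fixed_scaling is not None:
                        raise ModelSyntaxError(f"two scaling indicators for factor {lhs!r}")
                    fixed_scaling = term
            if lhs in scaling and fixed_scaling not in (None, scaling[lhs]):
                raise ModelSyntaxError(f"two scaling indicators for factor {lhs!r}")
            if lhs not in scaling:
                chosen = fixed_scaling or listed[0]
                scaling[lhs] = chosen
                if loadings[chosen][lhs] is None:
                    loadings[chosen][lhs] = 1.0
        elif "~~" in line:
            a, b = (part.strip() for part in line.split("~~", 1))
            cov_lines.append((a, b))
        elif "~" in line:
            lhs, rhs = (part.strip() for part in line.split("~", 1))
            preds = [t.strip() for t in rhs.split("+")]
            regressions.setdefault(lhs, [])
            for pv in preds:
                if pv in regressions[lhs]:
                    raise ModelSyntaxError(f"duplicate predictor {pv!r} for {lhs!r}")
                regressions[lhs].append(pv)
        else:
            raise ModelSyntaxError(f"cannot parse line {raw!r}")

    known = set(factors) | set(indicators)
    error_covs, factor_covs = [], []
    for a, b in cov_lines:
        if a not in known or b not in known:
            raise ModelSyntaxError(f"unknown variable in covariance {a!r} ~~ {b!r}")
        if a in factors and b in factors:
            factor_covs.append((a, b))
        elif a in indicators and b in indicators:
            error_covs.append((a, b))
        else:
            raise ModelSyntaxError(f"covariance {a!r} ~~ {b!r} mixes latent and observed")
    for dv, ivs in regressions.items():
        for v in [dv] + ivs:
            if v not in factors:
                raise ModelSyntaxError(f"unknown latent variable {v!r} in regression")

    var_types = dict(types) if types else {}
    for name in list(var_types):
        if name not in indicators:
            var_types.pop(name)
    return ModelSpec(
        factors=factors, indicators=indicators, loadings=loadings,
        scaling=scaling, regressions=regressions, error_covs=error_covs,
        factor_covs=factor_covs, var_types=var_types,
        n_categories=dict(n_categories) if n_categories else {},
    )


# ---------------------------------------------------------------------- #
#  L2O transformation
# ---------------------------------------------------------------------- #

def l2o_transform(model: ModelSpec) -> list[Equation]:
    """Rewrite the model as regressions among observed/underlying variables.

    Produces one equation per nonscaling indicator (composite error
    ``eps_j - sum_f lambda_jf eps_{s(f)}``) and one per endogenous latent
    variable (composite error ``zeta_i + eps_{s(i)} - sum_k b_ik eps_{s(k)}``).
    Regressors are scaling indicators only.
    """
    eqs: list[Equation] = []
    scaling_set = set(model.scaling.values())
    for y in model.indicators:
        if y in scaling_set:
            continue
        facs = list(model.loadings[y].keys())
        rhs, params = [], []
        eps_terms: dict[str, object] = {y: 1.0}
        for f in facs:
            val = model.loadings[y][f]
            if val is None:
                rhs.append(model.scaling[f])
                pname = f"l_{y}~{f}"
                params.append(pname)
                eps_terms[model.scaling[f]] = pname
            else:
                raise ModelSyntaxError(
                    f"fixed nonscaling loading {y!r} on {f!r} is not supported")
        eqs.append(Equation(index=len(eqs), kind="measurement", lhs=y, rhs=rhs,
                            param_names=params, eps_terms=eps_terms))
    for f in model.endogenous_factors:
        s_f = model.scaling[f]
        rhs, params = [], []
        eps_terms = {s_f: 1.0}
        for pred in model.regressions[f]:
            rhs.append(model.scaling[pred])
            pname = f"b_{f}~{pred}"
            params.append(pname)
            eps_terms[model.scaling[pred]] = pname
        eqs.append(Equation(index=len(eqs), kind="latent", lhs=s_f, rhs=rhs,
                            param_names=params, eps_terms=eps_terms,
                            zeta_terms={f: 1.0}))
    return eqs


# ---------------------------------------------------------------------- #
#  MIIV search
# ---------------------------------------------------------------------- #

def _random_draw(model: ModelSpec, rng: np.random.Generator):
    """One admissible random parameter point (free parameters in U(0.2, 0.8))."""
    t1 = {name: rng.uniform(0.2, 0.8) for name in model.theta1_names()}
    t2: dict[str, float] = {}
    for a, b in model.psi_entries():
        if a == b:
            t2[f"psi_{a}~~{b}"] = rng.uniform(0.5, 1.5)
    for a, b in model.psi_entries():
        if a != b:
            va, vb = t2[f"psi_{a}~~{a}"], t2[f"psi_{b}~~{b}"]
            t2[f"psi_{a}~~{b}"] = rng.uniform(0.1, 0.3) * np.sqrt(va * vb)
    th_diag = {y: rng.uniform(0.3, 1.0) for y in model.indicators}
    for a, b in model.theta_entries():
        if a == b:
            t2[f"theta_{a}~~{b}"] = th_diag[a]
        else:
            t2[f"theta_{a}~~{b}"] = rng.uniform(0.1, 0.3) * np.sqrt(th_diag[a] * th_diag[b])
    Lam, B, Psi, Th = model.assemble(t1, t2)
    # discrete diagonals are free to take any positive value for the purpose
    # of zero-structure detection
    for i, y in enumerate(model.indicators):
        if model.is_discrete(y):
            Th[i, i] = th_diag[y]
    return t1, Lam, B, Psi, Th


def _error_cov_with_observed(model: ModelSpec, eq: Equation, t1, Lam, B, Psi, Th):
    """cov(y*_m, e_j) for every observed variable m, at one parameter draw."""
    p, m = Lam.shape
    A = np.linalg.inv(np.eye(m) - B)
    cov_y_eps = Th                      # cov(y*, eps) = Theta
    cov_y_zeta = Lam @ A @ Psi          # cov(y*, zeta)
    yi = {y: i for i, y in enumerate(model.indicators)}
    fi = {f: i for i, f in enumerate(model.factors)}
    out = np.zeros(p)
    for var, spec in eq.eps_terms.items():
        coef = spec if isinstance(spec, float) else -t1[spec]
        out += coef * cov_y_eps[:, yi[var]]
    for fac, spec in eq.zeta_terms.items():
        coef = spec if isinstance(spec, float) else -t1[spec]
        out += coef * cov_y_zeta[:, fi[fac]]
    return out


def find_miivs(model: ModelSpec, eq: Equation, n_draws: int = 5,
               tol: float = 1e-10, seed: int = 20210607) -> list[str]:
    """Candidate MIIVs: observed variables with structurally zero error covariance.

    The zero structure is detected numerically: the model-implied covariance
    between every observed variable and the equation's composite error is
    evaluated at ``n_draws`` independent admissible parameter points; a
    candidate must satisfy ``|cov| < tol`` at all of them.  A regressor that
    is uncorrelated with the composite error may serve as its own instrument.
    """
    rng = np.random.default_rng(seed)
    ok = np.ones(len(model.indicators), dtype=bool)
    for _ in range(n_draws):
        t1, Lam, B, Psi, Th = _random_draw(model, rng)
        cov = _error_cov_with_observed(model, eq, t1, Lam, B, Psi, Th)
        ok &= np.abs(cov) < tol
    cands = [y for y, good in zip(model.indicators, ok) if good and y != eq.lhs]
    if len(cands) < eq.n_regressors:
        raise UnderIdentifiedEquationError(
            f"equation for {eq.lhs!r} has {len(cands)} candidate MIIVs but "
            f"{eq.n_regressors} regressors")
    eq.miiv_candidates = cands
    return cands


# ---------------------------------------------------------------------- #
#  Weak-instrument diagnostic and instrument selection
# ---------------------------------------------------------------------- #

def shea_partial_r2(moments, eq_or_rhs, miivs: Sequence[str] | None = None) -> np.ndarray:
    """Shea's partial R^2 of every right-hand regressor, from moment blocks.

    Each regressor is residualized on the other regressors; its first-stage
    instrument projection is residualized on the other regressors'
    projections; the statistic is the squared correlation of the two
    residuals.  All second moments are read off the moment matrix S, so the
    diagnostic is available for polychoric/polyserial entries where raw
    underlying data do not exist.
    """
    if isinstance(eq_or_rhs, Equation):
        z_names = list(eq_or_rhs.rhs)
        v_names = list(miivs if miivs is not None else
                       (eq_or_rhs.miivs or eq_or_rhs.miiv_candidates))
    else:
        z_names = list(eq_or_rhs)
        v_names = list(miivs)
    if len(v_names) < len(z_names):
        raise ValueError("need at least as many instruments as regressors")
    S_zz = moments.block(z_names, z_names)
    S_vv = moments.block(v_names, v_names)
    S_vz = moments.block(v_names, z_names)
    try:
        Szzhat = S_vz.T @ np.linalg.solve(S_vv, S_vz)   # cov of projected regressors
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular instrument moment block S_vv") from exc
    K = len(z_names)
    out = np.empty(K)
    for k in range(K):
        others = [i for i in range(K) if i != k]
        w_r = np.zeros(K)
        w_r[k] = 1.0
        w_u = np.zeros(K)
        w_u[k] = 1.0
        if others:
            A_r = np.linalg.solve(S_zz[np.ix_(others, others)], S_zz[others, k])
            A_u = np.linalg.solve(Szzhat[np.ix_(others, others)], Szzhat[others, k])
            w_r[others] = -A_r
            w_u[others] = -A_u
        var_r = w_r @ S_zz @ w_r
        var_u = w_u @ Szzhat @ w_u
        cov_ru = w_r @ Szzhat @ w_u
        if var_r <= 0 or var_u <= 0:
            raise np.linalg.LinAlgError("singular regressor moment block S_zz")
        out[k] = cov_ru ** 2 / (var_r * var_u)
    return np.clip(out, 0.0, 1.0)


_EXHAUSTIVE_CAP = 100_000


def select_miivs(eq: Equation, moments=None, strategy="all", n_extra: int = 1) -> list[str]:
    """Choose the instrument set for one equation.

    ``strategy="all"`` keeps the whole candidate set; ``strategy="n_extra"``
    keeps ``K_j + n_extra`` candidates chosen to maximize the minimum Shea
    partial R^2 over the regressors, ties broken by data-column order.
    """
    if eq.miiv_candidates is None:
        raise ValueError("candidate MIIVs not computed; call find_miivs first")
    cands = list(eq.miiv_candidates)
    if strategy == "all":
        eq.miivs = cands
        return cands
    if strategy != "n_extra":
        raise ValueError(f"unknown strategy {strategy!r}")
    size = eq.n_regressors + n_extra
    if size >= len(cands):
        if size > len(cands):
            warnings.warn(
                f"requested {size} MIIVs but only {len(cands)} candidates for "
                f"equation {eq.lhs!r}; falling back to all", stacklevel=2)
        eq.miivs = cands
        return cands
    if moments is None:
        raise ValueError("moment matrix required for n_extra selection")
    from math import comb
    if comb(len(cands), size) <= _EXHAUSTIVE_CAP:
        best, best_val = None, -np.inf
        for subset in itertools.combinations(cands, size):
            try:
                val = shea_partial_r2(moments, eq.rhs, list(subset)).min()
            except np.linalg.LinAlgError:
                continue              # rank-deficient projection: unusable subset
            if val > best_val + 1e-15:
                best, best_val = list(subset), val
        if best is None:
            eq.miivs = cands
            return cands
        eq.miivs = best
        return best
    # greedy forward selection for very large candidate pools
    chosen = []
    remaining = list(cands)
    while len(chosen) < size:
        best, best_val = None, -np.inf
        for c in remaining:
            trial = chosen + [c]
            if len(trial) < eq.n_regressors:
                val = 0.0
            else:
                try:
                    val = shea_partial_r2(moments, eq.rhs, trial).min()
                except np.linalg.LinAlgError:
                    val = -np.inf
            if val > best_val + 1e-15:
                best, best_val = c, val
        chosen.append(best)
        remaining.remove(best)
    eq.miivs = chosen
    return chosen
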