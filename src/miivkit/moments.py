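"""Mixed Pearson/polychoric/polyserial moment matrix estimation.

For continuous variable pairs the moment matrix S holds sample covariances
(divisor n).  A discrete (ordinal or binary) variable is modelled as a
thresholded standard-normal underlying variable, so its diagonal entry is
fixed at 1; discrete-discrete entries are polychoric correlations and
mixed entries are polyserial correlations scaled by the standard deviation
of the continuous member.  Correlations are estimated by the two-step
method: thresholds from the univariate margins, then one-dimensional
maximum likelihood for the correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

RHO_BOUND = 1.0 - 1e-6


# ---------------------------------------------------------------------- #
#  Bivariate normal rectangle probabilities
# ---------------------------------------------------------------------- #

def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses Owen's T representation, which is fully vectorized:
    Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, ah) - T(k, ak) - c.
    """
    h = np.atleast_1d(np.asarray(h, dtype=float)).copy()
    k = np.atleast_1d(np.asarray(k, dtype=float)).copy()
    h, k = np.broadcast_arrays(h, k)
    h, k = h.copy(), k.copy()
    out = np.empty(h.shape)
    lo = np.isneginf(h) | np.isneginf(k)
    hi_h, hi_k = np.isposinf(h), np.isposinf(k)
    out[lo] = 0.0
    out[hi_k & ~lo & ~hi_h] = special.ndtr(h[hi_k & ~lo & ~hi_h])
    out[hi_h & ~lo & ~hi_k] = special.ndtr(k[hi_h & ~lo & ~hi_k])
    out[hi_h & hi_k] = 1.0
    fin = np.isfinite(h) & np.isfinite(k)
    if fin.any():
        rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))
        hf, kf = h[fin], k[fin]
        # nudge exact zeros so the Owen's T arguments stay finite
        hf = np.where(hf == 0.0, 1e-13, hf)
        kf = np.where(kf == 0.0, 1e-13, kf)
        d = np.sqrt(1.0 - rho * rho)
        ah = (kf - rho * hf) / (hf * d)
        ak = (hf - rho * kf) / (kf * d)
        c = np.where(hf * kf < 0, 0.5, 0.0)
        val = (0.5 * (special.ndtr(hf) + special.ndtr(kf))
               - special.owens_t(hf, ah) - special.owens_t(kf, ak) - c)
        out[fin] = np.clip(val, 0.0, 1.0)
    return out


def cell_probabilities(tau_a: np.ndarray, tau_b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate-normal cells defined by thresholds."""
    ca = np.concatenate([[-np.inf], np.asarray(tau_a, float), [np.inf]])
    cb = np.concatenate([[-np.inf], np.asarray(tau_b, float), [np.inf]])
    H, K = np.meshgrid(ca, cb, indexing="ij")
    G = bvn_cdf(H.ravel(), K.ravel(), rho).reshape(H.shape)
    cells = G[1:, 1:] - G[:-1, 1:] - G[1:, :-1] + G[:-1, :-1]
    return np.clip(cells, 1e-300, 1.0)


# ---------------------------------------------------------------------- #
#  Thresholds
# ---------------------------------------------------------------------- #

def estimate_thresholds(category_counts) -> np.ndarray:
    """Thresholds as standard-normal quantiles of cumulative category proportions.

    Categories with zero counts are merged into their neighbours (their
    threshold would coincide with an adjacent one), with a warning.
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need at least two categories")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty count vector")
    if (counts == 0).any():
        warnings.warn("zero-count categories merged into neighbours", stacklevel=2)
        counts = counts[counts > 0]
        if counts.size < 2:
            raise ValueError("fewer than two populated categories")
    cum = np.cumsum(counts)[:-1] / total
    return stats.norm.ppf(cum)


# ---------------------------------------------------------------------- #
#  Polychoric correlation
# ---------------------------------------------------------------------- #

@dataclass
class CorrResult:
    rho: float
    thresholds_row: np.ndarray
    thresholds_col: np.ndarray
    boundary: bool = False


def _polychoric_negloglik(rho, table, tau_a, tau_b):
    return -(table * np.log(cell_probabilities(tau_a, tau_b, rho))).sum()


def polychoric_corr(table) -> CorrResult:
    """Two-step polychoric correlation from a two-way contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2 or table.sum() <= 0:
        raise ValueError("need a two-way table with at least 2x2 categories")
    tau_a = estimate_thresholds(table.sum(axis=1))
    tau_b = estimate_thresholds(table.sum(axis=0))
    tab = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    res = optimize.minimize_scalar(
        _polychoric_negloglik, args=(tab, tau_a, tau_b),
        bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-9})
    rho = float(res.x)
    if not np.isfinite(res.fun):
        raise FloatingPointError("non-finite polychoric likelihood")
    boundary = abs(rho) >= 1.0 - 1e-5
    if boundary:
        rho = np.sign(rho) * RHO_BOUND
    return CorrResult(rho, tau_a, tau_b, boundary)


# ---------------------------------------------------------------------- #
#  Polyserial correlation
# ---------------------------------------------------------------------- #

def _polyserial_negloglik(rho, z, y_codes, tau):
    """Negative conditional log-likelihood of ordinal y given standardized x."""
    cut = np.concatenate([[-np.inf], tau, [np.inf]])
    denom = np.sqrt(1.0 - rho * rho)
    upper = (cut[y_codes + 1] - rho * z) / denom
    lower = (cut[y_codes] - rho * z) / denom
    p = special.ndtr(upper) - special.ndtr(lower)
    return -np.log(np.clip(p, 1e-300, 1.0)).sum()


def polyserial_corr(x, y) -> CorrResult:
    """Two-step polyserial correlation of a continuous x with an ordinal y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.std() <= 0:
        raise ValueError("continuous variable has zero variance")
    cats, y_codes = np.unique(y, return_inverse=True)
    if cats.size < 2:
        raise ValueError("ordinal variable has a single category")
    tau = estimate_thresholds(np.bincount(y_codes))
    z = (x - x.mean()) / x.std()
    res = optimize.minimize_scalar(
        _polyserial_negloglik, args=(z, y_codes, tau),
        bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-9})
    rho = float(res.x)
    if not np.isfinite(res.fun):
        raise FloatingPointError("non-finite polyserial likelihood")
    boundary = abs(rho) >= 1.0 - 1e-5
    if boundary:
        rho = np.sign(rho) * RHO_BOUND
    return CorrResult(rho, np.array([]), tau, boundary)


# ---------------------------------------------------------------------- #
#  The moment matrix container
# ---------------------------------------------------------------------- #

@dataclass
class MixedMoments:
    """Moment matrix S with metadata and (optionally) its asymptotic covariance.

    ``s`` is the vector of nonredundant free entries: all below-diagonal
    entries plus the diagonal entries of continuous variables, in
    column-major lower-triangle order.  Diagonal entries of discrete
    variables are fixed at 1 and are excluded.
    """

    names: list[str]
    types: dict[str, str]
    S: np.ndarray
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    n: int = 0
    upsilon: np.ndarray | None = None
    upsilon_method: str | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.names)
        if self.S.shape != (p, p):
            raise ValueError("S shape does not match variable list")
        self._pos = {name: i for i, name in enumerate(self.names)}

    # -- free-entry bookkeeping ---------------------------------------- #
    def is_discrete(self, name: str) -> bool:
        return self.types.get(name, "continuous") in ("ordinal", "binary")

    def free_entries(self) -> list[tuple[int, int]]:
        p = len(self.names)
        out = []
        for j in range(p):
            for i in range(j, p):
                if i == j and self.is_discrete(self.names[i]):
                    continue
                out.append((i, j))
        return out

    def entry_index(self) -> dict[tuple[int, int], int]:
        idx = {}
        for k, (i, j) in enumerate(self.free_entries()):
            idx[(i, j)] = k
            idx[(j, i)] = k
        return idx

    @property
    def s(self) -> np.ndarray:
        return np.array([self.S[i, j] for i, j in self.free_entries()])

    def set_s(self, s_vec: np.ndarray) -> None:
        """Rebuild S from a free-entry vector (discrete diagonals stay 1)."""
        entries = self.free_entries()
        s_vec = np.asarray(s_vec, dtype=float)
        if s_vec.shape != (len(entries),):
            raise ValueError("free-entry vector has wrong length")
        for (i, j), v in zip(entries, s_vec):
            self.S[i, j] = self.S[j, i] = v

    def block(self, rows, cols) -> np.ndarray:
        r = [self._pos[name] for name in rows]
        c = [self._pos[name] for name in cols]
        return self.S[np.ix_(r, c)]

    def scalar(self, a: str, b: str) -> float:
        return float(self.S[self._pos[a], self._pos[b]])

    # -- export --------------------------------------------------------- #
    def to_frames(self):
        """S as a DataFrame plus a JSON-ready metadata dict."""
        S_df = pd.DataFrame(self.S, index=self.names, columns=self.names)
        meta = {
            "n": int(self.n),
            "types": {k: self.types.get(k, "continuous") for k in self.names},
            "thresholds": {k: list(map(float, v)) for k, v in self.thresholds.items()},
            "s_order": [[self.names[i], self.names[j]] for i, j in self.free_entries()],
            "upsilon_method": self.upsilon_method,
        }
        return S_df, meta


def recode_ordinal(series: pd.Series) -> pd.Series:
    """Recode an ordinal column to consecutive integer codes starting at 1."""
    cats = np.unique(series.dropna().to_numpy())
    mapping = {c: i + 1 for i, c in enumerate(cats)}
    return series.map(mapping)


def build_moment_matrix(data: pd.DataFrame, types: dict[str, str]) -> MixedMoments:
    """Estimate the mixed moment matrix S from a typed rectangular table.

    Continuous-continuous entries are sample covariances (divisor n),
    discrete diagonals are 1, mixed entries are polyserial correlations
    scaled by the continuous standard deviation, and discrete-discrete
    entries are polychoric correlations.  Listwise deletion is applied.
    """
    names = list(data.columns)
    for name in names:
        if name not in types:
            raise KeyError(f"no type declaration for column {name!r}")
    clean = data.dropna()
    dropped = len(data) - len(clean)
    if dropped:
        logger.info("listwise deletion removed %d of %d rows", dropped, len(data))
    n = len(clean)
    if n < 3:
        raise ValueError("fewer than 3 complete cases")

    p = len(names)
    discrete = [types[v] in ("ordinal", "binary") for v in names]
    cols = {}
    codes = {}
    thresholds = {}
    for v, disc in zip(names, discrete):
        x = clean[v].to_numpy()
        if disc:
            cats, cd = np.unique(x, return_inverse=True)
            if cats.size < 2:
                raise ValueError(f"discrete column {v!r} has a single category")
            codes[v] = cd
            thresholds[v] = estimate_thresholds(np.bincount(cd))
        else:
            x = np.asarray(x, dtype=float)
            if x.std() <= 0:
                raise ValueError(f"constant continuous column {v!r}")
            cols[v] = x - x.mean()

    S = np.eye(p)
    for j in range(p):
        for i in range(j, p):
            a, b = names[i], names[j]
            if i == j:
                if not discrete[i]:
                    S[i, i] = cols[a] @ cols[a] / n
                continue
            if not discrete[i] and not discrete[j]:
                S[i, j] = S[j, i] = cols[a] @ cols[b] / n
            elif discrete[i] and discrete[j]:
                tab = np.zeros((codes[a].max() + 1, codes[b].max() + 1))
                np.add.at(tab, (codes[a], codes[b]), 1.0)
                S[i, j] = S[j, i] = polychoric_corr(tab).rho
            else:
                cont, disc_v = (a, b) if not discrete[i] else (b, a)
                rho = polyserial_corr(clean[cont].to_numpy(), codes[disc_v]).rho
                sd = np.sqrt(cols[cont] @ cols[cont] / n)
                S[i, j] = S[j, i] = rho * sd
    return MixedMoments(names=names, types=dict(types), S=S,
                        thresholds=thresholds, n=n)
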