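"""Polychoric correlations, probit thresholds and reliability coefficients.

Two ordinal items are modelled as discretizations of a standard bivariate
normal pair; the polychoric correlation is the latent correlation that
maximizes the likelihood of the observed 3x3 contingency table given
thresholds estimated from the univariate margins (the usual two-step
estimator, matching the convention of diagonally weighted least squares
software). The module also supplies the asymptotic covariance matrix of
the full moment vector (thresholds + correlations), obtained from
per-person influence functions with the two-step threshold correction;
this feeds the weight matrix and the robust test-statistic adjustment of
the CFA engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import norm

from .sdq_data import MISSING, SCALES, ItemResponseMatrix, scale_items

try:  # sklearn-style estimator surface; the math does not depend on it
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

_CLIP = 10.0          # treat |z| > 10 as +-infinity in bivariate rectangles
_RHO_BOUND = 0.999    # hard clamp for the polychoric estimate
_PMIN = 1e-12


def bvn_cdf(h, k, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's T formulation; vectorized over h and k. Arguments beyond +-10
    are treated as infinite.
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    rho = float(np.clip(rho, -0.999999, 0.999999))
    # nudge exact zeros so the Owen's-T slope arguments are well defined
    h = np.where(np.abs(h) < 1e-13, 1e-13, h)
    k = np.where(np.abs(k) < 1e-13, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    delta = np.where(h * k > 0, 0.0, 0.5)
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - delta
    return np.clip(val, 0.0, 1.0)


def cell_probabilities(tau_row: np.ndarray, tau_col: np.ndarray,
                       rho: float) -> np.ndarray:
    """3x3 (or ragged) cell probabilities from per-margin thresholds."""
    er = np.concatenate(([-_CLIP], np.asarray(tau_row, float), [_CLIP]))
    ec = np.concatenate(([-_CLIP], np.asarray(tau_col, float), [_CLIP]))
    C = bvn_cdf(er[:, None], ec[None, :], rho)
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(P, _PMIN, 1.0)


def estimate_thresholds(category_counts) -> np.ndarray:
    """Probit thresholds from a 3-vector of category counts.

    tau_k = Phi^{-1}(cumulative proportion through category k); boundary
    proportions are clamped to [1/(2n), 1 - 1/(2n)] before the inverse CDF.
    """
    counts = np.asarray(category_counts, dtype=float)
    n = counts.sum()
    if counts.size < 2 or n <= 0:
        raise ValueError("need positive counts over at least two categories")
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    return ndtri(cum)


def _table_nll(table: np.ndarray, tau_r: np.ndarray, tau_c: np.ndarray):
    def nll(rho: float) -> float:
        P = cell_probabilities(tau_r, tau_c, rho)
        return -float(np.sum(table * np.log(P)))
    return nll


def polychoric_corr(cross_tab, thresholds: tuple | None = None
                    ) -> tuple[float, float]:
    """Two-step polychoric correlation and its asymptotic variance.

    Thresholds come from the table margins unless supplied; the correlation
    maximizes the bivariate-normal likelihood of the cell counts by bounded
    scalar minimization on (-0.999, 0.999). The variance is the inverse
    negative second derivative of the profile log-likelihood (numeric, step
    1e-4); it is +inf when the estimate sits on the clamp.
    """
    T = np.asarray(cross_tab, dtype=float)
    if not _usable(T):
        raise ValueError("need observations in >=2 rows and >=2 columns")
    if thresholds is None:
        # collapse empty categories before estimating margins
        T = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
        tau_r = estimate_thresholds(T.sum(axis=1))
        tau_c = estimate_thresholds(T.sum(axis=0))
    else:
        # fixed thresholds: keep the full table (empty cells contribute
        # nothing to the log-likelihood)
        tau_r, tau_c = thresholds
    nll = _table_nll(T, tau_r, tau_c)
    res = minimize_scalar(nll, bounds=(-_RHO_BOUND, _RHO_BOUND),
                          method="bounded", options={"xatol": 1e-8})
    rho = float(res.x)
    h = 1e-4
    if abs(rho) >= _RHO_BOUND - 1e-6:
        return float(np.clip(rho, -_RHO_BOUND, _RHO_BOUND)), float("inf")
    d2 = (nll(rho + h) - 2.0 * nll(rho) + nll(rho - h)) / (h * h)
    avar = 1.0 / d2 if d2 > 0 else float("inf")
    return rho, avar


@dataclass
class PolychoricSummary:
    """Univariate thresholds, polychoric matrix and moment (co)variances."""

    items: tuple[str, ...]
    n: int
    thresholds: np.ndarray          # n_items x 2
    threshold_var: np.ndarray       # n_items x 2
    corr: np.ndarray                # n_items x n_items
    corr_var: np.ndarray            # profile-likelihood variance per entry
    pair_n: np.ndarray              # pairwise-complete n per entry
    gamma: np.ndarray | None = None  # acov of [thresholds..., corrs...]
    excluded: list = field(default_factory=list)
    n_pd_repairs: int = 0

    @property
    def pair_order(self) -> list[tuple[int, int]]:
        p = len(self.items)
        return [(i, j) for i in range(p) for j in range(i + 1, p)]

    def moment_vector(self) -> np.ndarray:
        """Stacked sample moments: thresholds item-major, then corr pairs."""
        taus = self.thresholds.ravel()
        rhos = np.array([self.corr[i, j] for i, j in self.pair_order])
        return np.concatenate([taus, rhos])

    def moment_variances(self) -> np.ndarray:
        """Diagonal of the asymptotic covariance of the moment vector."""
        if self.gamma is not None:
            return np.diag(self.gamma).copy()
        tv = self.threshold_var.ravel()
        rv = np.array([self.corr_var[i, j] for i, j in self.pair_order])
        return np.concatenate([tv, rv])


def _nearest_pd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def _moment_acov(resp: np.ndarray, thresholds: np.ndarray,
                 corr: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of [thresholds, polychoric correlations].

    Per-person influence functions: thresholds use the inverse-CDF delta
    method; each correlation uses the implicit-function expansion of its
    score equation around the fitted value, including the propagation of
    threshold estimation error (two-step correction). Missing cells
    contribute zero influence, rescaled by the pairwise-complete fraction.
    """
    n, p = resp.shape
    obs = resp != MISSING
    n_cols = 2 * p + p * (p - 1) // 2
    IF = np.zeros((n, n_cols))

    # threshold influence columns and per-category lookup values
    tau_if = np.zeros((p, 2, 3))  # item, threshold, category value
    for i in range(p):
        ni = obs[:, i].sum()
        for k in range(2):
            tk = thresholds[i, k]
            Pk = ndtr(tk)
            phi = norm.pdf(tk)
            vals = (np.array([1.0, 1.0, 1.0]) * (np.arange(3) <= k) - Pk) / phi
            tau_if[i, k] = vals
            col = np.zeros(n)
            col[obs[:, i]] = vals[resp[obs[:, i], i]] * (n / ni)
            IF[:, 2 * i + k] = col

    def score_cells(tau_i, tau_j, rho, h=1e-5):
        Pp = np.log(cell_probabilities(tau_i, tau_j, rho + h))
        Pm = np.log(cell_probabilities(tau_i, tau_j, rho - h))
        return (Pp - Pm) / (2 * h)

    col_idx = 2 * p
    for i in range(p):
        for j in range(i + 1, p):
            both = obs[:, i] & obs[:, j]
            nij = both.sum()
            rho = corr[i, j]
            if not np.isfinite(rho) or nij == 0:
                col_idx += 1
                continue
            ti, tj = thresholds[i], thresholds[j]
            phat = np.zeros((3, 3))
            np.add.at(phat, (resp[both, i], resp[both, j]), 1.0)
            phat /= nij
            psi = score_cells(ti, tj, rho)

            def gbar(tau_i, tau_j, r):
                return float(np.sum(phat * score_cells(tau_i, tau_j, r)))

            h = 1e-4
            A = -(gbar(ti, tj, rho + h) - gbar(ti, tj, rho - h)) / (2 * h)
            if A <= 0:
                col_idx += 1
                continue
            # derivatives of the score equation w.r.t. the four thresholds
            B = np.zeros((2, 2))  # (which item, which threshold)
            for k in range(2):
                e = np.zeros(2); e[k] = h
                B[0, k] = (gbar(ti + e, tj, rho) - gbar(ti - e, tj, rho)) / (2 * h)
                B[1, k] = (gbar(ti, tj + e, rho) - gbar(ti, tj - e, rho)) / (2 * h)
            col = np.zeros(n)
            col[both] = psi[resp[both, i], resp[both, j]] * (n / nij)
            for k in range(2):
                col += B[0, k] * IF[:, 2 * i + k]
                col += B[1, k] * IF[:, 2 * j + k]
            IF[:, col_idx] = col / A
            col_idx += 1

    IFc = IF - IF.mean(axis=0, keepdims=True)
    return (IFc.T @ IFc) / (n * (n - 1))


class PolychoricMatrix(BaseEstimator):
    """Polychoric correlation matrix estimator for an ordinal item battery.

    Parameters
    ----------
    compute_acov : bool, default True
        Also compute the full asymptotic covariance of the moment vector
        (needed by the DWLS fit machinery).
    pd_repair : bool, default True
        Eigenvalue-clip the matrix to the nearest positive definite
        correlation matrix if it is indefinite (count logged in
        ``n_pd_repairs_``).

    Fitted attributes: ``thresholds_``, ``threshold_var_``, ``correlation_``,
    ``corr_var_``, ``pair_n_``, ``gamma_``, ``excluded_``, ``summary_``.
    """

    def __init__(self, compute_acov: bool = True, pd_repair: bool = True):
        self.compute_acov = compute_acov
        self.pd_repair = pd_repair

    def fit(self, X, y=None, items: tuple[str, ...] | None = None):
        resp = np.asarray(X)
        if np.issubdtype(resp.dtype, np.floating):
            resp = np.where(np.isnan(resp), MISSING, resp)
        resp = resp.astype(np.int64)
        n, p = resp.shape
        if p < 2:
            raise ValueError("need at least two items")
        items = tuple(items) if items is not None else tuple(
            f"item{i}" for i in range(p))
        obs = resp != MISSING

        thresholds = np.full((p, 2), np.nan)
        tvar = np.full((p, 2), np.nan)
        excluded = []
        for i in range(p):
            vals = resp[obs[:, i], i]
            counts = np.bincount(vals, minlength=3).astype(float)
            if (counts > 0).sum() < 2:
                excluded.append(items[i])
                continue
            ni = counts.sum()
            thresholds[i] = estimate_thresholds(counts)
            cum = np.clip(np.cumsum(counts)[:-1] / ni,
                          1 / (2 * ni), 1 - 1 / (2 * ni))
            tvar[i] = cum * (1 - cum) / (ni * norm.pdf(thresholds[i]) ** 2)

        corr = np.eye(p)
        cvar = np.zeros((p, p))
        pair_n = np.zeros((p, p), dtype=np.int64)
        np.fill_diagonal(pair_n, obs.sum(axis=0))
        for i in range(p):
            if items[i] in excluded:
                corr[i, :] = corr[:, i] = np.nan
                corr[i, i] = 1.0
                continue
            for j in range(i + 1, p):
                if items[j] in excluded:
                    continue
                both = obs[:, i] & obs[:, j]
                pair_n[i, j] = pair_n[j, i] = both.sum()
                tab = np.zeros((3, 3))
                np.add.at(tab, (resp[both, i], resp[both, j]), 1.0)
                rho, av = polychoric_corr(
                    tab, thresholds=(thresholds[i], thresholds[j])) \
                    if _usable(tab) else (np.nan, np.nan)
                corr[i, j] = corr[j, i] = rho
                cvar[i, j] = cvar[j, i] = av

        n_rep = 0
        good = [i for i in range(p) if items[i] not in excluded]
        sub = corr[np.ix_(good, good)]
        if self.pd_repair and np.isfinite(sub).all():
            if np.linalg.eigvalsh(sub).min() <= 0:
                corr[np.ix_(good, good)] = _nearest_pd(sub)
                n_rep = 1

        if excluded:
            warnings.warn(f"items with a single observed category excluded: "
                          f"{excluded}")
        gamma = None
        if self.compute_acov and not excluded:
            gamma = _moment_acov(resp, thresholds, corr)

        self.thresholds_ = thresholds
        self.threshold_var_ = tvar
        self.correlation_ = corr
        self.corr_var_ = cvar
        self.pair_n_ = pair_n
        self.gamma_ = gamma
        self.excluded_ = excluded
        self.n_pd_repairs_ = n_rep
        self.summary_ = PolychoricSummary(
            items=items, n=n, thresholds=thresholds, threshold_var=tvar,
            corr=corr, corr_var=cvar, pair_n=pair_n, gamma=gamma,
            excluded=excluded, n_pd_repairs=n_rep)
        return self


def _usable(tab: np.ndarray) -> bool:
    T = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    return T.shape[0] >= 2 and T.shape[1] >= 2


def polychoric_matrix(m: ItemResponseMatrix, group=None, reverse: bool = True,
                      compute_acov: bool = True) -> PolychoricSummary:
    """Polychoric summary for an item-response matrix (pairwise deletion).

    ``group`` selects one group label; ``None`` pools everyone. Positively
    worded problem items are reverse scored first so that all modelling is
    on the higher-is-more-problems scale.
    """
    mm = m if group is None else m.subset(group)
    if reverse:
        mm = mm.reversed()
    est = PolychoricMatrix(compute_acov=compute_acov)
    est.fit(mm.responses, items=mm.items)
    return est.summary_


def cronbach_alpha(scores: pd.DataFrame) -> float:
    """Cronbach's alpha from (pairwise-complete) Pearson item covariances."""
    C = scores.cov().to_numpy()
    k = C.shape[0]
    total = C.sum()
    if total <= 0:
        return float("nan")
    return k / (k - 1) * (1.0 - np.trace(C) / total)


def _standardized_alpha(R: np.ndarray) -> float:
    k = R.shape[0]
    off_sum = R.sum() - np.trace(R)
    return k / (k - 1) * (1.0 - k / (k + off_sum))


def ordinal_alpha(R: np.ndarray) -> float:
    """Cronbach-type alpha computed from a polychoric correlation matrix."""
    return _standardized_alpha(np.asarray(R, dtype=float))


def reliability(m: ItemResponseMatrix, group=None) -> pd.DataFrame:
    """Cronbach's and ordinal (polychoric) alpha per subscale and total.

    The total row covers the 20 problem items (prosocial excluded, as in
    the total-difficulties score). Items are reverse scored before both
    coefficients. Zero-variance items are dropped with a warning.
    """
    mm = (m if group is None else m.subset(group)).reversed()
    df = pd.DataFrame(mm.responses, columns=list(mm.items)).mask(
        mm.missing_mask())
    dropped = [c for c in df.columns if df[c].std() == 0 or df[c].isna().all()]
    if dropped:
        warnings.warn(f"zero-variance items dropped from reliability: {dropped}")
        df = df.drop(columns=dropped)
    summary = polychoric_matrix(m if group is None else m.subset(group),
                                reverse=True, compute_acov=False)
    R = pd.DataFrame(summary.corr, index=list(mm.items),
                     columns=list(mm.items)).drop(
        index=dropped, columns=dropped)
    rows = {}
    for scale in SCALES:
        cols = [c for c in scale_items(scale) if c in df.columns]
        rows[scale] = (cronbach_alpha(df[cols]),
                       ordinal_alpha(R.loc[cols, cols].to_numpy()))
    total_cols = [c for s in SCALES[:4] for c in scale_items(s)
                  if c in df.columns]
    rows["total"] = (cronbach_alpha(df[total_cols]),
                     ordinal_alpha(R.loc[total_cols, total_cols].to_numpy()))
    return pd.DataFrame(rows, index=["cronbach_alpha", "ordinal_alpha"]).T
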