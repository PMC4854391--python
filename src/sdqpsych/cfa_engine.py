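"""Ordinal confirmatory factor analysis by diagonally weighted least squares.

The observed moments are univariate probit thresholds and polychoric
correlations (delta parameterization: latent-response variances fixed to 1
in the reference group, free scale factors elsewhere). A model maps free
parameters to implied standardized moments

    Sigma_g = Lambda Phi_g Lambda' + Theta_g,

with group-2 total latent-response variances v_i = Delta_i^{-2} free from
the scalar-invariance rung onward, and estimation minimizes
sum_m w_m (s_m - sigma_m(theta))^2 with w_m the inverse asymptotic
variance of moment m. The test statistic is the mean-and-variance
adjusted (scaled-and-shifted) form: with U = W - W J (J'WJ)^{-1} J'W and
Gamma the full asymptotic covariance of the moments, a = tr(U Gamma),
b = tr((U Gamma)^2),

    T* = sqrt(df / b) * (T - a) + df,

which has mean df and variance 2 df to first order, making chi-square
based fit indices (CFI/TLI/RMSEA) comparable across nested constraint
sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import ncx2

from .polycor import PolychoricSummary, polychoric_matrix
from .published import FACTORS, ITEM_ORDER
from .sdq_data import ItemResponseMatrix

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

_THETA_FLOOR = 1e-4  # soft bound for residual variances (Heywood handling)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Loading pattern, residual correlations and identification rule.

    ``loadings`` lists every (item, factor) slot, primary and cross.
    Identification: factor variances fixed to 1 in the reference group,
    latent means 0 and scale factors 1 in the reference group.
    """

    items: tuple[str, ...]
    factors: tuple[str, ...]
    loadings: tuple[tuple[str, str], ...]
    residual_corrs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        loaded = {i for i, _ in self.loadings}
        if set(self.items) - loaded:
            raise ValueError(f"items without a loading: {set(self.items) - loaded}")

    def loading_slots(self) -> list[tuple[int, int]]:
        return [(self.items.index(i), self.factors.index(f))
                for i, f in self.loadings]

    def rc_slots(self) -> list[tuple[int, int]]:
        return [(self.items.index(a), self.items.index(b))
                for a, b in self.residual_corrs]


def sdq_model_spec(cross_loading: bool = True,
                   residual_corrs: bool = True) -> ModelSpec:
    """The five-factor SDQ model, optionally with the published modifications.

    Modifications: tantrum also loads on the emotional-problems factor, and
    the restless~~fidgety / distractible~~attends residuals correlate.
    """
    loadings = [(item, FACTORS[k // 5]) for k, item in enumerate(ITEM_ORDER)]
    if cross_loading:
        loadings.append(("tantrum", "emotion"))
    rc = (("restless", "fidgety"), ("distractible", "attends")) \
        if residual_corrs else ()
    return ModelSpec(items=tuple(ITEM_ORDER), factors=tuple(FACTORS),
                     loadings=tuple(loadings), residual_corrs=rc)


@dataclass(frozen=True)
class ConstraintPlan:
    """Which parameters exist and which are equated across groups.

    Defaults describe the configural two-group model: measurement
    parameters free per group, group-2 means 0, factor variances 1, scale
    factors 1. ``equal_measurement`` equates loadings and thresholds
    (scalar invariance) and is normally paired with ``means_free`` so that
    group-2 latent means, factor covariances and scale factors open up.
    ``free_items`` exempts items from the equality constraints (their
    group-2 scale factor is then fixed back to 1 — partial invariance).
    ``equal_factor_cov`` adds the structural-equivalence constraint on
    factor covariances, with ``free_factor_pairs`` exempted.
    """

    n_groups: int = 2
    equal_measurement: bool = False
    free_items: tuple[str, ...] = ()
    means_free: bool = False
    equal_factor_cov: bool = False
    free_factor_pairs: tuple[tuple[str, str], ...] = ()
    baseline: bool = False


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

@dataclass
class _Param:
    name: str
    start: float
    lb: float
    ub: float


class Parameterization:
    """Maps a free-parameter vector to per-group implied moments."""

    def __init__(self, spec: ModelSpec, plan: ConstraintPlan,
                 sample_thresholds: list[np.ndarray]):
        self.spec = spec
        self.plan = plan
        self.p = len(spec.items)
        self.m = len(spec.factors)
        self.G = plan.n_groups
        self.params: list[_Param] = []
        self.index: dict[str, int] = {}
        self._build(sample_thresholds)
        pairs = [(i, j) for i in range(self.p) for j in range(i + 1, self.p)]
        self._pair_rows = np.array([i for i, _ in pairs])
        self._pair_cols = np.array([j for _, j in pairs])

    # -- construction -----------------------------------------------------
    def _add(self, name, start, lb=-np.inf, ub=np.inf):
        if name not in self.index:
            self.index[name] = len(self.params)
            self.params.append(_Param(name, start, lb, ub))
        return self.index[name]

    def _build(self, sample_taus):
        spec, plan = self.spec, self.plan
        self._lam_ref: list[list] = [[] for _ in range(self.G)]
        self._tau_ref: list[np.ndarray] = []
        self._phi_ref: list[dict] = [dict() for _ in range(self.G)]
        self._psi_ref: dict = {}
        self._kappa_ref: dict = {}
        self._v_ref: dict = {}

        if plan.baseline:
            for g in range(self.G):
                tau_idx = np.empty((self.p, 2), dtype=np.int64)
                for i, item in enumerate(spec.items):
                    for k in range(2):
                        tau_idx[i, k] = self._add(
                            f"tau[{item},{k + 1}]@{g + 1}",
                            sample_taus[g][i, k], -8, 8)
                self._tau_ref.append(tau_idx)
            return

        for g in range(self.G):
            for item, factor in spec.loadings:
                shared = plan.equal_measurement and item not in plan.free_items
                suffix = "" if (shared or self.G == 1) else f"@{g + 1}"
                idx = self._add(f"lam[{item}->{factor}]{suffix}", 0.5, -3, 3)
                self._lam_ref[g].append(idx)

        for g in range(self.G):
            tau_idx = np.empty((self.p, 2), dtype=np.int64)
            for i, item in enumerate(spec.items):
                shared = plan.equal_measurement and item not in plan.free_items
                suffix = "" if (shared or self.G == 1) else f"@{g + 1}"
                start_tau = sample_taus[0 if shared else g][i]
                for k in range(2):
                    tau_idx[i, k] = self._add(
                        f"tau[{item},{k + 1}]{suffix}", start_tau[k], -8, 8)
            self._tau_ref.append(tau_idx)

        fpairs = [(a, b) for ai, a in enumerate(spec.factors)
                  for b in spec.factors[ai + 1:]]
        for g in range(self.G):
            for a, b in fpairs:
                shared = plan.equal_factor_cov and \
                    (a, b) not in plan.free_factor_pairs and \
                    (b, a) not in plan.free_factor_pairs
                suffix = "" if (shared or self.G == 1) else f"@{g + 1}"
                self._phi_ref[g][(a, b)] = self._add(
                    f"phi[{a}--{b}]{suffix}", 0.0, -3, 3)

        # group-2 structure (delta parameterization, scalar rung onward)
        if self.G == 2 and plan.means_free:
            self._psi_ref = {f: self._add(f"psi2[{f}]", 1.0, 0.05, 10)
                             for f in spec.factors}
            self._kappa_ref = {f: self._add(f"kappa2[{f}]", 0.0, -4, 4)
                               for f in spec.factors}
            for item in spec.items:
                if item in plan.free_items:
                    continue  # freed items: group-2 scale factor fixed to 1
                self._v_ref[item] = self._add(f"v2[{item}]", 1.0, 0.1, 10)

        for a, b in spec.residual_corrs:
            self._add(f"rc[{a}~~{b}]", 0.0, -0.99, 0.99)

    # -- vector interface --------------------------------------------------
    @property
    def n_free(self) -> int:
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def start_vector(self) -> np.ndarray:
        return np.array([p.start for p in self.params])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([p.lb for p in self.params]),
                np.array([p.ub for p in self.params]))

    # -- assembly ----------------------------------------------------------
    def group_matrices(self, x: np.ndarray, g: int):
        spec, plan = self.spec, self.plan
        p, m = self.p, self.m
        tau = x[self._tau_ref[g]]
        L = np.zeros((p, m))
        Phi = np.eye(m)
        kappa = np.zeros(m)
        v = np.ones(p)
        if plan.baseline:
            return L, Phi, kappa, v, tau, np.zeros(0)
        for s, (i, f) in enumerate(spec.loading_slots()):
            L[i, f] = x[self._lam_ref[g][s]]
        for (a, b), idx in self._phi_ref[g].items():
            ia, ib = spec.factors.index(a), spec.factors.index(b)
            Phi[ia, ib] = Phi[ib, ia] = x[idx]
        if self.G == 2 and g == 1 and plan.means_free:
            for f, idx in self._psi_ref.items():
                k = spec.factors.index(f)
                Phi[k, k] = x[idx]
            for f, idx in self._kappa_ref.items():
                kappa[spec.factors.index(f)] = x[idx]
            for item, idx in self._v_ref.items():
                v[spec.items.index(item)] = x[idx]
        rc = np.array([x[self.index[f"rc[{a}~~{b}]"]]
                       for a, b in spec.residual_corrs])
        return L, Phi, kappa, v, tau, rc

    def implied_group_moments(self, x: np.ndarray, g: int
                              ) -> tuple[np.ndarray, np.ndarray]:
        """(standardized thresholds p x 2, correlation matrix p x p)."""
        spec = self.spec
        L, Phi, kappa, v, tau, rc = self.group_matrices(x, g)
        Gmat = L @ Phi @ L.T
        comm = np.diag(Gmat).copy()
        theta = np.maximum(v - comm, _THETA_FLOOR)
        total = comm + theta
        Sigma = Gmat.copy()
        np.fill_diagonal(Sigma, total)
        if rc.size:
            for s, (i, j) in enumerate(spec.rc_slots()):
                add = rc[s] * np.sqrt(theta[i] * theta[j])
                Sigma[i, j] += add
                Sigma[j, i] += add
        sd = np.sqrt(total)
        P = Sigma / np.outer(sd, sd)
        mu = L @ kappa
        thr = (tau - mu[:, None]) / sd[:, None]
        return thr, P

    def implied_vector(self, x: np.ndarray) -> np.ndarray:
        out = []
        for g in range(self.G):
            thr, P = self.implied_group_moments(x, g)
            out.append(thr.ravel())
            out.append(P[self._pair_rows, self._pair_cols])
        return np.concatenate(out)

    def heywood_items(self, x: np.ndarray) -> list[str]:
        flagged = []
        for g in range(self.G):
            L, Phi, kappa, v, tau, rc = self.group_matrices(x, g)
            comm = np.einsum("if,fh,ih->i", L, Phi, L)
            for i in np.nonzero(v - comm <= _THETA_FLOOR)[0]:
                flagged.append(self.spec.items[int(i)])
        return sorted(set(flagged))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, discrepancy and adjusted test statistic for one model."""

    spec: ModelSpec
    plan: ConstraintPlan
    param_names: list[str]
    x: np.ndarray
    stat: float               # raw weighted discrepancy
    stat_scaled: float        # mean-and-variance adjusted statistic
    df: int
    trace_ug: float
    trace_ug2: float
    n_per_group: tuple[int, ...]
    converged: bool
    grad_norm: float
    n_iter: int
    heywood_items: list[str]
    parameterization: Parameterization = field(repr=False, default=None)
    summaries: list[PolychoricSummary] = field(repr=False, default=None)

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.x))

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_group))

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    # -- standardized solution -------------------------------------------
    def standardized(self, group: int = 0) -> pd.DataFrame:
        """Standardized loadings and thresholds for one group.

        Loadings are on unit-variance latent-response and unit-variance
        factor scale; thresholds on the unit-variance probit scale.
        """
        pz = self.parameterization
        L, Phi, kappa, v, tau, rc = pz.group_matrices(self.x, group)
        thr, P = pz.implied_group_moments(self.x, group)
        sd_f = np.sqrt(np.diag(Phi))
        comm = np.einsum("if,fh,ih->i", L, Phi, L)
        sd_i = np.sqrt(comm + np.maximum(v - comm, _THETA_FLOOR))
        rows = []
        for item, factor in self.spec.loadings:
            i = self.spec.items.index(item)
            f = self.spec.factors.index(factor)
            rows.append({
                "item": item, "factor": factor,
                "loading": L[i, f] * sd_f[f] / sd_i[i],
                "threshold1": thr[i, 0], "threshold2": thr[i, 1],
            })
        return pd.DataFrame(rows)

    def standardized_loading(self, item: str, factor: str,
                             group: int = 0) -> float:
        tab = self.standardized(group)
        sel = tab[(tab["item"] == item) & (tab["factor"] == factor)]
        return float(sel["loading"].iloc[0])

    def factor_correlation(self, f1: str, f2: str, group: int = 0) -> float:
        pz = self.parameterization
        L, Phi, kappa, v, tau, rc = pz.group_matrices(self.x, group)
        i, j = self.spec.factors.index(f1), self.spec.factors.index(f2)
        return float(Phi[i, j] / np.sqrt(Phi[i, i] * Phi[j, j]))

    def residual_correlation(self, a: str, b: str) -> float:
        return float(self.params[f"rc[{a}~~{b}]"])

    def latent_means(self) -> dict[str, tuple[float, float, float]]:
        """Per factor: (kappa2, phi1, phi2) — group-2 mean with both groups'
        factor variances, ready for effect-size conversion."""
        if not (self.plan.n_groups == 2 and self.plan.means_free):
            raise ValueError("latent means identified only from the strong/"
                             "partial-invariance rung onward")
        _, Phi1, _, _, _, _ = self.parameterization.group_matrices(self.x, 0)
        _, Phi2, kappa2, _, _, _ = self.parameterization.group_matrices(self.x, 1)
        out = {}
        for f in self.spec.factors:
            k = self.spec.factors.index(f)
            out[f] = (float(kappa2[k]), float(Phi1[k, k]), float(Phi2[k, k]))
        return out


def _stack_sample(summaries: list[PolychoricSummary]):
    s = np.concatenate([sm.moment_vector() for sm in summaries])
    w = 1.0 / np.concatenate([sm.moment_variances() for sm in summaries])
    return s, w


def _stack_gamma(summaries: list[PolychoricSummary]) -> np.ndarray:
    mats = [sm.gamma for sm in summaries]
    if any(mat is None for mat in mats):
        raise ValueError("summaries lack the moment asymptotic covariance")
    sizes = [mat.shape[0] for mat in mats]
    G = np.zeros((sum(sizes), sum(sizes)))
    ofs = 0
    for mat in mats:
        G[ofs:ofs + mat.shape[0], ofs:ofs + mat.shape[0]] = mat
        ofs += mat.shape[0]
    return G


def _jacobian(pz: Parameterization, x: np.ndarray, step: float = 1e-6
              ) -> np.ndarray:
    """Central-difference Jacobian of the implied-moment map."""
    f0 = pz.implied_vector(x)
    J = np.empty((f0.size, x.size))
    for k in range(x.size):
        xp = x.copy(); xp[k] += step
        xm = x.copy(); xm[k] -= step
        J[:, k] = (pz.implied_vector(xp) - pz.implied_vector(xm)) / (2 * step)
    return J


def adjusted_statistic(pz: Parameterization, x: np.ndarray,
                       summaries: list[PolychoricSummary]
                       ) -> tuple[float, float, float, float, int]:
    """Raw and scaled-shifted statistics plus tr(UG), tr((UG)^2), df."""
    s, w = _stack_sample(summaries)
    resid = s - pz.implied_vector(x)
    T = float(np.sum(w * resid * resid))
    df = s.size - pz.n_free
    Gamma = _stack_gamma(summaries)
    J = _jacobian(pz, x)
    WJ = w[:, None] * J
    H = J.T @ WJ
    Hinv = np.linalg.pinv(H, rcond=1e-10)
    # M = U Gamma without forming U: W Gamma - W J H^{-1} J' W Gamma
    WG = w[:, None] * Gamma
    M = WG - WJ @ (Hinv @ (WJ.T @ Gamma))
    a = float(np.trace(M))
    b = float(np.sum(M * M.T))
    if df <= 0 or b <= 0:
        return T, T, a, b, df
    T_scaled = float(np.sqrt(df / b) * (T - a) + df)
    return T, max(T_scaled, 0.0), a, b, df


def fit_dwls(summaries: list[PolychoricSummary], spec: ModelSpec,
             plan: ConstraintPlan, start: np.ndarray | None = None,
             compute_stat: bool = True) -> FitResult:
    """Fit one (possibly multigroup) ordinal CFA by DWLS.

    ``summaries`` must carry the moment asymptotic covariance (gamma) when
    ``compute_stat``; groups follow the order of the list (reference
    first). Raises on non-convergence with the best-so-far discrepancy in
    the message.
    """
    if len(summaries) != plan.n_groups:
        raise ValueError("one polychoric summary per group required")
    taus = [sm.thresholds for sm in summaries]
    pz = Parameterization(spec, plan, taus)
    s, w = _stack_sample(summaries)
    sw = np.sqrt(w)
    if s.size < pz.n_free:
        raise ValueError("fewer informative moments than free parameters")

    def residuals(x):
        return sw * (s - pz.implied_vector(x))

    x0 = pz.start_vector() if start is None else np.asarray(start, float)
    lb, ub = pz.bounds()
    x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
    res = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-10,
                        max_nfev=20000)
    grad_norm = float(np.max(np.abs(res.grad))) if res.grad is not None else np.nan
    converged = res.status > 0
    if compute_stat:
        T, T_s, a, b, df = adjusted_statistic(pz, res.x, summaries)
    else:
        resid = s - pz.implied_vector(res.x)
        T = float(np.sum(w * resid * resid))
        T_s, a, b = T, float("nan"), float("nan")
        df = s.size - pz.n_free
    fit = FitResult(
        spec=spec, plan=plan, param_names=pz.names, x=res.x,
        stat=T, stat_scaled=T_s, df=df, trace_ug=a, trace_ug2=b,
        n_per_group=tuple(sm.n for sm in summaries),
        converged=converged, grad_norm=grad_norm, n_iter=int(res.nfev),
        heywood_items=pz.heywood_items(res.x),
        parameterization=pz, summaries=summaries)
    if not converged:
        raise RuntimeError(f"DWLS did not converge: {res.message}; "
                           f"best discrepancy {T:.4g}")
    return fit


def fit_baseline(summaries: list[PolychoricSummary], spec: ModelSpec
                 ) -> FitResult:
    """Independence baseline: zero correlations, free thresholds."""
    plan = ConstraintPlan(n_groups=len(summaries), baseline=True)
    return fit_dwls(summaries, spec, plan)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    chi2_scaled: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    n_groups: int = 1
    rmsea_convention: str = "sqrt(G) multigroup convention"


def _rmsea_from_stat(T, df, N, G):
    if df <= 0:
        return 0.0
    return float(np.sqrt(G * max(T - df, 0.0) / (df * (N - 1))))


def _rmsea_ci(T, df, N, G, level=0.90):
    """Noncentrality-based RMSEA confidence interval."""
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2

    def bound(target):
        if ncx2.cdf(T, df, 1e-10) < target:
            return 0.0
        hi = max(10.0, 2 * T)
        while ncx2.cdf(T, df, hi) > target and hi < 1e7:
            hi *= 2
        return brentq(lambda nc: ncx2.cdf(T, df, max(nc, 1e-10)) - target,
                      1e-10, hi)

    try:
        lam_lo, lam_hi = bound(lo_p), bound(hi_p)
    except ValueError:
        return (0.0, 0.0)

    def conv(lam):
        return float(np.sqrt(G * lam / (df * (N - 1))))

    return (conv(lam_lo), conv(lam_hi))


def fit_indices(fit: FitResult, baseline: FitResult) -> FitIndices:
    """CFI, TLI and RMSEA (with 90% CI) from adjusted statistics.

    CFI uses the max-guarded noncentrality ratio; RMSEA uses the sqrt(G)
    multigroup convention with N the total sample size. With df = 0 the
    RMSEA is reported as 0.
    """
    Tm, dfm = fit.stat_scaled, fit.df
    T0, df0 = baseline.stat_scaled, baseline.df
    num = max(Tm - dfm, 0.0)
    den = max(T0 - df0, Tm - dfm, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df0 > 0 and dfm > 0 and (T0 / df0) != 1.0:
        tli = ((T0 / df0) - (Tm / dfm)) / ((T0 / df0) - 1.0)
    else:
        tli = float("nan")
    G = fit.plan.n_groups
    N = fit.n_total
    rmsea = _rmsea_from_stat(Tm, dfm, N, G)
    ci = _rmsea_ci(Tm, dfm, N, G) if dfm > 0 else (0.0, 0.0)
    return FitIndices(chi2_scaled=Tm, df=dfm, cfi=float(np.clip(cfi, 0, 1)),
                      tli=float(tli), rmsea=rmsea, rmsea_ci=ci, n_groups=G)


# ---------------------------------------------------------------------------
# sklearn-style single-group estimator
# ---------------------------------------------------------------------------

class OrdinalCFA(BaseEstimator):
    """Single-group (pooled) ordinal CFA estimator.

    Parameters
    ----------
    model_spec : ModelSpec or None
        Defaults to the modified five-factor SDQ model.
    reverse : bool, default True
        Reverse score the positively worded problem items before modeling.

    Fitted attributes: ``fit_result_``, ``indices_``, ``loadings_``
    (standardized table), ``factor_corr_``, ``summary_``.
    """

    def __init__(self, model_spec: ModelSpec | None = None,
                 reverse: bool = True):
        self.model_spec = model_spec
        self.reverse = reverse

    def fit(self, X, y=None):
        spec = self.model_spec or sdq_model_spec()
        if isinstance(X, ItemResponseMatrix):
            summary = polychoric_matrix(X, reverse=self.reverse)
        else:
            from .polycor import PolychoricMatrix
            summary = PolychoricMatrix().fit(
                np.asarray(X), items=spec.items).summary_
        plan = ConstraintPlan(n_groups=1)
        self.fit_result_ = fit_dwls([summary], spec, plan)
        self.baseline_ = fit_baseline([summary], spec)
        self.indices_ = fit_indices(self.fit_result_, self.baseline_)
        self.loadings_ = self.fit_result_.standardized(0)
        self.factor_corr_ = np.array(
            [[self.fit_result_.factor_correlation(a, b)
              for b in spec.factors] for a in spec.factors])
        self.summary_ = summary
        return self
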