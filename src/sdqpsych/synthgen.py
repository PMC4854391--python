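"""Two-group ordinal item-response generator for the SDQ latent-response model.

Observed categories arise by cutting a latent continuous response

    y*_i = lambda_i' eta + eps_i,    eta ~ MVN(kappa_g, Phi_g)

at two increasing probit thresholds per item. Residuals are independent
across items except for the listed residual-correlation pairs; residual
variances are the delta-parameterization remainders 1 - Var(lambda_i' eta),
so every latent response has unit variance within each group (group-wise
standardized truth). Presets encode the published population parameters so
that the entire downstream analysis is testable without the study's raw
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import published as pub
from .sdq_data import MISSING, ItemResponseMatrix

GROUP_LABELS = ("girls", "boys")


@dataclass
class PopulationSpec:
    """Full generative parameter set for a two-group SDQ population.

    Loadings and thresholds are on the standardized (unit latent-response
    variance) probit scale per group; ``factor_corr`` are 5x5 latent factor
    covariance matrices (unit diagonal in group 1); ``latent_means`` are the
    factor means with the reference group fixed at zero.
    """

    loadings: tuple[np.ndarray, np.ndarray]       # each 25 x 5
    thresholds: tuple[np.ndarray, np.ndarray]     # each 25 x 2, increasing
    factor_corr: tuple[np.ndarray, np.ndarray]    # each 5 x 5
    latent_means: tuple[np.ndarray, np.ndarray]   # each length 5, group 1 == 0
    residual_corrs: tuple = pub.RESIDUAL_CORRELATIONS
    n_per_group: tuple[int, int] = (pub.N_GIRLS, pub.N_BOYS)
    missing_rate: float = 0.015
    seed: int = 0
    items: tuple[str, ...] = field(default=pub.ITEM_ORDER)
    factors: tuple[str, ...] = field(default=pub.FACTORS)

    def __post_init__(self) -> None:
        self.loadings = tuple(np.asarray(L, dtype=float) for L in self.loadings)
        self.thresholds = tuple(np.asarray(t, dtype=float) for t in self.thresholds)
        self.factor_corr = tuple(np.asarray(P, dtype=float) for P in self.factor_corr)
        self.latent_means = tuple(np.asarray(k, dtype=float) for k in self.latent_means)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_items, n_fac = len(self.items), len(self.factors)
        for g in range(2):
            L, t, P, k = (self.loadings[g], self.thresholds[g],
                          self.factor_corr[g], self.latent_means[g])
            if L.shape != (n_items, n_fac) or t.shape != (n_items, 2):
                raise ValueError("loading/threshold shape mismatch")
            if not np.allclose(P, P.T):
                raise ValueError("factor covariance not symmetric")
            if np.linalg.eigvalsh(P).min() <= 0:
                raise ValueError("factor covariance not positive definite")
            if np.any(np.diff(t, axis=1) <= 0):
                bad = self.items[int(np.argwhere(np.diff(t, axis=1) <= 0)[0, 0])]
                raise ValueError(f"thresholds not strictly increasing for {bad}")
            if np.any(self.residual_variances(g) <= 0):
                raise ValueError("communality >= 1: negative residual variance")
        if not np.allclose(self.latent_means[0], 0.0):
            raise ValueError("reference-group latent means must be zero")
        if not np.allclose(np.diag(self.factor_corr[0]), 1.0):
            raise ValueError("reference-group factor variances must be one")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    # -- derived quantities ----------------------------------------------
    def communalities(self, g: int) -> np.ndarray:
        L, P = self.loadings[g], self.factor_corr[g]
        return np.einsum("if,fh,ih->i", L, P, L)

    def residual_variances(self, g: int) -> np.ndarray:
        return 1.0 - self.communalities(g)

    def residual_cov(self, g: int) -> np.ndarray:
        theta = self.residual_variances(g)
        T = np.diag(theta)
        for a, b, r in self.residual_corrs:
            i, j = self.items.index(a), self.items.index(b)
            T[i, j] = T[j, i] = r * np.sqrt(theta[i] * theta[j])
        return T

    def latent_response_corr(self, g: int) -> np.ndarray:
        """Model-implied correlation matrix of the latent responses."""
        L, P = self.loadings[g], self.factor_corr[g]
        return L @ P @ L.T + self.residual_cov(g)


def _base_arrays(dif: bool) -> dict:
    """Build parameter arrays from the published tables.

    When ``dif`` is false both groups get the reference (girls) measurement
    parameters; otherwise the eight DIF items carry their group-specific
    published values.
    """
    n_items = len(pub.ITEM_ORDER)
    L = [np.zeros((n_items, 5)), np.zeros((n_items, 5))]
    T = [np.zeros((n_items, 2)), np.zeros((n_items, 2))]
    for i, item in enumerate(pub.ITEM_ORDER):
        fac = i // 5
        girls, boys = pub.LOADINGS_THRESHOLDS[item]
        use_boys = dif and item in pub.DIF_ITEMS
        row2 = boys if use_boys else girls
        L[0][i, fac], T[0][i] = girls[0], girls[1:]
        L[1][i, fac], T[1][i] = row2[0], row2[1:]
    # tantrum loads on the emotional-problems factor in both groups
    i_tantrum = pub.ITEM_ORDER.index("tantrum")
    L[0][i_tantrum, 0] = pub.CROSS_LOADING_TANTRUM_EMOTION
    L[1][i_tantrum, 0] = pub.CROSS_LOADING_TANTRUM_EMOTION
    return {"loadings": (L[0], L[1]), "thresholds": (T[0], T[1])}


def make_population_spec(preset: str = "table2_full", **overrides) -> PopulationSpec:
    """Construct a validated population spec from a named preset.

    Presets:

    ``table2_full``
        All published parameters: group-specific loadings/thresholds for the
        eight DIF items, shared (girls') values for the rest, published
        factor correlations per group and boys' latent mean offsets.
    ``no_dif``
        Girls' measurement parameters and factor correlations in both
        groups, zero latent mean offsets — an exactly invariant population.
    ``custom``
        Starts from ``no_dif``; everything comes from overrides.

    Overrides replace PopulationSpec fields by keyword and are re-validated.
    """
    kappa0 = np.zeros(5)
    if preset == "table2_full":
        base = _base_arrays(dif=True)
        kwargs = dict(
            factor_corr=(pub.FACTOR_CORR_GIRLS.copy(), pub.FACTOR_CORR_BOYS.copy()),
            latent_means=(kappa0, np.array([pub.LATENT_MEANS_BOYS[f]
                                            for f in pub.FACTORS])),
            **base,
        )
    elif preset in ("no_dif", "custom"):
        base = _base_arrays(dif=False)
        kwargs = dict(
            factor_corr=(pub.FACTOR_CORR_GIRLS.copy(), pub.FACTOR_CORR_GIRLS.copy()),
            latent_means=(kappa0, kappa0.copy()),
            **base,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


def inject_dif(spec: PopulationSpec, item: str, d_loading: float = 0.0,
               d_threshold: float = 0.0) -> PopulationSpec:
    """Shift one item's group-2 primary loading and both thresholds.

    Returns a new, re-validated spec; the original is untouched.
    """
    if item not in spec.items:
        raise ValueError(f"unknown item {item!r}")
    i = spec.items.index(item)
    L2 = spec.loadings[1].copy()
    T2 = spec.thresholds[1].copy()
    L2[i, i // 5] += d_loading
    T2[i] += d_threshold
    return replace(spec, loadings=(spec.loadings[0], L2),
                   thresholds=(spec.thresholds[0], T2))


def simulate_responses(spec: PopulationSpec, seed: int | None = None) -> ItemResponseMatrix:
    """Draw ordinal responses from the latent-response model.

    Deterministic under (spec, seed): group sizes, latent factor draws,
    residual draws and the MCAR missingness mask all flow from one
    ``numpy.random.default_rng(seed)``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    blocks, labels = [], []
    n_items = len(spec.items)
    for g in range(2):
        n = spec.n_per_group[g]
        eta = rng.multivariate_normal(
            spec.latent_means[g], spec.factor_corr[g], size=n,
            method="cholesky")
        eps = rng.multivariate_normal(
            np.zeros(n_items), spec.residual_cov(g), size=n,
            method="cholesky")
        ystar = eta @ spec.loadings[g].T + eps
        t = spec.thresholds[g]
        cats = (ystar > t[:, 0]).astype(np.int64) + (ystar > t[:, 1])
        # thresholds live on the reversed (higher = more problems) scale;
        # emit raw questionnaire coding for the positively worded problem items
        for item in pub.REVERSE_SCORED:
            j = spec.items.index(item)
            cats[:, j] = 2 - cats[:, j]
        if spec.missing_rate > 0:
            mask = rng.random(cats.shape) < spec.missing_rate
            cats[mask] = MISSING
        blocks.append(cats)
        labels.append(np.full(n, GROUP_LABELS[g], dtype=object))
    return ItemResponseMatrix(np.vstack(blocks), np.concatenate(labels),
                              spec.items)
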