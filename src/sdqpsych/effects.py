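"""Latent mean effect sizes and DIF magnitude flags.

The group-2 latent mean (reference group fixed at zero) converts to a
Cohen's d by standardizing with the sample-size-weighted pooled construct
variance:

    d = kappa2 / sqrt( (n1/(n1+n2)) phi1 + (n2/(n1+n2)) phi2 )

where phi1, phi2 are the two groups' factor variances. A parameter
difference between groups larger than 0.25 on the standardized scale is
flagged as a small-or-larger DIF effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cfa_engine import FitResult


def cohens_d_latent(kappa2: float, phi1: float, phi2: float,
                    n1: int, n2: int) -> float:
    """Signed standardized latent mean difference (group 2 minus reference)."""
    if phi1 <= 0 or phi2 <= 0:
        raise ValueError("construct variances must be positive")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    w1 = n1 / (n1 + n2)
    pooled = w1 * phi1 + (1.0 - w1) * phi2
    return float(kappa2 / np.sqrt(pooled))


def dif_magnitude_flag(param_g1: float, param_g2: float,
                       threshold: float = 0.25) -> bool:
    """True when |group difference| strictly exceeds the threshold.

    Intended for standardized loadings/thresholds; 0.25 corresponds to a
    small effect size.
    """
    return bool(abs(param_g1 - param_g2) > threshold)


def effect_size_table(fit: FitResult) -> pd.DataFrame:
    """Per-factor latent mean difference and Cohen's d from one fit."""
    n1, n2 = fit.n_per_group
    rows = []
    for factor, (k2, p1, p2) in fit.latent_means().items():
        rows.append({"factor": factor, "delta_mean": k2,
                     "phi1": p1, "phi2": p2,
                     "d": cohens_d_latent(k2, p1, p2, n1, n2)})
    return pd.DataFrame(rows)


def dif_impact_table(fit_with_dif: FitResult,
                     fit_without: FitResult) -> pd.DataFrame:
    """Side-by-side latent means and effect sizes with and without DIF.

    ``fit_without`` is the fully constrained (DIF-disregarding) model,
    ``fit_with_dif`` the partial-invariance model. The d difference is the
    change in magnitude |d_with| - |d_without|.
    """
    if fit_with_dif.spec.factors != fit_without.spec.factors:
        raise ValueError("factor sets differ between the two fits")
    a = effect_size_table(fit_without).set_index("factor")
    b = effect_size_table(fit_with_dif).set_index("factor")
    out = pd.DataFrame({
        "delta_mean_without_dif": a["delta_mean"],
        "d_without_dif": a["d"],
        "delta_mean_with_dif": b["delta_mean"],
        "d_with_dif": b["d"],
    })
    out["d_difference"] = out["d_with_dif"].abs() - out["d_without_dif"].abs()
    return out.reset_index()


def effect_size_reduction(d_with: float, d_without: float) -> float:
    """Magnitude change between two reported effect sizes."""
    return float(abs(d_with) - abs(d_without))
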