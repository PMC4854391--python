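"""Renderers for publication-shaped CSV outputs and small desk statistics.

Percentages and effect sizes render at 2 decimals, loadings/thresholds and
correlations at 3; rounding is half-away-from-zero to match the usual
printed style of psychometric tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cfa_engine import FitResult
from .effects import dif_magnitude_flag
from .published import N_PARTICIPANTS, TARGET_POPULATION


def round_half_away(x, decimals: int = 3):
    """Round half away from zero (vectorized)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def participation_rate(n_participants: int = N_PARTICIPANTS,
                       target_population: int = TARGET_POPULATION,
                       decimals: int = 0) -> float:
    """Participation percentage at the stated display precision."""
    return round_half_away(100.0 * n_participants / target_population,
                           decimals)


def render_endorsement(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Endorsement-rate table with flattened columns, 2 decimals."""
    out = table.copy()
    out.columns = [f"{s}_{c}" for s, c in out.columns]
    return out.apply(lambda col: round_half_away(col, decimals))


def render_loadings(fit: FitResult, group_labels=("girls", "boys"),
                    dif_threshold: float = 0.25,
                    decimals: int = 3) -> pd.DataFrame:
    """Standardized loadings/thresholds per group with a DIF marker column.

    The marker flags parameters whose between-group difference exceeds the
    standardized small-effect threshold.
    """
    frames = []
    for g in range(fit.plan.n_groups):
        tab = fit.standardized(g).set_index(["item", "factor"])
        label = group_labels[g] if g < len(group_labels) else f"group{g + 1}"
        tab.columns = [f"{label}_{c}" for c in tab.columns]
        frames.append(tab)
    out = pd.concat(frames, axis=1).reset_index()
    if fit.plan.n_groups == 2:
        g1, g2 = group_labels[:2]
        flags = []
        for _, row in out.iterrows():
            flags.append(any(
                dif_magnitude_flag(row[f"{g1}_{c}"], row[f"{g2}_{c}"],
                                   dif_threshold)
                for c in ("loading", "threshold1", "threshold2")))
        out["dif_flag"] = flags
    num = out.select_dtypes(float).columns
    out[num] = round_half_away(out[num].to_numpy(), decimals)
    return out


def render_factor_correlations(fit: FitResult,
                               decimals: int = 3) -> pd.DataFrame:
    """Factor correlation matrix: group 1 above, group 2 below the diagonal."""
    factors = fit.spec.factors
    k = len(factors)
    M = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            M[i, j] = fit.factor_correlation(factors[i], factors[j], group=0)
            if fit.plan.n_groups == 2:
                M[j, i] = fit.factor_correlation(factors[i], factors[j],
                                                 group=1)
            else:
                M[j, i] = M[i, j]
    return pd.DataFrame(round_half_away(M, decimals), index=factors,
                        columns=factors)


def render_effects(impact: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Latent-mean comparison table with d printed as magnitudes."""
    out = impact.copy()
    for c in out.columns:
        if c.startswith("d_"):
            out[c] = round_half_away(out[c].abs(), decimals)
        elif c != "factor":
            out[c] = round_half_away(out[c], decimals)
    return out


def render_ladder(report: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    out = report.copy()
    num = out.select_dtypes(float).columns
    out[num] = round_half_away(out[num].to_numpy(), decimals)
    return out
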