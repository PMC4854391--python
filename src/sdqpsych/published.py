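"""Published SDQ population parameters for Norwegian 16-18 year-olds.

These constants transcribe the parameter estimates reported for the
youth@hordaland sample (n = 5,399 girls / 4,854 boys): standardized factor
loadings and thresholds of the final partially invariant five-factor model,
latent factor correlations per gender, latent mean offsets for boys, the
tantrum->emotion cross-loading, two residual correlations within the
hyperactivity/inattention factor, and per-item endorsement rates. They are
the generative truth behind the ``table2_full`` synthetic-data preset and
the printed inputs for the desk-check utilities.
"""

from __future__ import annotations

import numpy as np

#: factor order used throughout the package
FACTORS = ("emotion", "conduct", "hyper", "peer", "prosocial")

#: item order (5 per factor, factor-major)
ITEM_ORDER = (
    "somatic", "worries", "unhappy", "clingy", "afraid",
    "tantrum", "obeys", "fights", "lies", "steals",
    "restless", "fidgety", "distractible", "reflective", "attends",
    "loner", "friend", "popular", "bullied", "oldbest",
    "considerate", "shares", "caring", "kind", "helpout",
)

#: the five positively worded problem items that are reverse scored
REVERSE_SCORED = ("obeys", "reflective", "attends", "friend", "popular")

#: items flagged with gender differential item functioning
DIF_ITEMS = ("unhappy", "clingy", "afraid", "tantrum", "obeys",
             "reflective", "bullied", "caring")

#: group sizes: girls (reference) and boys
N_GIRLS = 5399
N_BOYS = 4854
TARGET_POPULATION = 19430
N_PARTICIPANTS = 10254

# Standardized factor loadings and thresholds (probit scale) per item:
# (loading, threshold1, threshold2), girls column then boys column.
LOADINGS_THRESHOLDS = {
    #               girls                    boys
    "somatic":      ((0.578, -0.205, 0.783), (0.559, -0.210, 0.804)),
    "worries":      ((0.670, -0.610, 0.607), (0.589, -0.569, 0.566)),
    "unhappy":      ((0.814, 0.012, 1.117), (0.822, -0.085, 0.801)),
    "clingy":       ((0.595, -0.671, 0.665), (0.560, -0.867, 0.478)),
    "afraid":       ((0.650, 0.277, 1.321), (0.748, 0.230, 1.133)),
    "tantrum":      ((0.412, -0.025, 1.231), (0.359, 0.364, 1.590)),
    "obeys":        ((0.571, 0.028, 1.909), (0.552, 0.538, 2.406)),
    "fights":       ((0.622, 1.647, 2.401), (0.696, 2.114, 3.083)),
    "lies":         ((0.621, 1.403, 2.141), (0.650, 1.685, 2.572)),
    "steals":       ((0.471, 1.418, 2.089), (0.532, 1.838, 2.708)),
    "restless":     ((0.517, -0.519, 0.976), (0.439, -0.466, 0.875)),
    "fidgety":      ((0.496, -0.107, 1.236), (0.456, -0.104, 1.201)),
    "distractible": ((0.755, -0.559, 0.719), (0.731, -0.572, 0.736)),
    "reflective":   ((0.468, -0.476, 1.602), (0.499, -0.419, 1.422)),
    "attends":      ((0.710, -0.643, 1.010), (0.674, -0.645, 1.013)),
    "loner":        ((0.573, 0.022, 1.305), (0.499, 0.021, 1.217)),
    "friend":       ((0.745, 1.149, 1.998), (0.737, 1.217, 2.117)),
    "popular":      ((0.706, 0.255, 1.821), (0.673, 0.260, 1.859)),
    "bullied":      ((0.628, 1.439, 2.217), (0.775, 1.427, 2.275)),
    "oldbest":      ((0.422, 0.264, 1.406), (0.418, 0.280, 1.491)),
    "considerate":  ((0.806, -2.611, -1.178), (0.792, -2.374, -1.071)),
    "shares":       ((0.475, -1.794, -0.228), (0.518, -1.810, -0.230)),
    "caring":       ((0.607, -2.217, -0.878), (0.635, -1.940, -0.331)),
    "kind":         ((0.650, -1.993, -0.731), (0.710, -2.017, -0.740)),
    "helpout":      ((0.479, -1.402, 0.495), (0.504, -1.366, 0.483)),
}

#: standardized cross-loading of tantrum on the emotional-problems factor
CROSS_LOADING_TANTRUM_EMOTION = 0.353

#: residual correlations within hyperactivity/inattention
RESIDUAL_CORRELATIONS = (("restless", "fidgety", 0.555),
                         ("distractible", "attends", 0.332))

# Latent factor correlation matrices (emotion, conduct, hyper, peer, prosocial)
FACTOR_CORR_GIRLS = np.array([
    [1.000, 0.310, 0.525, 0.577, -0.097],
    [0.310, 1.000, 0.799, 0.502, -0.622],
    [0.525, 0.799, 1.000, 0.245, -0.341],
    [0.577, 0.502, 0.245, 1.000, -0.512],
    [-0.097, -0.622, -0.341, -0.512, 1.000],
])

FACTOR_CORR_BOYS = np.array([
    [1.000, 0.488, 0.534, 0.671, -0.092],
    [0.488, 1.000, 0.790, 0.568, -0.569],
    [0.534, 0.790, 1.000, 0.261, -0.294],
    [0.671, 0.568, 0.261, 1.000, -0.506],
    [-0.092, -0.569, -0.294, -0.506, 1.000],
])

#: boys' latent mean offsets relative to girls (fixed at 0), DIF-accounting model
LATENT_MEANS_BOYS = {
    "emotion": -0.65,
    "conduct": 0.43,
    "hyper": -0.09,
    "peer": 0.07,
    "prosocial": -0.37,
}

#: DIF-ignoring latent mean offsets and both models' reported Cohen's d values
LATENT_MEANS_BOYS_NO_DIF_MODEL = {
    "emotion": -0.61,
    "conduct": 0.11,
    "hyper": -0.10,
    "peer": 0.07,
    "prosocial": -0.50,
}

COHENS_D_REPORTED = {
    # factor: (d without DIF accounting, d with DIF accounting)
    "emotion": (1.062, 1.147),
    "conduct": (0.280, 1.113),
    "hyper": (0.188, 0.181),
    "peer": (0.116, 0.117),
    "prosocial": (0.622, 0.439),
}

# Endorsement rates (%) per item: (full sample, boys, girls) for categories
# "not true", "somewhat true", "certainly true".
ENDORSEMENT_RATES = {
    "somatic":      ((53.88, 69.11, 40.33), (31.30, 23.63, 38.12), (14.82, 7.26, 21.55)),
    "worries":      ((40.21, 54.22, 27.77), (40.54, 34.97, 45.50), (19.25, 10.81, 26.72)),
    "unhappy":      ((64.97, 81.28, 50.47), (26.26, 14.92, 36.33), (8.78, 3.80, 13.20)),
    "clingy":       ((33.01, 41.93, 25.10), (47.62, 45.39, 49.59), (19.37, 12.69, 25.31)),
    "afraid":       ((73.09, 86.78, 60.91), (20.96, 11.04, 29.77), (5.96, 2.17, 9.32)),
    "tantrum":      ((53.88, 59.74, 49.01), (36.84, 33.21, 40.08), (9.09, 7.05, 10.92)),
    "obeys":        ((3.40, 4.07, 2.81), (48.34, 50.91, 46.07), (48.25, 45.02, 51.11)),
    "fights":       ((92.63, 89.96, 94.99), (6.36, 8.80, 4.20), (1.01, 1.24, 0.81)),
    "lies":         ((87.12, 82.12, 91.56), (10.30, 14.19, 6.85), (2.58, 3.69, 1.59)),
    "steals":       ((90.46, 88.22, 92.44), (7.70, 9.67, 5.94), (1.85, 2.11, 1.61)),
    "restless":     ((32.47, 35.07, 30.17), (50.83, 47.51, 53.77), (16.70, 17.42, 16.06)),
    "fidgety":      ((47.40, 48.59, 46.33), (42.20, 41.28, 43.03), (10.40, 10.14, 10.63)),
    "distractible": ((30.84, 34.26, 27.80), (47.63, 47.95, 47.33), (21.54, 17.78, 24.87)),
    "reflective":   ((5.94, 6.49, 5.46), (59.76, 56.30, 62.84), (34.30, 37.21, 31.70)),
    "attends":      ((14.26, 13.24, 15.17), (57.79, 57.88, 57.71), (27.95, 28.89, 27.13)),
    "loner":        ((49.68, 47.31, 51.79), (39.49, 41.30, 37.87), (10.84, 11.39, 10.34)),
    "friend":       ((2.20, 2.30, 2.12), (10.51, 11.08, 10.01), (87.28, 86.62, 87.87)),
    "popular":      ((3.58, 4.16, 3.06), (37.77, 37.94, 37.63), (58.65, 57.90, 59.31)),
    "bullied":      ((91.74, 90.88, 92.50), (6.87, 7.66, 6.17), (1.39, 1.46, 1.33)),
    "oldbest":      ((59.76, 59.63, 59.87), (32.48, 33.14, 31.90), (7.76, 7.22, 8.23)),
    "considerate":  ((1.15, 1.71, 0.66), (16.12, 22.61, 10.36), (82.73, 75.68, 88.98)),
    "shares":       ((4.56, 5.85, 3.41), (40.45, 43.56, 37.70), (54.99, 50.59, 58.89)),
    "caring":       ((2.93, 4.73, 1.33), (29.47, 42.77, 17.67), (67.60, 52.50, 81.00)),
    "kind":         ((3.22, 3.84, 2.66), (24.62, 29.31, 20.46), (72.17, 66.85, 76.88)),
    "helpout":      ((10.11, 12.41, 8.08), (62.02, 62.51, 61.57), (27.87, 25.08, 30.35)),
}


def endorsement_proportions(item: str, group: str = "girls") -> np.ndarray:
    """Return the published category proportions (summing to 1) for one item.

    group is one of ``full``, ``boys``, ``girls``.
    """
    idx = {"full": 0, "boys": 1, "girls": 2}[group]
    rates = ENDORSEMENT_RATES[item]
    p = np.array([rates[k][idx] for k in range(3)]) / 100.0
    return p / p.sum()
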