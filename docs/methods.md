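# Methods

This note documents the statistical machinery of `sdqpsych`: the models,
the estimators, the numerical choices, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Latent-response model and scales

All 25 SDQ items are three-category ordinal variables. The five positively
worded problem items (obeys, reflective, attends, friend, popular) are
recoded x → 2 − x before any modeling, so that on every problem subscale a
higher latent score means more problems; prosocial items keep their
direction (higher = more prosocial). The generator emits files in the raw
questionnaire coding and the modeling layer re-applies the reversal, so
simulated endorsement tables are directly comparable to published
endorsement rates.

Item *i* in group *g* follows a probit latent-response model
y\*ᵢ = λᵢ'η + εᵢ with η ~ N(κ_g, Φ_g) and two increasing thresholds per
item. Identification is the **delta parameterization**: in the reference
group (girls) every latent response has unit variance, factor variances
are 1 and latent means 0; in the second group latent means, factor
(co)variances and per-item scale factors Δᵢ are free once measurement
parameters are constrained. Internally the scale factors are parameterized
as total latent-response variances vᵢ = Δᵢ⁻², which keeps the moment map
simple: the implied correlation of items i and j is
(λᵢ'Φλⱼ + θᵢⱼ)/√(vᵢvⱼ) and the implied standardized threshold is
(τᵢₖ − λᵢ'κ)/√vᵢ, with residual variances as remainders
θᵢᵢ = vᵢ − λᵢ'Φλᵢ and residual covariances r·√(θᵢᵢθⱼⱼ) for the two
declared pairs (restless↔fidgety, distractible↔attends).

## Polychoric correlations and moment uncertainties

Thresholds are estimated univariately as probits of cumulative category
proportions, with boundary proportions clamped to [1/(2n), 1 − 1/(2n)].
Pairwise polychoric correlations use the standard two-step estimator:
margins fixed, then the latent correlation maximizes the bivariate-normal
likelihood of the 3×3 table (bounded scalar minimization on ±0.999,
tolerance 1e−8). The bivariate normal CDF is evaluated through Owen's T
function (exact to ~1e−14 against quadrature). Missing responses are
handled by pairwise deletion; an item with a single observed category is
excluded and reported.

The full asymptotic covariance Γ of the moment vector (50 thresholds +
300 correlations per group) is assembled from per-person influence
functions: the inverse-CDF delta method for thresholds, and for each
correlation the implicit-function expansion of its score equation,
including the propagation of threshold-estimation error (the two-step
correction). Rows with missing cells contribute zero influence and are
rescaled by the pairwise-complete fraction — exact under MCAR, a good
approximation at the ~1.5% missingness modeled here. Γ's diagonal supplies
the DWLS weights; the full matrix feeds the robust test statistic.

If the polychoric matrix is indefinite it is repaired by eigenvalue
clipping at 1e−6 followed by re-standardization, and the repair is
counted; with the sample sizes used here repairs do not occur.

## DWLS estimation and the adjusted test statistic

The fit function is Σₘ wₘ(sₘ − σₘ(θ))² with wₘ = 1/Γₘₘ. It is minimized
with a trust-region-reflective least-squares solver on box bounds, with a
finite-difference Jacobian of the implied-moment map; the map is 25×5
matrix algebra, so numeric Jacobians cost microseconds and avoid a large
analytic-derivative surface. Start values: loadings 0.5, factor
correlations 0, thresholds at their sample values, scale parameters 1;
ladder refits warm-start from the previous rung through an exact
reparameterization map. Residual variances are floored at 1e−4
(Heywood-adjacent solutions are flagged, not failed). Degenerate Φ is not
constrained during iteration — the moment map needs no PD factorization —
and is checked at the solution.

The reported statistic is the mean-and-variance adjusted
(scaled-and-shifted) form used with WLSMV estimation: with
U = W − WJ(J'WJ)⁻¹J'W evaluated at the solution and a = tr(UΓ),
b = tr((UΓ)²),

T\* = √(df/b)·(T − a) + df,

which has mean df and variance 2·df to first order. On data generated
from the fitted model T\* tracks its degrees of freedom closely (verified
in the tests), which is what makes CFI differences comparable across the
constraint ladder. CFI and TLI use the independence baseline (free
thresholds, zero correlations); RMSEA uses the √G multigroup convention
with N the total sample size, and its 90% CI comes from noncentral-χ²
root finding.

Degrees of freedom are pure bookkeeping: 350 moments per group minus free
parameters — 262 for the single-group modified five-factor model, 526 for
the configural two-group model, 567 for the scalar model, minus 2 per
freed item (3 for tantrum, which carries the cross-loading).

## Invariance ladder

Measurement rungs compare each constrained model's CFI to the
**configural** CFI; the model is accepted when the drop is ≤ 0.002.
While the drop exceeds the cutoff, modification indices are computed for
every still-constrained item and the top item's loading(s) and both
thresholds are freed together; the freed item's group-2 scale factor is
fixed back to 1 (the usual convention), so each freeing releases net two
parameters. Candidates are restricted so that every factor keeps at least
one constrained anchor item; ties break on item order. The structural
step equates factor covariances (variances stay free) and frees pairs by
the same rule, comparing against the final measurement model's CFI.

Modification indices are univariate Lagrange-multiplier approximations:
the fitted solution is mapped into the relaxed parameterization — an
exact reparameterization, shared loadings/thresholds dividing by √v for
the group-2 copies — and the LM quadratic form g'(J'WJ)⁺g of the DWLS
discrepancy is evaluated there. A slower "refit-delta" oracle (free the
candidate, refit, measure the CFI gain) is provided and the tests confirm
both modes select the same top candidate.

Latent mean differences are read from any rung with equated measurement:
boys' means κ̂₂ against the zero-fixed girls' reference, with both groups'
factor variances. Cohen's d standardizes κ̂₂ by the sample-size-weighted
pooled construct variance; the implementation returns signed d (negative =
boys lower) and the renderer prints magnitudes with the sign carried by
the Δ-mean column.

## Synthetic-data generator

The `table2_full` preset treats the published **standardized** loadings
and thresholds as generative truth on a unit-variance latent-response
scale *per group*: the eight DIF items carry their group-specific values,
all other items the reference (girls') values, both groups share the
tantrum→emotion cross-loading (0.353) and the residual correlations
(0.555, 0.332), factor correlation matrices and boys' latent mean offsets
are the published ones (boys' factor variances, which are not published,
are set to 1), group sizes are 5,399/4,854 and missingness is MCAR at
1.5% ("less than 2 percent" in the source study). The `no_dif` preset
gives both groups the girls' parameters and zero mean offsets — an
exactly invariant population for null calibration. `inject_dif` shifts a
single item's group-2 loading/thresholds for controlled-DIF experiments.

What the generator does **not** emulate: real-data model error (its
non-DIF items are *exactly* invariant and the factor model holds
exactly), unstandardized-scale DIF (only standardized values are
published), non-MCAR missingness, and acquiescence or method factors.
Consequences seen in the tests: the configural model fits essentially
perfectly (real data gave CFI ≈ 0.92), and the partial-invariance search
stops after freeing the four items with the largest standardized DIF
(caring, clingy, tantrum, obeys) because the ΔCFI criterion is already
satisfied — the free scale factors absorb much of the smaller DIF in
unhappy, afraid, reflective and bullied. Passing tests therefore
demonstrate correctness of the machinery under the stated population, not
that real SDQ data would free the same item set.

A deliberate consequence of the mixture design: fitting the *pooled*
modified model to two groups whose latent means differ inflates the
standardized tantrum→emotion cross-loading slightly (≈0.375 population
value versus 0.353 generating value); the pooled estimate is reported as
computed.

## Graded response model

Each subscale is fit separately by marginal maximum likelihood: EM with 41
Gauss–Hermite nodes for a standard-normal trait, per-item M-steps by
L-BFGS-B on (log a, b₁, log(b₂−b₁)) to keep a > 0 and b₁ < b₂, stopping
when the marginal log-likelihood improves by < 1e−6. The metric is pure
logistic — the 1.702 normal-ogive constant is *not* folded into a, and
the probit↔logit bridge a ≈ 1.702·λ/√(1−λ²) is verified in the tests at
10% tolerance. Test information sums the item Fisher informations of the
observed categories; curves are evaluated on θ ∈ [−4, 4] step 0.05. The
precision bands use r(θ) = I/(I+1), the reliability of the ML trait
estimate — the mapping of α bands onto information is an interpretive
choice, so curve shapes are illustrative rather than validation targets.

## Scale scores, reliability, descriptives

Subscale scores are sums of five (reversed) items, 0–10; the total
difficulties score sums the four problem subscales (prosocial excluded),
0–40. A person missing any item of a subscale gets a missing subscale
score — scores are descriptive here; the CFA works at item level with
pairwise deletion, so no prorating rule is needed. Cronbach's α uses
pairwise-complete Pearson covariances; ordinal α applies the
standardized-α formula to the polychoric matrix, with the total row over
the 20 problem items. Rendered tables round half-away-from-zero, three
decimals for loadings/thresholds/correlations and two for percentages and
effect sizes.

## Problem sizes used by the test suite

Deterministic identities run at desk scale. Stochastic checks use the
sizes at which their conditions are stated: parameter recovery at the
published n (5,399/4,854, fixed seed), the ΔCFI mechanism and null
calibration at n = 2,000 per group — the cutoff's null noise scales like
1/n, and at n ≈ 1,000 per group sampling fluctuation alone regularly
exceeds 0.002, which is a documented property of the fixed-cutoff rule,
not of this implementation. Margin and association convergence checks use
single groups of 20,000–50,000.

## Known limitations

- Exact Mplus/lavaan WLSMV numbers are not reproduced bit-for-bit: weight
  and Γ estimation details (pairwise-n conventions, threshold-correlation
  cross terms) differ legitimately between implementations, so test
  statistics agree in distribution and calibration rather than digit by
  digit.
- Modification indices are quadratic approximations; their magnitudes are
  trusted only for ranking, and the ladder's accept/reject decisions
  always come from full refits.
- The GRM ignores the local dependencies (restless↔fidgety,
  distractible↔attends) that the CFA models; its per-subscale information
  curves inherit that simplification, as is conventional.
- Standard errors for structural parameters are not computed (the study's
  questions are answered through fit comparison and recovery tests);
  sandwich covariances would be the natural extension.
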