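# Methods

## Models and parameterization

All three polytomous models use the unscaled logistic link; no 1.7
normal-ogive constant appears anywhere. The packaged 68-item bank fixes
this convention: its slopes cluster between 0.8 and 2, magnitudes
typical of unscaled-logistic estimates.

- **GRM** (slope–threshold form): cumulative curves
  `P*(X≥k|θ) = logistic(a(θ − b_k))` with one positive slope and
  strictly increasing thresholds per item; category probabilities by
  differencing adjacent cumulatives.
- **GPCM**: adjacent-category logits with an item slope and `m−1` step
  difficulties (no order constraint on steps).
- **NRM**: per-category slopes and intercepts with the first category's
  pair anchored at 0 for identification.

Mixed category counts (3/4/5 in the packaged bank) are carried per item;
nothing is padded at the parameter level. Fisher information is computed
from analytic category-probability derivatives as `Σ_k (P'_k)²/P_k`;
every item's information is verified against a central-difference
numerical oracle in the test suite (tolerance 1e−6).

## Quadrature and EAP scoring

The latent-trait prior is Normal(0, 1) discretized on 81 equally spaced
points over [−4, 4] with renormalized masses. The same grid serves the
calibration E-step and EAP scoring; a 2001-point refinement changes
full-bank EAP estimates by less than 0.01, which is far below the
estimate SDs involved, so the coarse grid is the default everywhere.
Likelihoods are accumulated in log space and the posterior is normalized
after subtracting its maximum, so underflow cannot silently zero the
posterior (an all-`−inf` posterior raises instead).

## Calibration (MML-EM)

The E-step computes each person's posterior over the grid from the
current item parameters; the M-step maximizes the expected complete-data
log-likelihood per item with a bounded quasi-Newton optimizer (L-BFGS-B)
on an unconstrained reparameterization: log slope, first threshold, and
log threshold increments for the GRM. This keeps slopes positive and
thresholds strictly ordered *by construction* rather than by re-sorting
after the fact, which is why the package never needs an "unordered
thresholds" repair path post-fit. Convergence is declared when the
maximum absolute change of the unconstrained parameter vector falls
below 1e−4 or the relative marginal log-likelihood change falls below
1e−7, capped at 500 EM cycles; non-convergence produces a flagged result
and a warning, not an exception. Starting values come from marginal
category proportions mapped through the logit. Missing responses
contribute a likelihood factor of 1 (missing at random); listwise
deletion, when wanted, is an explicit upstream step.

Model comparison fits GRM/GPCM/NRM on identical data and grid and
reports `AIC = −2ℓ + 2p` and `BIC = −2ℓ + p ln N`. When the two criteria
disagree, BIC decides and a warning is emitted; the disagreement case is
a genuine design choice since both criteria agreeing is the common
outcome on unidimensional ordinal scales and no convention is
universal. Absolute AIC/BIC values depend on quadrature and convergence
settings, so only the *selection* is treated as a reproducible output.

## Item screening

The four QC stages run in pipeline order, each consuming the previous
stage's survivors: unidimensionality → calibration → item fit → DIF →
discrimination.

- **Unidimensionality**: principal-component extraction from the
  Pearson correlation matrix of the raw ordinal codes (first-factor
  loadings = first eigenvector × √λ₁). Items with |loading| < 0.30 are
  dropped once and the factorization is repeated (two passes total);
  the screen passes when λ₁/λ₂ ≥ 3 and the first factor's variance
  share is ≥ 20%. Pearson-on-codes is a deliberate simplification —
  polychoric correlations are the more principled choice for ordinal
  data but attenuation affects the eigenvalue *ratio* much less than
  the individual correlations, and the thresholds used are coarse.
- **S-X² item fit**: observed category frequencies within rest-score
  groups are compared with model-expected frequencies, where the
  rest-score distribution at each quadrature point comes from the
  generalized (polytomous) summed-score recursion. Adjacent rest-score
  rows, and then adjacent category cells, are merged until every
  expected cell count reaches 1; degrees of freedom are
  Σ(group cells − 1) minus the item's free parameter count, and items
  with no usable degrees of freedom report p = NaN unflagged, with a
  warning. Under null simulations (data generated from the refitted
  model, 10 seeds × 10 items × n=1000) the flag rate at α = 0.05 is
  0.04 — within the ≤ 2α calibration band asserted by the test suite.
- **DIF**: per item, nested proportional-odds models on identical rows —
  `response ~ θ̂` versus `response ~ θ̂ + group + θ̂×group` — with the
  conditioning θ̂ taken as EAP scores from the current surviving bank
  (recomputed after any removal). The statistic is the McFadden
  pseudo-R² gain, `ΔR² = (ℓ_M2 − ℓ_M0) / (−ℓ_0)` with ℓ₀ the
  intercepts-only likelihood; items are flagged at ΔR² ≥ 0.02, the
  established magnitude criterion for this statistic. The threshold is
  configurable. ΔR² is invariant to swapping the group coding and is
  clipped at 0 against optimizer noise in the nested fits.
- **Discrimination**: GRM/GPCM items with `a < 0.8` are removed; the
  cutoff is inclusive on the retained side (a = 0.8 survives).

## The adaptive engine

Administration starts from a uniformly random bank item (a dedicated
seeded generator, so respondent simulation and administration draw from
independent streams; a fixed first item can be configured instead).
After every recorded response the trait is re-estimated by EAP and the
stopping check runs — never before the first response, so the minimum
test length is 1. Stopping uses the information-based standard error
`1/√(Σ_administered I_j(θ̂))` as printed in the formula block above; the
EAP posterior SD is recorded alongside for diagnostics but does not
drive stopping. Selection is maximum Fisher information at the current
θ̂ among unadministered items, ties broken deterministically by bank
position. With a threshold set, the cap defaults to 20 items; with no
threshold, the entire bank is administered and the final estimate equals
the full-bank EAP by construction. In post-hoc mode the respondent
oracle reads a pre-generated complete response vector, so adaptive and
full-bank scores share response realizations; an item with no available
answer is skipped with a warning and excluded from further selection.

## The synthetic cohort and what it does (not) show

The generator draws θ ~ Normal(0, 1) — the scale the bank is calibrated
on — and samples each response by inverse CDF from the item's category
distribution at the respondent's θ. The study default is n = 1000,
matching the order of magnitude of the screening samples this kind of
instrument is built on. Each respondent carries a stable sub-seed, which
makes study summaries invariant to respondent ordering.

Because responses are drawn *exactly* from the calibrated GRM, the
synthetic cohort contains no model misfit, no careless or extreme
response styles, and no item-content effects. Consequences worth
keeping in mind: adaptive/full-bank score correlations run one to two
points of the second decimal *higher* than they would on comparable real
data, and the full-bank marginal reliability lands slightly below the
value a real, information-rich score distribution can show. Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery under the stated population model, not field performance
of any specific instrument.

## Evaluation conventions

- Marginal reliability aggregates per-person SEs as `1 − mean(SE²)` on
  the unit-variance scale (so a constant SE of 0.19 gives 0.964). The
  "mean SE" column of study summaries averages SE itself, not SE².
- Screening cutoffs are inclusive (criterion score ≥ cutoff is
  positive). AUC uses the rank/Mann–Whitney formulation with midranks,
  so ties count 1/2. The Youden identity `J = se + sp − 1` holds exactly
  at every cutpoint; the default cutpoint chooser maximizes J over
  observed scores with ties resolved to the lowest cutpoint.
- The diagnosis curve is a logistic regression of the binary criterion
  on the adaptive score (a nonparametric smoother would also be
  defensible; logistic keeps the 0.50-probability score interpretable as
  `−intercept/slope`). Percentile ranks use the midrank convention.
- Descriptive moments use the n−1 variance denominator, standardized
  third moment for skewness, and *excess* kurtosis (normal = 0) — the
  convention implied by the negative kurtosis values a bank of
  right-skewed symptom items produces.

## Problem sizes in the shipped tests

Recovery and null-calibration checks run at n = 1000 persons with
10-item banks (slopes 0.9–1.8, thresholds spread over [−2, 2]); model
comparison at n = 500 with 6 items; DIF checks at 600–1000 per group;
the study reproduction at n = 1000 on the full 68-item bank. These sizes
keep every statistical assertion comfortably inside its tolerance while
the whole suite stays desk-scale. Threshold recovery degrades for
thresholds beyond roughly ±3 (few observations fall in the relevant
categories at realistic n), which is a property of the data, not the
optimizer — the packaged bank's most extreme thresholds (up to 4.38) are
kept as printed but would not be re-estimable to two decimals from
n = 1000.

## Known limitations

- No multidimensional, bifactor, or testlet models; no 1.7-scaled
  normal-ogive variant.
- No item-parameter standard errors or MCMC calibration; no
  linking/equating across forms.
- The CAT engine implements no exposure control or content balancing —
  deliberate, as the target workflow uses none.
- DIF is a screening flag (total effect), not a uniform/non-uniform
  decomposition.
- Polychoric-based factor extraction is not implemented; the Pearson
  route is the default and only path.
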