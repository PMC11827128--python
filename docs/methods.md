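# Methods

## Model and estimation

Items follow the logistic graded response model with one slope `a > 0`
and strictly ordered boundary locations `b_1 < ... < b_{K-1}` per item
(`K = 5` throughout; the pure logistic metric is used, no 1.7 scaling
constant). Category probabilities are adjacent differences of the
boundary curves and are floored at 1e-12 before any log or division.
Responses are 1..K at every API surface and 0..K-1 only inside array
code.

Calibration is marginal maximum likelihood via Bock–Aitkin EM with a
fixed latent quadrature of 61 equally spaced nodes on [-6, 6] weighted
by the standard-normal density (renormalized). The M-step maximizes each
item's expected complete-data log-likelihood with bounded L-BFGS on the
parameterization (log a, b₁, log gaps), which enforces the slope and
ordering constraints by construction; warm starts from the previous
cycle make this a generalized EM, so the marginal log-likelihood is
non-decreasing (asserted to 1e-8 in tests). Slopes are boxed to
[0.05, 25]: near-duplicate response columns otherwise push the slope to
infinity (a quasi-Guttman degeneracy; estimates above 8 additionally
warn). Start values are slope 1 and thresholds at normal quantiles of
the observed cumulative category frequencies. Convergence is the largest
absolute parameter change below `em_tol` (default 1e-4; the simulation
studies in the test suite use 1e-3, which changes recovered parameters
by less than the Monte-Carlo noise) with a 500-cycle cap.

Trait scores are posterior modes (MAP) with a standard-normal prior,
found by bounded scalar minimization on [-6, 6]; the reported standard
error is the reciprocal square root of the posterior curvature
approximation `I(θ̂) + 1/σ²_prior`. Including the prior precision keeps
the error defined after very few items, which the stopping rule needs.

## Screens

Thresholds are the method's standard cutoffs and all live in `RunConfig`:
item-remainder r < 0.3 (one pass, on the item set entering the stage),
first-principal-component variance share ≥ 0.20 with first/second
eigenvalue ratio ≥ 4 (else iterative removal of the smallest absolute
first-component loading), one-factor residual correlation > 0.2 (refit
after each removal; the pair member with the smaller first-component
loading leaves), Loevinger H_i < 0.3 (one pass), never-modal categories
on a θ grid [-4, 4] step 0.01 (ties count for all tied categories),
S-X² and DIF at α = 0.01. PCA and the one-factor fit use Pearson
correlations of the raw 1..5 scores, not polychorics — the default of
the common factor-analysis tooling for this design. Ties in loadings or
H break by input item order, for determinism.

The one-factor model behind the local-dependence screen minimizes the
normal-theory discrepancy over loadings bounded in (-0.999, 0.999) with
unit-diagonal implied correlation; hitting the bound is a clamped
Heywood case and warns.

S-X² conditions on the rest score. Expected tables come from the
generalized Lord–Wingersky summed-score recursion over the quadrature;
adjacent rest-score groups are merged until each can support the K
category cells, then adjacent categories within a group are merged until
every expected cell is at least 1. Degrees of freedom are the collapsed
cell count net of the per-group total constraints, minus the item's K
free parameters; df ≤ 0 leaves the item untestable (retained, with a
warning). Under the correctly specified model the empirical exclusion
rate at α = 0.01 is about 0.006 (see the acceptance suite).

The DIF screen fits a two-group GRM in which the reference group's
latent distribution is fixed at N(0,1), the focal group's mean and
variance are free (updated from posterior moments inside EM), and the
baseline constrains all item parameters equal across groups. Each item's
test frees that item's K parameters in the focal group with all other
items as anchors; the likelihood ratio is referred to χ²(K). Tests are
simultaneous against the one baseline, not sequentially purified. Items
with a category unused in either group are skipped with a warning.

## Adaptive testing

Selection is unweighted Fisher information at the current trait
estimate, starting from θ = 0, ties toward earlier bank order, no
exposure control; the trait is re-estimated after every response.
Stopping: SEM ≤ 0.32 once at least `min_items = 3` items are
administered, else exhaustion of `max_items` (defaulting to the full
bank). With the SEM threshold set to 0, a session administers the whole
bank and its final estimate equals the one-shot MAP score of the
complete response vector.

## Synthetic data

The generator emulates a typical calibration sample: several hundred
respondents (default 600), θ ~ N(0,1), 5-point items with slopes a ~ U(1.0, 2.5), sorted
normal threshold draws (spread 1.0) pushed apart to a minimum gap of
0.3, two-group labels for DIF and discriminant validity, and external
criterion columns that are ±θ plus N(0,1) noise — a deliberately
minimal stand-in for a real external instrument. Simulated CAT responses
are freshly sampled from the calibrated model at each respondent's
full-bank score (θ_true); a replay mode exists for the full-bank
equivalence check. Each respondent's response stream is keyed to their
trait value rather than their position, so pooled statistics are
invariant to respondent ordering.

Violations are injectable one item each: an emptied category, a pure
noise column, a pair regenerated from θ + δ with shared nuisance
δ ~ N(0, 0.8²), a partially reversed item (a random quarter of
respondents answer at −θ), and a +0.75 focal-group threshold shift.
Injections target the most discriminating items (weak items would be
screened out on their own, confounding attribution); effect sizes sit
deliberately near the screens' operating points.

## Problem sizes and numerical choices

The test suite runs its simulation studies at sizes chosen to finish in
minutes on one CPU: parameter recovery over 20 seeds at n = 1000 and 10
items; S-X² type-I calibration over 200 replicates and DIF type-I over
100 replicates at n = 600 and 10 items; the headline accuracy experiment
at a single seed with a 50-item bank and n = 600; screening-funnel rates
over 15–20 seeds. The MAP grid oracle uses step 1e-4 and agreement
tolerance 1e-3; the information function is validated against central
finite differences at 1e-4.

## What passing tests do and do not show

The generator draws unidimensional, locally independent, monotone GRM
data by construction, so clean-data screening results measure the
screens' false-positive behavior, not their validity on real mood items.
Two structural findings from the synthetic conditions are worth knowing:

- Items with slopes near the generator's lower bound (a ≈ 1.0) have
  population Loevinger H of about 0.31 in these banks, so the H < 0.3
  screen excludes one of them in roughly 15% of clean datasets at
  n = 600. Item pools whose retained items are more discriminating (as
  fielded mood scales with internal consistency above 0.9 tend to be)
  would not sit on this boundary.
- With thresholds drawn as sorted N(0,1) values, middle categories of
  a ∈ [1, 2.5] items are almost never the modal response anywhere on the
  θ axis, so the never-modal screen would excise such banks nearly
  wholesale. That is the screen working as intended on narrow category
  bands, not a defect; end-to-end pipeline demonstrations therefore use
  a category-functional bank (threshold spread 1.2, minimum gap 1.2)
  whose every category is modal somewhere, as is true of fielded Likert
  items that survive this screen.
- Under SEM-0.32 stopping with a ~ U(1, 2.5) banks, the pooled
  correlation between adaptive and full-bank scores is structurally
  about 0.94–0.95: the stopping rule caps the adaptive score's posterior
  SEM near 0.31, and θ_true itself carries measurement error (SE ≈ 0.16
  for 50 such items). Reaching clearly beyond 0.95 requires more
  discriminating items than this generator draws.

## Known limitations

No missing-data machinery beyond complete-case filtering; no polychoric
factor analysis; no exposure control or content balancing; two groups
only for DIF; the external validity columns are linear in θ rather than
a simulated instrument. The DIF baseline is refit per scale, which is
the dominant cost of the full pipeline at large item counts.
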