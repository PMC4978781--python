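# Methods

## Model and the linking problem

The 3PL response probability for person ability θ and item parameters
(a, b, c) is `c + (1 − c)Ψ[a(θ − b)]` with Ψ the standard logistic. The
joint likelihood of a response matrix is a product of Bernoulli terms; the
success probabilities π_pi are identifiable, the item/person parameters
behind them are not. Three concrete failures are implemented as executable
demonstrations (`irtlink.identifiability`):

1. with a ≡ 1, the Maris form π = (ϑ + δ)/(ϑ + β) (ϑ = e^θ, β = e^b,
   δ = c·e^b) is invariant under adding a constant to every ϑ while
   subtracting it from every β and δ;
2. with a common ability θ for all persons, scaling γ = 1 − c by
   κ ∈ (1 − Ψ, 1] is exactly compensated by
   `b* = θ − ln(κ(1 + E) − 1)/a`, `θ* = b + ln(κ(1 + E) − 1)/a`, or
   `a* = ln(κ(1 + E) − 1)/(θ − b)` where `E = exp(a(θ − b))`; the `a`
   trade-off additionally needs κ > 2(1 − Ψ) and θ > b for a positive
   compensated slope. An explicit override exposes the negative branch for
   plotting; it is off by default.

Because each calibration resolves the indeterminacy with its own
restrictions (θ ~ N(0, 1) in MML practice), the same item gets different
values in different calibrations, connected by a componentwise monotone map
that for the 3PL is affine: θ* = uθ + v, a* = a/u, b* = ub + v, c* = c.

**Direction convention.** All links map source (calibration 1) onto target
(calibration 2): `u = a_source/a_target` for a common item. The convention
is stated in every report because the classical "new form onto old form"
formulas are written in the opposite orientation.

**Slope-intercept form.** Under the parameterization αθ + β the link has
three parameters: α* = (α − u)/v, β* = β + u, ϑ* = (ϑ − u)/w, identifiable
only from designs with both a common item and a common person
(`si_link_from_design`). The (u, v, w) family is over-parameterized relative
to the two-parameter standard link; rather than impose an unstated
constraint tying them together, `si_apply_link` returns the logit-invariance
residual α*ϑ* + β* − (αϑ + β), which vanishes for links derived from a
consistent design and is the caller's check otherwise.

## Link estimators

Given matched common-item tables (and optionally per-item covariance
matrices of the estimates within each calibration):

- **per item + precision weighting**: u_i = a_i₁/a_i₂,
  v_i = b_i₂ − u_i b_i₁. First-order delta SEs treat the two calibrations
  as independent and items as independent across the table, keeping the
  within-item (a, b) covariance per calibration:
  `Var(u_i) = σ²_{a₁}/a₂² + a₁²σ²_{a₂}/a₂⁴`; for v_i the gradient with
  respect to (a₁, b₁, a₂, b₂) is (−b₁/a₂, −u, u·b₁/a₂, 1). Cross-item and
  cross-calibration covariances are taken as zero — the per-item blocks are
  all that a separate-calibration workflow provides. Pooling uses weights
  1/SE², giving pooled SE (Σ SE⁻²)^(−1/2), never above the best single item.
- **mean/mean** (and geometric-mean variant): u = μ(a₁)/μ(a₂),
  v = μ(b₂) − u·μ(b₁); SEs propagate u's dependence on the a's into v.
- **mean/sigma**: u = σ(b₂)/σ(b₁) with population (divide-by-n) SDs —
  u is invariant to the n vs n−1 choice — and ∂σ(b)/∂b_i =
  (b_i − μ(b))/(nσ(b)) in the delta method.
- **Stocking–Lord / Haebara**: bounded Powell minimization (u ∈ [0.1, 10],
  v ∈ [−5, 5], start (1, 0), xtol 1e-10) of the squared difference of summed
  (respectively per-item) response functions over a default grid of 41
  equispaced θ in [−4, 4] with unit weights; grid and bounds are
  configurable. The Haebara criterion is implemented as the per-item
  squared-difference sum, the standard form in the linking literature.
  These two criteria are the only estimators touched by error in the c
  estimates, since φ_c is the identity; a test demonstrates that perturbing
  target c's moves Stocking–Lord but not the per-item identification.

All estimators recover a true link exactly (machine precision for closed
forms, 1e-6 for the optimizer) on noise-free transformed tables.
`sequential_se_curve` re-estimates on the first k items of a given order;
the precision-weighted SEs are nonincreasing in k by construction and the
k = n endpoint is order-invariant. The two packaged orders are table order
(discrimination blocks) and increasing generating difficulty with ties
broken by discrimination then row index — the difficulty order's
tie-breaks are this package's convention.

First-order delta SEs are accurate when the coefficient of variation of the
discrimination estimates is small. At cv(â) ≳ 12% the Monte-Carlo SD of the
ratio u_i exceeds the delta SE by 5–8% (heavier ratio tails); the v_i SEs
are less affected. This is an inherent property of the first-order
approximation, which is nevertheless the standard reported quantity and the
one the worked example's printed SEs correspond to.

## MML-EM calibration

Bock–Aitkin EM with a fixed standard-normal quadrature prior: 61 equispaced
nodes on [−5, 5] with normalized N(0, 1) masses (dense enough that EAP
values agree with a 401-node grid to 1e-3). The E-step computes per-person
posterior masses over nodes; the M-step maximizes each item's expected
Bernoulli log-likelihood by bounded L-BFGS-B with analytic gradients, warm
started at the current estimates, so the marginal log-likelihood is
nondecreasing (asserted per run). Convergence: largest absolute parameter
change < 1e-4, cap 500 cycles; non-convergence flags the result and warns,
never silently returns. Response probabilities inside likelihoods are
floored at 1e-12 (configurable in `log_likelihood`), with a warning when
clamping occurs.

The unpenalized 3PL likelihood is near-flat in c. When c is estimated, a
weak logit-normal prior centred at logit(0.25) (SD 1.0) plus box bounds
a ∈ [0.05, 5], c ∈ [0.001, 0.5] stabilize the M-steps; the prior is on by
default exactly when c is free, off for the 2PL, and always recorded in the
result's settings. Fixing c at a known value (`c_fixed`) is the
configuration the built-in study uses.

Per-item covariances are the inverse of the cross-product matrix of
per-person marginal score vectors, s_p = Σ_k w_pk ∂log f(u_p|θ_k)/∂ξ with
posterior weights w_pk, accumulated at the solution. Unlike the expected
complete-data information, this accounts for the latency of θ; a
parametric-bootstrap check (50 replications) keeps the ratio of bootstrap
SD to reported SE within 30% for mid-range items. Cross-item blocks are not
reported (the EM blocks are item-separable given the posterior).

Calibrating data whose abilities were drawn from N(m, s) under the
θ ~ N(0, 1) restriction re-expresses parameters as a → a·s, b → (b − m)/s —
verified as a regression property in the tests — which is precisely why two
calibrations of the same items need linking.

## The built-in study and what it does (not) show

`StudyDesign` encodes a two-form common-item study: 20 common items
(b ∈ −2(.5)2 with 0 twice, crossed with a ∈ {.5, 1.5}, all c = .25),
20 unique items per form (a ~ U(.5, 2), b ~ N(0, 1), c = .25), and group
abilities N(−.5, 2) and N(.5, 1.5) with 10,000 examinees each. The second
distribution argument is read as an SD by default; `scale_is_sd=False`
switches to the variance reading. Neither reading is asserted as the
historically correct one — the flag exists because the notation is
ambiguous. Under the SD reading the design-implied link is
u = 2/1.5 ≈ 1.333, v = −1/1.5 ≈ −0.667.

`run_linking_study` simulates both groups, calibrates each form separately
(default: c fixed at the design's generating .25, tolerance 5e-4, 200-cycle
cap — sample-size-appropriate settings for this design), and runs the full
estimation battery plus both sequential-SE orders. The `noise_free` mode
replaces simulation and calibration by the analytic re-expression above and
is the bridge between design parameters and estimators: every estimator
must return the design-implied link exactly there. It is a verification
device of this package, not an empirical procedure.

The acceptance checks run the stochastic study at 2,000 examinees per group
over 20 seeded replications — a problem size chosen to exercise the whole
pipeline at desk scale — and require the precision-weighted û to cover the
design-implied u within three pooled SEs in at least 18 of them.

What the simulator does *not* emulate: real response data features such as
local dependence, multidimensionality, speededness, missingness by design,
or examinee groups that are not normal. Passing tests show the estimators
and their SEs behave as advertised under the model's own assumptions; they
do not certify behaviour under misfit.

## Packaged worked-example tables

The three fixture CSVs (common-item generating values with both
calibrations' estimates; per-item covariance matrices; per-item link
estimates with SEs) are checksummed, and `regenerate_table3` recomputes the
third from the first two: the u_i and v_i reproduce exactly at three
decimals. The printed covariance entries carry only three decimals, so the
regenerated per-item SEs can differ from the printed ones by up to ~0.005
where variances are as small as 0.007 (±7% rounding on a variance is ±3.5%
on an SE); the pooled SEs agree to ~0.001. Several printed 3×3 covariance
matrices are mildly indefinite for the same reason; the delta method uses
only their (a, b) blocks, and the PSD check warns rather than fails.

## Numerical choices and edge cases

- c = 0 is allowed (2PL submodel); c = 1 is rejected everywhere an item is
  validated (an item with c = 1 is uninformative) — the operative range for
  the lower asymptote is [0, 1). The response simulator accepts degenerate
  table rows (e.g. c = 1) for constructing boundary checks.
- Degenerate designs raise typed errors: equal source difficulties in the
  two-item solver, a single common person (not identifiable), item-only or
  person-only designs for the slope-intercept link.
- Trade-off curves emit missing values outside each target's admissible
  range instead of raising, so full-grid plots can be drawn.
- Constant-response items (all 0 or all 1) are rejected before calibration;
  all-missing persons are rejected when a response matrix is built.
- Item tables and covariance tables are validated against their schemas on
  read, with offending columns and line numbers named.

## Known limitations

- Statistical theory beyond the first-order delta method (consistency,
  asymptotic efficiency of the precision-weighted estimator, robust or
  weighted response-function variants) is out of scope.
- Only the 3PL family's closed-form links are implemented; for other
  monotone continuous response models only the existence of componentwise
  monotone links is relied upon, not their shape.
- The calibrator is a desk-scale Bock–Aitkin implementation: single
  N(0, 1) quadrature prior, no adaptive quadrature, no concurrent
  calibration of multiple forms, no polytomous or multidimensional models.
- Exact replication of any third-party program's estimates is not
  attempted; calibration quality is assessed by parameter-recovery and
  bootstrap properties instead.
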