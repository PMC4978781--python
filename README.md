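# irtlink

Linking 3PL item response model parameters across calibrations.

## The problem

The three-parameter logistic (3PL) model gives the probability that person
*p* answers item *i* correctly as

```
p(θ_p; a_i, b_i, c_i) = c_i + (1 − c_i) · Ψ[a_i(θ_p − b_i)],
Ψ(x) = exp(x) / (1 + exp(x)),
```

with discrimination `a_i > 0`, difficulty `b_i`, and lower asymptote
(guessing) `c_i`. The model is not identifiable: many parameter
configurations imply exactly the same response distribution, so every
calibration must impose restrictions — in practice MML estimation with
θ ~ N(0, 1), which pins the ability scale to the calibration sample. Two
separate calibrations therefore assign *different* parameter values to the
*same* items, and the values must be **linked** before they can be compared.
For the 3PL in its standard parameterization the link is affine:

```
θ* = uθ + v,    a* = a/u,    b* = ub + v,    c* = c,
```

with `u` the ratio of (θ − b) differences across the two scales. The `c`
parameters need no linking at all; methods that use the full response
function (Stocking–Lord, Haebara) consequently mix estimation error in `c`
into the link, while the moment and per-item methods do not.

The package is for psychometricians and measurement researchers who need to
place item banks, test forms, or ability estimates from separate
calibrations on one scale — and to know the standard error of the linking.

## What is implemented

- `irtlink.model` — the 3PL response function, slope-intercept and
  multiplicative-Rasch reparameterizations, Bernoulli log-likelihood.
- `irtlink.identifiability` — numerical demonstrations of
  non-identifiability: the Maris-form shift and the γ = 1 − c scaling
  trade-offs against `b`, `a`, or θ, with admissibility bounds and
  full trade-off curves.
- `irtlink.linking` — the affine link (apply, invert, compose) and its
  identification from minimal designs (one common item; two common items;
  two common persons), plus the three-parameter slope-intercept link, which
  is identifiable only from designs with both common items *and* persons.
- `irtlink.estimation` — link estimators over common-item tables:
  per-item `u_i = a_i₁/a_i₂`, `v_i = b_i₂ − u_i b_i₁` with first-order
  delta-method SEs, inverse-variance (precision-weighted) pooling,
  mean/mean, log-mean/mean, mean/sigma, Stocking–Lord and Haebara, and
  sequential SE curves as items accrue. Estimators follow the
  scikit-learn protocol (`fit`, `transform`, `get_params`, trailing
  underscore attributes).
- `irtlink.calibration` — Bock–Aitkin MML-EM calibration with θ ~ N(0, 1),
  per-item covariance matrices from the cross-product of marginal scores,
  EAP ability estimation, and a seeded response simulator.
- `irtlink.study` — a two-form common-item linking-study generator
  (20 common + 20 unique items per form, c = .25, difficulty grid −2(.5)2
  crossed with a ∈ {.5, 1.5}, group abilities N(−.5, 2) and N(.5, 1.5),
  10,000 examinees per group, scalable), a noise-free analytic mode, and the
  packaged worked-example tables.
- `irtlink.io` / `irtlink.cli` — CSV/JSON/YAML schemas and the `irtlink`
  command-line tool (`tradeoff`, `link apply|estimate`, `calibrate`,
  `simulate-study`, `report`).

## Worked example

The package ships the worked example's common-item estimates from two
calibrations of the study design above, together with their per-item
covariance matrices:

```python
from irtlink import PrecisionWeightedLink, fixture_calibration_tables

source, target, cov1, cov2 = fixture_calibration_tables()
est = PrecisionWeightedLink().fit(source, target, cov1, cov2)
print(f"u = {est.u_:.3f} (SE {est.se_u_:.3f})")
print(f"v = {est.v_:.3f} (SE {est.se_v_:.3f})")
print(est.per_item_.head(3).round(3).to_string(index=False))
```

prints

```
u = 1.226 (SE 0.026)
v = -0.687 (SE 0.024)
 item_id     u      v  se_u  se_v
       1 1.208 -0.707 0.104 0.102
       2 1.160 -0.686 0.089 0.072
       3 1.108 -0.630 0.078 0.050
```

Each row is one common item's own estimate of the link (`u_i` the ratio of
its two discrimination estimates, `v_i` from its difficulties), with
delta-method standard errors; the header lines are the precision-weighted
combination. `u ≈ 1.23, v ≈ −0.69` says the first calibration's scale must
be stretched by 1.23 and shifted down by 0.69 to land on the second's —
the direct consequence of the two samples' ability distributions
(N(−.5, 2) vs N(.5, 1.5)) both being standardized to N(0, 1) during
calibration. `est.transform(items)` then maps any calibration-1 item table
onto the calibration-2 scale, e.g. item 1's `(2.612, −0.843)` to
`(2.130, −1.720)`, within estimation error of that item's calibration-2
estimates `(2.162, −1.725)`.

The same analysis from the shell:

```sh
irtlink report --out report.json
```

## File formats

- item tables: CSV `item_id,a,b,c`
- covariance tables: CSV `item_id,var_a,var_b,var_c,cov_ab,cov_ac,cov_bc`
  (one row per item within one calibration)
- response matrices: CSV `person_id` + one 0/1 column per item
- links: JSON `{"u": ..., "v": ..., "direction": ...}`; reports: JSON with
  `methods`, `per_item`, `provenance` blocks; study designs: YAML

Every link in this package maps **calibration-1 (source) parameters onto the
calibration-2 (target) scale**; reports embed that convention string.

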