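# Methods

## Design and notation

Each case `i` contributes a vector of binary exposure indicators
`x_i = (x_i0, x_i1, ..., x_iM)`: period `m = 0` is the hazard period ending
at the event, and `m = 1..M` are referent (control) periods counted backward
in time. Optionally a binary time-varying confounder `z_im` is recorded on
the same grid. Cases may carry an integer `multiplicity` so that
expected-count (deterministic) datasets can be stored compactly; every
estimator treats a case with multiplicity `k` exactly like `k` identical
unit cases.

A case is *exposure-concordant* when all `x_im` are equal; such cases carry
no information about the exposure effect and are dropped (counted in
`n_concordant_dropped` / reported as `n_informative`).

## Estimators

### Standard conditional logistic (`ConditionalLogitOR`)

Maximises `sum_i w_i [ eta_i0 - log sum_m exp(eta_im) ]` with
`eta_im = beta * x_im (+ gamma * z_im)`. Valid only when each subject's
period labels are exchangeable given the multiset of exposures; under
within-subject autocorrelation the estimate is biased, and the bias grows
with `M` (see the `cyclic` grid: 4.00 at `M = 1`, 3.55 at `M = 3`, 6.02 at
`M = 21`, 7.92 at `M = 69`, 8.71 at `M = 139`).

### Mantel–Haenszel (`MantelHaenszelOR`)

Each case is a stratum; with one hazard period the matched-pair estimator
reduces to a person-time ratio

```
OR_MH = sum_i PT10_i / sum_i PT01_i
```

where `PT10_i` is the number of control periods with `x = 0` for a case
exposed at `m = 0` (and symmetrically `PT01_i`). Variance is
Robins–Breslow–Greenland over the per-case 2x2 strata; at `M = 1` it reduces
exactly to `1/a1 + 1/a0` (discordant-pair counts). Confounder stratification
("delete discordant-confounder periods") keeps only control periods with
`z_im = z_i0`. `OR_MH` is consistent whenever period pairs are pairwise
exchangeable — strictly weaker than the full exchangeability that the
conditional-logistic likelihood needs.

### Weighting method (`WeightedGreenlandOR`)

Estimates the discordance ratio

```
pi10 = mean(PT01) / mean(PT10)   over exposure-discordant cases
```

and enters per-period weights `w1 = pi10 / m1`, `w0 = 1 / m0` (with `m1`,
`m0` the per-case counts of exposed / unexposed periods) into the
conditional-likelihood denominator as log offsets. For a single binary
exposure the maximiser has the closed form

```
OR_G = (a1 / a0) / pi10 ,   var(log OR_G) = 1/a1 + 1/a0
```

which the implementation computes directly and cross-checks against the
offset fit (tolerance 1e-6). Algebraically `OR_G = OR_MH` on every dataset
(verified property-wise in the tests). With `adjust_confounder=True` the
weights are still computed from the exposure alone and `(beta, gamma)` are
fit jointly; `weighting="unit"` reproduces the standard conditional fit.
Percentile-bootstrap intervals resample cases with replacement (multiplicity
expanded first) and re-estimate `pi10` within each replicate.

### Permutation likelihood (`VinesFarringtonOR`)

Given a table of population sequence probabilities `P(x_0, ..., x_M)`, the
likelihood for case `i` sums over all distinct arrangements of the observed
within-subject multiset. Rather than enumerating `(M+1)!` permutations,
arrangements are grouped by the value at the case period, giving at most two
(four with a confounder) distinct case-period values; group masses use exact
combinatorial counts, and the grouped terms are fed through the same Newton
solver as pseudo-rows with log-mass offsets. A full permutation enumeration
oracle in the tests confirms the grouping. The confounder variant factorises
`P(x)·prod_m q(z_m | x_m)` with `q(1|1) = f1`, `q(1|0) = f0`
(defaults 0.4 / 0.2, matching the generator).

The method requires positivity: for each case, at least one supported
arrangement must move exposure into and out of the case period. Cases that
fail are excluded with a diagnostic; if all fail, `NoInformativeCasesError`
is raised. With the 7-day cyclic table this happens exactly when `M + 1` is
a multiple of the cycle length (window lengths 7, 14, 21, ... days), because
then every subject's window contains a fixed number of exposed days and no
arrangement is distinguishable.

### Bias diagnostic (`diagnose_bias`)

Reports `|OR_SCL - OR_MH| / OR_MH` (confounder ignored) and flags the
dataset when it exceeds `threshold_fraction` (default 0.10). Under the
default scenario the flag turns on at `M = 6` and stays on.

## Simulator

`build_cyclic_population` constructs a stationary population on a
`cycle_length`-day cycle (default 7) exposed on `exposed_days`
(default {1, 4}), with `n_per_subgroup` members (default 10 000) in each of:

- one *stopper* subgroup (label A): carries the phase whose case day is the
  first exposed cycle day but has stopped, so `x_0` is forced to 0;
- *ongoing* subgroups (B, C, ...): one per remaining cycle phase, exposed
  whenever the lagged day falls on an exposed day; the phase whose case day
  is the second exposed cycle day is the exposed-at-case ongoing group;
- one *starter* subgroup (H with defaults): exposed at `m = 0` only.

The lagged cycle day at lag `m` is `((case_day - 1 - m) mod C) + 1`. With
the defaults, exactly 2 of the 8 subgroups are exposed on every day, so the
exposed fraction is 1/4 at all times — the population is stationary and
pairwise exchangeable, which is what makes the conditional-logistic bias a
pure artifact of within-subject dependency. The constructor asserts this
stationarity.

`expected_cases` generates deterministic expected counts: each subgroup of
size N contributes `N * r0` cases if unexposed at `m = 0` and `N * RR * r0`
if exposed (defaults `r0 = 0.001`, `RR = 4` give 10/40 per subgroup, 140
total). Non-integer expected counts are rejected rather than rounded
(tolerance 1e-9). `expected_cases_with_confounder` splits each subgroup by
the confounder state at the case period using `RRz` (default scenario
`RRz = 2` gives strata (8, 4) unexposed / (24, 32) exposed, 184 total) and
draws control-period confounders as independent Bernoulli with
`P(z=1 | x) = f1 = 0.4` if exposed, `f0 = 0.2` otherwise, from
`numpy.random.default_rng(seed)`. The exposure process stays deterministic;
only the confounder draw is random, so crude person-time ratios such as the
ignoring-`z` Mantel–Haenszel OR (14/3 ≈ 4.67) are exact.

The `motivating` scenario is a 3-day cycle exposed on days {1, 2} with three
ongoing subgroups and no stopper/starter; its conditional-logistic OR is the
root of `3 psi^2 - 7 psi - 8 = 0`, i.e. `(7 + sqrt(145)) / 6 ≈ 3.17`.

What the generator does **not** emulate: stochastic case sampling (counts
are expectations), exposure measurement error, continuous exposures,
subject-level effect heterogeneity, or calendar trends.

## Aggregation

`aggregate_periods` forms `d`-day periods backward from the case day; period
`j` covers lag days `j*d .. j*d + d - 1`, the newest day of a block is index
0, and oldest leftover days are dropped. Definitions:

- **I** — period exposed iff its last (newest) day is exposed;
- **II** — control periods exposed iff at least half the days are exposed
  (`2 * count >= d`, ties exposed); case period uses the last-day rule;
- **III** — control periods exposed iff any day is exposed; case period uses
  the last-day rule;
- **IV** — any-day rule for all periods including the case period.

Confounders aggregate by the same rule. Aggregating the default 22-day
window to 7-day periods under Definition I leaves `M = 2` and a
conditional-logistic OR of `3 + sqrt(13) ≈ 6.61`.

## Numerical choices

- Conditional-likelihood maximisation is a hand-written Newton–Raphson with
  analytic gradient/Hessian, log-sum-exp stabilisation, step-halving, and a
  BFGS fallback when the Hessian is singular (`tol = 1e-10`,
  `max_iter = 100`). A hand-written solver is used because the denominator
  log-weight offsets required by the weighting and permutation methods are
  not expressible in standard conditional-logistic APIs; the statsmodels
  `ConditionalLogit` is used in the test suite as an independent oracle for
  the unweighted case (agreement 1e-6 on the default scenario).
- `|theta| > 30` is treated as separation: the fit is flagged, the OR is
  reported as 0/inf, and no Wald interval is produced.
- Ragged within-case rows are padded with `-inf` log-weights so all cases
  fit one dense array.
- Bootstrap replicates use `numpy.random.default_rng(seed)`; replicates
  that fail to fit are counted and skipped, with a warning recorded when
  more than 10 % fail.
- Random streams in the CLI and acceptance script are derived from the user
  seed via `numpy.random.SeedSequence` spawning keyed on a label digest, and
  all derived seeds are kept below 2^31.
- Problem sizes: the default scenarios have ≤ 184 distinct case patterns
  (multiplicities cover 80 000 subjects), so every fit completes in well
  under a second; the full test suite runs in about 10 seconds on one CPU.
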