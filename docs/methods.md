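# Methods

## Cohort definitions and standardization

The unit of observation is one examined child (exam year, age in whole
years, sex, residence parish, birth class, dmfs).  A caries case is
dmfs > 0 — manifest dentin caries; early enamel lesions are outside this
case definition, so prevalences here underestimate total caries activity
exactly as registry analyses of dentin-level data do.  Records with a
missing or unparseable age/dmfs, an age outside [0, 19], an unknown birth
class or an empty parish are rejected at ingestion with a logged row
number; there is no imputation.  The domestic vs foreign-born split is an
input column — the package makes no attempt to infer migration timing.

Expected counts are internally standardized by sex only:
`E_i = Σ_s n_is · r_s` with `r_s` the region-wide case rate in sex stratum
`s`, computed from the same filtered cohort, so `Σ E = Σ O` by
construction.  Age is deliberately not a stratum; each calendar year is
standardized and mapped separately, which also handles secular change in
the age mix.  Reported percentages round half-up to one decimal, matching
how such tables are printed.

## The spatial smoothing model

For parish *i*: `O_i ~ Poisson(E_i θ_i)`, `log θ_i = α + u_i + v_i`.

* `u` — intrinsic conditional autoregressive (ICAR) effect on the parish
  adjacency graph: each `u_i` is conditionally normal around the mean of
  its neighbours with variance `σ_u²/d_i`.  The improper prior is
  identified by a sum-to-zero constraint per connected component.  Parishes
  with no neighbours receive only the unstructured effect (logged warning).
* `v_i ~ N(0, σ_v²)` — exchangeable heterogeneity.
* `α ~ N(0, 10²)`; `σ_u, σ_v ~ HalfNormal(1)`.  Half-normal scale priors
  are used instead of the inverse-gamma precision priors of the
  WinBUGS-era literature, which are known to be fragile when the
  random-effect variance is near zero.

Reported per parish: SmRR = posterior median of `θ_i` (robust to the
right-skew of a lognormal-like posterior), equal-tailed 90% and 95%
credible intervals, and the exceedance probability
`Pr(RR > 1 | data)` = fraction of pooled post-burn-in draws above 1.
Certainty classification uses strict inequalities: elevated (red) iff
`Pr > 0.95`, lowered (green) iff `1 − Pr > 0.95`, else uncertain (yellow);
0.95 exactly is uncertain.  For equal-tailed intervals the yellow class
coincides with "the 90% credible interval covers RR = 1".

### Sampler

Adaptive Metropolis-within-Gibbs, all plain numpy:

* `u` is updated in simultaneous blocks given by a greedy proper coloring
  of the adjacency graph — within a color class no two parishes are
  adjacent, so the single-site ICAR full conditionals are independent and
  the block update is an exact kernel.  After each sweep `u` is centered
  per connected component; for a connected graph the removed mean is
  absorbed into `α`, which leaves the likelihood unchanged (exact).  For a
  disconnected graph the per-component centering is applied without
  compensation, the standard practical treatment; all graphs used here are
  connected lattices.
* `v` is updated at all sites simultaneously (conditionally independent).
* `α`, `log σ_u`, `log σ_v`: scalar random-walk Metropolis (with the log
  Jacobian for the scales).
* Joint rescaling moves `(u, σ_u) → (c·u, c·σ_u)` and
  `(v, σ_v) → (c·v, c·σ_v)` with `log c` normal: the ICAR/normal prior is
  invariant under this map (the Jacobian nets to `+log c`), so acceptance
  depends only on the likelihood and hyperprior.  These moves break the
  strong coupling between a centered random effect and its scale that
  otherwise makes `σ` mix an order of magnitude more slowly.
* Proposal scales adapt toward ~44% acceptance during burn-in only, so the
  retained chain has a fixed kernel with the correct stationary
  distribution.  Chain seeds are spawned from the config seed; identical
  data + config + seed gives bit-identical output.

Default run: 4 chains × 5,000 iterations with 2,500 burn-in and no
thinning — a 58-parish fit takes a few seconds on one core, and a full
two-year pipeline under a minute.  Convergence is monitored with a
variance-ratio Gelman–Rubin statistic, `sqrt(1 + B_n/W)` (`B_n` = variance
of chain means, `W` = mean within-chain variance): identical chains give
exactly 1, and any statistic above 1.1 sets a warning flag that propagates
to the run report rather than raising.

Hyperparameters can be pinned (`sigma_u_fixed=0` disables the spatial
effect entirely).  The test suite exploits this: with the spatial effect
off and `α`, `σ_v` fixed, the parish posteriors are independent
Poisson-lognormals, and the sampler is checked against dense-grid
quadrature to ~3 decimal places on the posterior median.  A second check
simulates data from the model family with known scales and verifies ~90%
coverage of the 90% credible intervals.

## Polarization index

`index = max(SmRR) / min(SmRR)` over parishes, reported rounded half-up to
one decimal.  It is computed on smoothed values, not raw SMRs: the raw
max/min ratio is dominated by small-population noise, while smoothing
shrinks exactly that noise.  The sensitivity analysis excludes parishes
whose SmRR lies outside the Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
(values beyond 3·IQR additionally flagged extreme) and recomputes the
index; exclusion can only narrow the range, so the sensitivity value never
exceeds the index.  Quartiles use linear interpolation by default;
`quartile_method="hinges"` switches to Tukey hinges, the dialect of SPSS
box-plots, since the two can flag different borderline parishes.

## Capitation scoring and allocation

Component scores follow fixed three-band cutoffs (configurable, or
replaceable by empirical tertiles): higher education 1 iff > 24.6%,
2 in 17.7–24.6%, 3 iff < 17.7% (more education ⇒ lower need); foreign
background 1 iff ≤ 7%, 2 in (7%, 9.5%], 3 iff > 9.5%; low purchasing power
1 iff ≤ 17.9%, 2 in (17.9%, 25%], 3 iff > 25%; caries risk (the SmRR)
1 iff ≤ 0.60, 2 in (0.60, 1.33], 3 iff > 1.33 — the nominal band gap
between 0.60 and 0.61 is closed by treating band 2 as a half-open
interval.  Boundary values always land in the band whose printed interval
notation includes them.  Whether the risk input should be the raw SMR or
the SmRR is configurable; SmRR is the default since allocation should not
reward small-parish noise.

Total score = 0.2·education + 0.2·foreign + 0.2·purchasing + 0.4·risk,
bounded in [1.0, 3.0].  Allocation is linear in score with a fixed total
budget *B*: `per_child_i = B·score_i / Σ_j score_j·n_j`, a zero-sum
re-allocation (raising one parish's score lowers every other parish's
per-child amount).  Parish budgets are rounded to the currency unit by
largest-remainder so they sum to *B* exactly; the per-child amounts are
reported unrounded so strict monotonicity in the score is preserved.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, for
a region of ~58 parishes on a trimmed rook-contiguity lattice:

* Parish child populations: lognormal around 188 children/parish (sd 0.5
  on the log scale), floor 10 — heterogeneous sizes matter because they
  drive differential shrinkage.
* SES indicators: beta-distributed proportions (education mean 0.21,
  foreign background 0.082, low purchasing power 0.215) chosen to straddle
  the scoring cutoffs; a standardized risk composite combines them.
* True log relative risk = 0.25·composite + spatial + noise, where the
  spatial term is a unit-standardized ICAR draw scaled to sd 0.40 and the
  noise is iid N(0, 0.1²), centered to mean zero.  The surface scale is
  calibrated so the fitted pipeline's smoothed polarization index lands
  near 7 under the early-year profile — the magnitude reported for the
  region this emulates — and the later-year profile attenuates the surface
  (rr_scale 0.88) so the index narrows toward ~5.5.  An `rr_range` option
  affinely pins the exact true RR span for recovery experiments, and
  `spatial_structure="independent"` provides a deliberately misspecified
  truth for robustness tests.
* Cohorts: base case probability 0.106 × parish RR (clamped to [0, 1]),
  with a mild sex effect (boy/girl rate ratio 1.15, population-mean
  preserving).  Case dmfs is zero-truncated geometric (p = 0.4) — only
  dmfs > 0 matters downstream, so the magnitude model is deliberately
  simple.  Newly arrived (foreign-born) children are added at a configured
  fraction of the cohort with a flat, much higher prevalence (3.1% at 36%
  in the early profile; 6.4% at 45% in the late profile), allocated to
  parishes proportionally to population.  The late profile also shifts the
  age mix toward 3- and 6-year-olds and scales the cohort to ~74%,
  mimicking extended recall intervals.

What the generator does *not* emulate: real geography (a lattice is not a
coastline), migration dynamics over time, within-parish socio-economic
heterogeneity, examiner variation, or any recall/visit process — the age
shift is reproduced by sampling weights, not by modelling visits.  Passing
tests therefore demonstrate statistical correctness of the pipeline under
the assumed structure, not fidelity to any particular region's data.

## Known limitations and numerical notes

* A max/min ratio of shrunken point estimates is downward biased relative
  to the true max/min — at ~20 expected cases per parish the fitted index
  averages ~80% of the truth-implied one.  This is a property of any
  correctly calibrated smoother, not a defect; comparisons between years
  fitted the same way remain meaningful.
* The certainty rule has high specificity but moderate sensitivity:
  under the null (~all RR = 1) essentially no parish is flagged, at the
  price of missing genuinely but mildly elevated parishes.
* Prevalence percentages use decimal-string half-up rounding to avoid
  binary-float artifacts at printed precision.
* Quartile dialects (interpolated vs hinges) can change which borderline
  parish is an outlier; both are exposed, linear interpolation is the
  fixed default.
* Degenerate inputs: empty cohorts raise; a sex stratum with no regional
  children raises naming the stratum; zero expected counts are rejected
  before fitting; exclusion that leaves fewer than two parishes raises.
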