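# Methods

## Model

The two doses' efficacy rates are linked by a dynamic linear model on the
probit scale: `y_j ~ Bin(n_j, p_j)`, `mu_j = probit(p_j)`, with
`mu_1 ~ N(theta, sigma1^2)`, `mu_2 | mu_1 ~ N(mu_1, sigma2^2)` and
`sigma2 ~ HC(xi, tau)` supported on `sigma2 > xi` with density
`2 / (pi tau [1 + ((s - xi)/tau)^2])`.  Defaults are `theta = probit(p0)`,
`sigma1 = 3`, `xi = 0`, `tau = 1`: a vague location prior anchored at the
historical control rate, and a heavy-tailed scale on the between-dose
increment so that the degree of borrowing is learned from the data.  The
model deliberately does not impose dose–efficacy monotonicity; with only two
doses, flexibility matters more than ordering.

Toxicity, in the co-primary extension, gets an independent DLM of identical
form anchored at the toxicity limit (`theta_tox = probit(q0)`); no
efficacy–toxicity association is modeled.  The utility `u_j = p_j - rho q_j`
converts the two rates to a single risk–benefit score; `rho` is the number
of efficacy points demanded per point of toxicity (0.67 in the reference
configuration: a 3:2 exchange).

## Posterior computation

All design decisions consume three posterior summaries: `Pr(p_j > p0 | D)`,
`PP_NI = Pr(p2 - p1 < delta1 | D)` and the posterior means.  These are
computed by a deterministic scheme built for exhaustive enumeration:

* The half-Cauchy layer is integrated exactly under
  `sigma2 = xi + tau tan(pi u / 2)`, which maps HC(xi, tau) to Uniform(0,1);
  48 Gauss–Legendre nodes in `u` cover the mixture.
* The (mu1, mu2) plane is discretized into cells of width 0.05 on
  [-8, 8], with prior and transition masses assigned per cell by exact
  normal CDF differences.  Two analytic tail cells per axis (response
  probability pinned at 0 and 1) absorb the heavy Cauchy-mixture tails, so
  no probability mass is ever truncated — this is what keeps extreme
  hyperparameters (e.g. sigma1 = tau = 50) and extreme outcomes (y = 0 or
  y = n) accurate.
* Event probabilities split the boundary cell fractionally (threshold
  position interpolated within the cell), reducing the indicator error from
  O(h) to O(h^2).  Complementary events therefore sum to 1 exactly.

Because the prior/transition kernel is independent of the data, a whole
outcome table (all `(y1, y2)` at sizes `(n1, n2)`) reduces to a handful of
small matrix products; full trial enumeration and the calibration grid
search stay in the seconds range.  `dlm_posterior` re-integrates at half the
step with doubled sigma nodes and raises `NumericalError` if any probability
moves by more than the stated tolerance (1e-3) — integration never fails
silently.  A vectorized random-walk Metropolis sampler (512 chains,
between-chain standard errors) serves as an independent cross-check; the
test battery holds the two backends to 1e-3 plus sampler noise.

A conjugate beta-binomial backend (`Beta(p0, 1 - p0)` priors, independent
doses) mirrors the same table interface for the comparator designs;
between-dose probabilities there use the quantile transform of the Beta
posterior, which is robust to shape parameters below one.

The utility-scale probability `Pr(u2 - u1 < delta1 | D)` combines the two
independent joint posteriors by binning each between-dose difference onto a
2000-cell grid and convolving the CDFs; with `rho = 0` it returns the
efficacy `PP_NI` exactly, so the extension reduces cell-for-cell to the
efficacy-only design.

### Prior effective sample size

PESS moment-matches the prior marginal of `p_j` (mean m, variance v) to a
`Beta(a, b)` and reports `a + b = m(1-m)/v - 1`, using exact formulas
(`E[Phi(mu)]` via the scaled probit identity, `E[Phi(mu)^2]` via Owen's T).
Under the default `sigma1 = 3` prior this gives 0.41 phantom patients for
dose 1 and 0.32 for dose 2 — comfortably inside the (0.01, 4) vagueness
band.  A unit prior SD would give 2.19 and 0.82 instead; the package keeps
the a+b convention (the alternative ratio convention can never fall below
one and so could not describe a sub-unit PESS at all).

## Decision rules

Boundary conventions follow the design's inequalities exactly: drop iff
`Pr(p_j > p0 | D_k) < a_k` (strict); select d2 iff `PP_NI <= c1`; select d1
iff `PP_NI > c2`.  A dose dropped at the interim is never re-admitted, but
its accumulated data stay in the joint posterior at later analyses —
borrowing is the model's point, and nothing in the design says to discard
them.  If both doses fail the interim, the trial stops at 2·m1 patients
with no selection; a lone final survivor is selected outright; `c1 = c2`
degenerates to a conventional two-outcome comparison.  The interim happens
once, after exactly m1 evaluable patients per active arm.

## Operating characteristics

For the efficacy-only design, `exact_oc` sums binomial mass over the
complete outcome tree — `(m1+1)^2` interim cells, monitored, then
conditional stage-2 tables per survival configuration — so FWER, OMP, Go%,
selection probabilities, SIR, ASS, bias and MSE carry no Monte-Carlo error.
`simulate_oc` is the replication-based twin (fixed draw order from one
seeded generator, binomial standard errors), kept for reporting and as the
backend for the joint extension, whose `(y, t)` outcome space is too large
to enumerate.  Estimates `p_hat_j` are posterior means at trial
termination, from all accumulated data including dropped arms, averaged
unconditionally over replications; bias and MSE average over the two doses.

`ASS_j = m1 + m2 Pr(dose j passes interim)` holds as an identity and is
tested as such.

## Calibration

Step 1 scans n upward; for each n, every `(m1, lambda, a2)` with
`m1 in [ceil(n/3), floor(2n/3)]`, `lambda in {0.1, ..., 1.0}`,
`a2 in {0.50, 0.51, ..., 0.99}` and `a1 = a2 (m1/n)^lambda` is evaluated by
exact enumeration.  Combinations breaching the FWER cap are discarded;
among those within one percentage point of the best OMP, the smallest
global-null ASS wins (ties: higher OMP, then smaller m1, then smaller a2 —
fully deterministic).  The first n whose winner reaches the OMP target is
returned.  Step 2 grid-searches `c1 <= c2` over {0.05, ..., 0.95},
keeps pairs with MRID <= alpha2 and SIR <= alpha3 (SIR averaged across the
two alternatives `(pA, pA + delta1)` and `(pA, pA + delta2)`), and
minimizes WL with ties broken toward the smaller inconclusive gap, then
smaller c1 — which provably collapses the gap when wl = 1.  The grids are
package defaults in BOP2 style and are fully configurable; at the reference
configuration they yield n = 28, m1 = 14, within one patient per arm of the
published reference search, whose exact grids are not public.

"Within 1% of the maximum OMP" is read as absolute percentage points.

The comparator calibrations: the beta-binomial variant runs the identical
algorithm on the conjugate backend at the same (n, m1); the DREAMM-2-style
design takes the largest interim cutoff keeping the per-dose early-stop
rate under the promising rate at or below 5%, and the smallest final cutoff
keeping FWER at or below 10% (the most powerful controlling choice;
cutoff candidates are the attainable posterior values, so both searches are
exact), with the superiority rule `Pr(p2 > p1 | D) >= 0.6` expressed as a
two-outcome rule at `c1 = c2 = 0.4`.  Simon's optimal two-stage design is
found by exhaustive exact-binomial search minimizing the expected null
sample size.

The joint extension calibrates with Monte-Carlo operating characteristics
(default 10,000 replications per grid evaluation, one shared draw set per
(n, m1) so the cutoff grid is thresholding, seed recorded).  Its step-1
optimum therefore carries simulation error of a few tenths of a percent on
OMP; configurations sitting exactly at the power target can tip to a
neighboring n between seeds.

## Synthetic data

Scenario generators draw per-arm binomial counts at stated true rates —
exactly the data-generating process the design assumes.  Built-in scenario
sets cover the nine efficacy configurations (null, flat, plateau, steep,
decreasing) and the fifteen joint toxicity–efficacy configurations used in
the reference tables.  What the generator does not emulate: staggered
accrual, evaluation lag, dropout, within-patient efficacy–toxicity
correlation, or non-binomial overdispersion.  Passing tests certify the
decision machinery and its error-rate calibration under the design's own
model, not robustness to those real-world departures.

## Problem sizes and tolerances used in the checks

The test suite and acceptance script calibrate at the reference
configuration with the exact backend (seconds), evaluate operating
characteristics by exact enumeration where possible, and use 10,000
replications for the simulation cross-checks (2,000 per scenario for the
bias sweep) — agreement bands are three binomial standard errors.  The
quadrature/MCMC battery runs 20 outcome tables at 1e-3 plus three sampler
standard errors.  Joint-design tests run at deliberately reduced sizes
(hundreds of replications, small n) to exercise the full code path quickly;
the full-scale joint calibration is a one-command run.

## Known limitations

* Two doses only; the monotone (truncated-normal) variant for three or more
  doses is out of scope.
* The probit link is fixed (no logit variant).
* Equal randomization only; no outcome-adaptive allocation, and no
  multistage (>2) monitoring.
* The utility extension treats efficacy and toxicity as independent within
  a patient, in model and in simulation.
* Calibration reproduces published sample sizes only up to grid choice:
  the search grids behind the published reference designs are not printed,
  and configurations at the feasibility boundary (the joint design's n in
  particular) are sensitive to them.
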