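# Methods

## The model

A gene is a continuous-time Markov chain over `S` promoter states per
allele (default: nearest-neighbour "ladder" transitions `i <-> i+1` with
rates `kappa_ij`), with state-dependent mRNA synthesis `beta_i` and
first-order degradation `delta`. A diploid cell carries `n_alleles = 2`
identical, independent copies. An induction stimulus at a known time
switches a subset of the kinetic parameters from their unstimulated (U) to
stimulated (S) values; which subset switches is the *induction model*,
written as a binary code over the ordered parameter list
`(kappa_01, kappa_12, kappa_21, kappa_10, beta_0, beta_1, beta_2, delta)`
for `S = 3`. The observable is the smFISH snapshot pair
`(m, TS)` per cell: the mature-mRNA count and the number of alleles in a
high-activity ("transcription-site") state. By default every state except
the basal state 0 counts as active; the active set is configurable because
the threshold between a visible transcription site and basal activity is an
imaging convention, not a model property.

## The hybrid simulator

Conditioned on a promoter path `s(t)`, and once initial transients have
decayed (`t >> 1/delta`), the mRNA count is exactly Poisson with rate
`lambda(t)` obeying `dlambda/dt = beta_{s(t)} - delta*lambda`. The joint
snapshot law is therefore a Poisson mixture over promoter paths. The
engine samples paths by kinetic Monte Carlo in the small `S`-state space,
propagates `lambda` with the exact per-interval exponential solution (no
ODE solver, hence no solver tolerance in the error budget), and convolves
the sampled `(state, lambda)` kernel with Poisson probability mass
functions. The only approximation is Monte Carlo: total-variation distance
to the truncated-master-equation reference decays as `N_s^(-1/2)` in the
number of sampled paths.

Numerical details:

- **Burn-in.** Paths start at `t = -10/delta` with `lambda = 0` and the
  promoter state drawn from the U-phase stationary law (null-space solve of
  the generator), so the genetic marginal is exactly stationary and the
  Poisson form holds at the first observation. A chain with all switching
  rates zero has no stationary law; the initial state is then uniform.
- **Randomness.** Waiting times and jump choices come from counter-based
  substreams keyed on `(seed, path, event)` (a splitmix64 finalizer). A
  fixed seed reproduces every path bit-for-bit and acts as common random
  numbers across parameter values; a fresh seed gives an independent
  kernel. Results are independent of scheduling or path order.
- **Induction boundary.** Waiting times that straddle the induction time
  are clamped there without a jump and re-drawn under the new rates, which
  is exact by memorylessness.
- **Truncation.** The mRNA support for full joint distributions is cut at
  `max(lambda) + 10*sqrt(lambda) + 10`; the discarded Poisson tail is below
  1e-10 and the truncated mass is reported. Likelihood evaluation never
  truncates: the Poisson pmf is evaluated directly at observed bins, with
  per-component support windows of 12 standard deviations (contributions
  outside are < 1e-26 per component).

## The master-equation reference

The truncated chemical master equation over `(s1, s2, m <= M)` — dimension
`S^2 (M+1)` — is the accuracy oracle. Synthesis flux out of `m = M` leaves
the system (the diagonal keeps the outflow, so column sums vanish except at
the boundary) and the lost mass is tracked; the default truncation
`M = ceil(2*mu + 10*sqrt(mu))` with `mu = n_alleles*max(beta)/delta` keeps
the loss far below 1e-6. Integration uses the stiff BDF solver at
`rtol = 1e-8, atol = 1e-12`, so the oracle error is negligible against the
Monte Carlo error it judges. Closed-form checks: a constitutive gene
relaxes to Poisson(`beta/delta`); the single-allele two-state gene relaxes
to the Peccoud–Ycart beta-Poisson law, evaluated through Kummer's
confluent hypergeometric function and cross-checked against direct
quadrature of the Beta mixture.

## Likelihood, prior, and sampling

Each observation time is an independent multinomial draw of `N_l` cells
over `(m, TS)` bins; the log-likelihood sums `h*ln P` plus the multinomial
coefficient (constant in the parameters; kept by default so evidence values
are comparable across models, cached per data set). Monte Carlo bin
probabilities can be exactly zero at an observed bin, so probabilities are
floored at 1e-12 before the log and the number of floored bins is
reported.

Priors are independent log-uniform on `[1e-2, 1e3]` in units of
`delta = 1` — wide enough to contain the benchmark values with two decades
of margin on each side. Proposals are joint Gaussian steps in
log10-parameter space. Because the multiplicative proposal is symmetric in
`log(theta)` but not in `theta`, the acceptance ratio carries the Jacobian
factor `prod theta'_i/theta_i`; with the log-uniform prior this is exactly
MH in log coordinates, and a flat-likelihood chain provably samples the
prior (a regression test asserts this with a Kolmogorov–Smirnov check).
During burn-in the proposal covariance adapts to the chain history
(adaptive Metropolis, target acceptance 0.23) and freezes afterwards.

**Handling likelihood noise.** The likelihood is itself a Monte Carlo
estimate; its noise scale grows with the data size and shrinks as
`N_s^(-1/2)`. Three kernel policies are provided:

- `fresh` (default): an independent kernel per evaluation, with the
  current state's estimate retained (pseudo-marginal style). Appropriate
  when `N_s` is large enough that the noise is ~1 nat.
- `fixed`: one common-random-number kernel for the whole chain — a
  deterministic surface, ideal for optimization, but carrying that one
  kernel's bias.
- `mcwm`: the current state is re-evaluated with a fresh kernel every step
  (Monte Carlo within Metropolis). This can neither lock onto a lucky
  estimate nor inherit a single kernel's bias; the posterior is mildly
  widened by the noise, an effect that vanishes as `N_s` grows. The
  reduced-size experiments in the tests and the acceptance script use this
  mode; at full size (`N_s = 1e5`, >= 1e6 steps) the policies coincide in
  practice.

**Initialization.** The likelihood surface over 8–12 log-decades per
coordinate is multimodal, so chains are seeded by a deterministic
method-of-moments search: state-resolved first and second moments of
`lambda` obey a closed linear ODE system of dimension `3S` per allele
(linear flow, so no closure approximation), giving the exact mean and
variance of `m` and the exact binomial TS distribution in microseconds per
parameter set. A weighted least-squares match of these summaries is
globally optimized (DIRECT rectangle division plus Sobol-seeded
Nelder-Mead restarts); because moment matching alone can be ambiguous
between switching regimes, up to three distinct moment optima are carried
forward and adjudicated under the full likelihood before a final
Nelder-Mead polish on a common-random-number surface. The moments are used
only to pick a starting point — inference is always through the full
snapshot likelihood.

## Evidence and model selection

The evidence `P(h|M)` is estimated by the importance-sampled harmonic-mean
identity `1/Z = E_post[phi/(L*pi)]` with `phi` the uniform density on the
Mahalanobis ellipsoid (in log coordinates) containing a fraction
`alpha = 0.25` of the posterior draws — small enough that `phi` stays
inside the posterior's support, which is what keeps the estimator's
variance finite. Stored draws are re-evaluated with larger, independent
kernels before the evidence is computed, so chain-time likelihood noise
does not enter `L` in the identity. The standard error comes from batch
means on the linear scale. BIC uses `n` = total cell count (cells are the
i.i.d. units of the multinomial likelihood) and `k` = free base parameters
plus one extra value per induced parameter; AIC uses the same `k`. Model
weights are softmax in log-evidence, or `exp(-Delta/2)` for the criteria.

## The synthetic benchmark

`default_benchmark` reproduces the canonical induction study: a diploid
3-state gene with rates `(0.5, 0.5, 5, 5, 20, 150, 300, 1)` in units of the
mRNA lifetime, induced at `t = 10`. Ground truth `00110000` slows both
downward rates to 0.5 (stabilizing the active states); the variant
`11000000` raises both upward rates 10-fold to 5 (a documented stand-in,
chosen to produce a comparably strong induction response). `N` cells per
time point (100 or 1000) are sampled at `Phi = {9.9, 11, 13, 16}` — one
snapshot just before induction, three spanning about six mRNA lifetimes of
the post-induction transient; the exact times are a design choice made to
capture pre-stimulus stationarity and the relaxation. Each cell is an
independent pair of allele paths simulated from burn-in, with
`m ~ Poisson(lambda_total)` — data generation therefore never depends on a
truncation. The generator emulates ideal smFISH: no probe efficiency,
segmentation error, cell-cycle or extrinsic-noise effects; passing tests
demonstrate correctness of the inference machinery under the model, not
robustness to real-data artefacts. For inference, `beta_0` and `delta` are
held fixed at known values by default (the constrained model class
`xxxx0xx0` with 64 candidates), matching the study design; the mask is
configurable.

## Problem sizes used in tests and the acceptance script

Full-size Bayesian runs (`N_s = 1e5` per likelihood call, >= 1e6 MH steps
per model, 64 models) are a workstation-scale computation. The shipped
experiments keep every algorithm identical and scale sizes down; these are
the package's standard desk-scale settings:

- Hybrid-vs-CME equivalence: `N_s = 1e5`, full truncated CME for the
  2-, 3- and 4-state classes (the 3-state class uses the canonical
  benchmark parameters; 2- and 4-state use documented analogues with the
  same slow-switching, graded-synthesis pattern).
- Parameter recovery: `N_s = 4000` (mcwm), 4500 steps (burn-in 1500) at
  `N = 1000` cells per time and 3000 steps (burn-in 1000) at `N = 100`,
  thinning 8.
- Model selection: ground truth plus five to seven competitor codes
  spanning no-induction, wrong-direction, nested-subset and over-complex
  models; `N_s = 2500` (mcwm), 800 steps per model, evidence from draws
  re-scored at `N_s = 6000`.
- Evidence calibration: 1-D conjugate normal model with 8000 posterior
  draws against the quadrature-exact marginal.
- Desk-scale priors: switching rates (`kappa_*`) use a log-uniform box
  `[1e-2, 1e2]` instead of the default `[1e-2, 1e3]` upper bound. KMC cost
  grows linearly with the switching rate, and switching faster than ~100
  events per mRNA lifetime self-averages into an effective single state
  that snapshot data cannot resolve; the benchmark rates sit at least one
  decade below the cap, as does the observed posterior mass.

## Known limitations

- The Poisson-mixture representation is exact only after the initial
  transient (`t >> 1/delta`); the burn-in enforces this regime, and
  experiments probing `t ~ 1/delta` from a non-stationary start would need
  the full CME.
- At desk-scale `N_s`, posterior intervals from `mcwm` chains are slightly
  conservative (widened by likelihood noise); evidence values carry a
  Monte Carlo error of order 1 nat, far below the tens-to-hundreds of nats
  separating competing models in the benchmark.
- The moment-based initializer assumes the observation schedule is
  informative about the induction response; a design with no pre-induction
  snapshot would weaken it (chains then fall back to prior-draw
  initialization).
- No interallele coupling, cell-cycle, partitioning or measurement-noise
  extensions; a single U-to-S parameter switch is the only time dependence.
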