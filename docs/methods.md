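# Methods

## Scope and model

`demogen-ga` infers demographic histories of one to three populations from
an allele frequency spectrum by maximizing the Poisson composite
log-likelihood over a structured model space.  A history is an ordered
sequence of time intervals and splits under a structure `(s_1, ..., s_P)`;
every interval carries per-population end sizes (relative to the ancestral
size `N_A`), one of three size-change dynamics, a duration (in `2 N_A`
generations) and a constant scaled migration matrix; every split carries
the fraction of the most recently formed population that separates.  The
first interval is special: the ancestral population is taken to sit at its
drift–mutation equilibrium with relative size 1 and sudden dynamics, so it
contributes no free parameters, and the absolute scale `theta = 4 mu L N_A`
is profiled out of the likelihood in closed form (`theta-hat =
sum S / sum M` over unmasked entries).  Within-epoch size trajectories are
`nu(t) = nu_1` (sudden), `nu_0 + (nu_1 - nu_0) t/T` (linear) and
`nu_0 (nu_1/nu_0)^{t/T}` (exponential); the named dynamics fix only the
shape, these formulas are this package's concrete choice.  Splits always
divide the last formed population, which covers all rooted topologies for
up to three ordered populations.

## The expected-spectrum engine

The built-in engine integrates the master equation of a continuous-time
Moran model.  Population `i` is represented by `K_i` gene copies; the state
of a segregating variant is its copy-number vector `(k_1, ..., k_P)` and
`phi(k)` is the expected number of variants in that state.  Transition
rates:

* drift in population `i` of relative size `nu_i`: `k -> k +/- 1` at rate
  `k (K_i - k) / (2 nu_i)` — the exact Moran rates, whose sample genealogy
  is the Kingman coalescent with pairwise rate `1 / nu_i` per `2 N_A`
  generations for any sample size `n <= K`;
* migration at scaled rate `M_ij`: each copy of `i` is replaced by a copy
  drawn from `j`, giving `k_i -> k_i + 1` at `M_ij (K_i - k_i) k_j / K_j`
  and the mirror-image loss rate;
* mutation influx into population `i` at count one at rate `theta K_i / 2`,
  the unique calibration for which the stationary sampled spectrum is
  exactly `theta nu / d`.

At a split the parent's `K` copies are partitioned hypergeometrically over
the daughters (`K_parent = K_a + K_b`), which leaves both daughter
marginals identical to the parent spectrum; at the end the population
states are down-sampled hypergeometrically to the requested `n_i`.  Because
hypergeometric subsampling commutes with the coalescent, drift, splits and
sampling are all exact for any `K_i >= n_i`; the only finite-resolution
error is an `O(M/K)` excess of between-deme coalescence through migrant
placement.  The default resolution is therefore `K_i = 2 n_i`
(`EngineConfig.bins_factor = 2`); three-population spectra with `n_i > 10`
fall back to `K_i = n_i` to keep the joint state space (at most
`21^3` states for the shipped scenarios) tractable on one core.

The linear system `phi' = Q phi + s` is advanced per epoch with the
coefficients frozen at substep midpoints (`time_step = 0.1` in `2 N_A`
units, at most `max_substeps = 50` substeps; sudden-dynamics epochs are a
single exact step).  Each substep uses the sparse exponential action
(`expm_multiply` on the source-augmented generator) while
`max |Q_ii| * h <= 50`, and otherwise Crank–Nicolson with a capped number
of implicit steps: the stiff transients of extreme parameter combinations
(tiny sizes, huge migration) decay within the first steps, so the slow
modes that shape the spectrum remain accurate while the cost stays bounded.

The Monte-Carlo oracle used in the validation suite builds the same model
in `msprime` (haploid populations of size `nu_i`, so scaled times and
migration rates carry over unchanged; linear size change is approximated
piecewise-constant in twenty substeps), averages branch-mode frequency
spectra over replicates and multiplies by `theta/2`.  It shares no code
path with the builtin engine.

## Optimization

The genetic algorithm follows the reference design: generations of ten
models split 0.2 : 0.3 : 0.3 : 0.2 into elite copies, mutated offspring,
uniform crossovers and fresh random models; rank-proportional parent
selection (average ranks for ties — plain fitness-proportionality is
ill-defined for negative log-likelihoods); mutation of
`max(1, Binomial(N, strength))` parameters chosen proportionally to
per-parameter weights that increment when a parameter's mutation improved
its model; multiplicative numeric updates `theta (1 +/- |x|)` with
`x ~ Normal(rate, rate/2)` (the variance convention is read literally);
dynamics switch to one of the other two forms with equal probability.  The
rate adapts by the one-fifth rule with constant 1.02 (multiplied on any
improving mutation, divided by the fourth root otherwise, clipped to
`[1e-3, 2]`) and the strength with constant 1.05, where success requires a
new global best (clipped to `[0.01, 1]`).  The run stops after 100 (default)
iterations without improvement of the best log-likelihood rounded to two
decimals.  Elite copies are carried unchanged, so the best-so-far fitness
is monotone.

Local search fixes the dynamics and optimizes the numeric parameters with
Powell (default; Nelder-Mead, BFGS and L-BFGS-B are available).  Sizes,
durations and split fractions are optimized in log space, migration rates
linearly with a floor at zero.  Powell and Nelder-Mead run unconstrained on
the transformed scale with clipping inside the objective: scipy's *bounded*
direction-set line search degenerates on very wide log-scale boxes (the
duration lower bound is `1e-15`) and can terminate at a point worse than
its start.  The optimizer is restarted from its own result (up to five
passes) until the gain drops below 0.01 log-units — direction-set methods
profit substantially from the reset.  A refinement never returns a model
worse than its input.

Structure growth divides one eligible interval at its median: the first
child ends at the parent's mid-trajectory sizes (arithmetic midpoint for
linear, geometric for exponential, the end size for sudden), both children
keep the dynamics and migration, so the size-through-time function and the
likelihood are preserved exactly.  Splitting the (stationary) ancestral
equilibrium interval inserts a constant-size sudden interval whose duration
is immaterial for the likelihood; it is initialized at 1.0 and left to the
next GA round.

## Model comparison and uncertainty

AIC uses the dynamics-fixed parameter count of the reported structure.  The
composite-likelihood AIC replaces `k` with the Godambe trace
`tr(J H^{-1})`: `H` is the negative central-difference Hessian of the
full-data composite log-likelihood at the optimum and `J` the covariance of
central-difference scores over block-bootstrap resamples of unlinked region
spectra.  Derivatives are taken with respect to the logs of all positive
numeric parameters *including* the fitted scale `theta-hat`, so on
independent, correctly specified data `tr(J H^{-1})` tends to the
differentiated dimension and CLAIC tends to AIC — the property the test
suite checks, together with stability of the score across
`epsilon in {1e-5, 1e-4, 1e-3}` (relative steps in log space).  Very small
steps eventually hit numerical noise, so a sweep over `epsilon` is always
recommended.  Bootstrap confidence intervals follow the reference recipe:
one local optimization per resampled spectrum launched from the reported
optimum, intervals `exp(mean(log t*) +/- sd(log t*))`; fits that fail are
dropped with a warning while they stay under 10%.  When the
best-likelihood and best-criterion models differ, the report carries an
explicit overfitting warning.

## Synthetic data and what the tests show

`demogen_ga.simulate` fixes three true histories with sudden dynamics, 20
chromosomes per population and `theta0 = 1000` (large enough that Poisson
noise does not drown the signal, small enough for desk-scale runs):

* **bottleneck_1pop** — crash to `0.1 N_A` for `tau = 0.2`, recovery to
  `N_A` for `0.1`; 4 free parameters.
* **split_mig_2pop** — split (fraction 0.5, unidentifiable under sudden
  dynamics and therefore not counted), daughter sizes 1.5 and 0.5,
  asymmetric migration 1.0 / 0.5, duration 0.5; 5 free parameters.
* **secondary_contact_3pop** — two splits, isolation intervals, then
  symmetric migration 1.0 among all pairs; sizes shared across the two
  three-population intervals; 8 free parameters.

Observed spectra are independent Poisson draws around the builtin engine's
expected spectrum, and "unlinked regions" are independent Poisson spectra
at `theta0 / n_regions` — exactly the model under which the composite
likelihood is correctly specified.  Passing tests therefore demonstrate
correctness of the machinery and identifiability under ideal, unlinked,
correctly polarized data; they do not speak to linkage, ancestral-state
misidentification, or engine mis-specification on real genomes.

Problem sizes in the shipped suite are deliberate package choices: the
two-population recovery check runs five GA runs with the stop criterion
reduced to 30 unimproved iterations; the one-population end-to-end check
(five GA runs, 20 regions, 10 bootstrap refits) asserts the truth inside a
3-standard-deviation log-space band, since a strict 1-sd coverage assertion
would fail by construction about a third of the time per parameter; the
three-population scenario is exercised through its spectrum and a
local-identifiability sensitivity check (perturbing any free parameter by
15% strictly lowers the noise-free likelihood) rather than a full
GA-plus-bootstrap campaign.  The
known AFS ambiguity between sudden and exponential bottlenecks is asserted
as a likelihood gap below one unit between the best models of the two
dynamics classes, not as identity of the selected dynamics.

## Known limitations

* At most three populations, one split topology (the last formed population
  divides), no admixture pulses or selection.
* The builtin engine's migration operator carries an `O(M/K)` bias; at the
  default resolution this is within Monte-Carlo noise of the msprime oracle
  for scaled rates up to a few, but analyses dominated by extreme migration
  deserve a finer `bins_factor` or an external engine plug-in.
* Composite-likelihood values on linked data are not true likelihoods;
  model choice there should rely on CLAIC with genuinely unlinked bootstrap
  regions.
* Observed spectra are assumed polarized (unfolded) or explicitly folded;
  no projection between sample sizes is provided.
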