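# demogen-ga

Unsupervised inference of multi-population demographic history from an
allele frequency spectrum (AFS), for population geneticists who have a
site-frequency spectrum (from whole genomes, RAD-seq or transcriptomes)
and want the demographic model *searched for*, not just tuned: a genetic
algorithm explores the space of structured demographic histories globally,
local search polishes the winner, the model's complexity can grow during
the run, and candidate models are compared with AIC or its
composite-likelihood variant.

## The model

For `P <= 3` populations the observed AFS `S[d_1, ..., d_P]` counts SNVs by
derived-allele count in each population's sample of `n_i` chromosomes.
Assuming unlinked sites, every entry is an independent Poisson variable
with mean `M[d_1, ..., d_P]`, the expected spectrum of a demographic model,
giving the (composite) log-likelihood

    log L(M | S) = sum over unmasked d of ( -M[d] + S[d] log M[d] - log S[d]! )

A demographic history is a chronological sequence of **time intervals**
(each with per-population end sizes `nu` relative to the ancestral size
`N_A`, a size-change dynamic — sudden, linear or exponential — and constant
scaled migration rates `M_ij = 2 N_A m_ij`) and **splits** (a fraction of
the most recently formed population separates).  The **structure**
`(s_1, ..., s_P)` fixes how many intervals surround each split; with the
dynamics free the model has `(P-1) + 3(s_1-1) + 7 s_2 + 13 s_3` parameters,
and with dynamics fixed (as reported after local search)
`(P-1) + 2(s_1-1) + 5 s_2 + 10 s_3`.  Time is measured in units of
`2 N_A` generations; the overall mutation scale `theta = 4 mu L N_A` is
profiled out of the likelihood analytically, so `N_A` is recovered from the
fitted scale rather than searched for.

The GA maintains a generation of candidate models (default ten, split
0.2 : 0.3 : 0.3 : 0.2 into elite, mutated, crossed and random), mutates a
binomially distributed number of parameters with adaptive one-fifth-rule
rate and strength, crosses parents uniformly, and stops when the best
log-likelihood (rounded to two decimals) has not improved for a configured
number of iterations.  The expected spectrum comes from a built-in Moran
master-equation engine (exact for drift, validated against `msprime`
coalescent simulations), or from any registered plug-in backend.

## Worked example

```python
import numpy as np
from demogen_ga import (EngineConfig, GAConfig, Dynamics, make_scenario,
                        simulate_observed_afs, model_loglikelihood,
                        run_ga, local_optimize)

scenario = make_scenario("split_mig_2pop")        # 2 pops, 5 parameters
data = simulate_observed_afs(scenario.model, scenario.engine_config(), seed=1)

config = EngineConfig(sample_sizes=(20, 20))
fitness = lambda m: model_loglikelihood(m, data, config)[0]

best, history = run_ga(
    fitness, (1, 1),
    GAConfig(stop_after_no_improvement=30, fixed_dynamics=Dynamics.SUDDEN),
    np.random.default_rng(7))
refined = local_optimize(best.model, fitness)
print(fitness(scenario.model), fitness(refined))
```

prints (seeds as above)

```
-905.0184634660752 -904.4841161075303
```

— the refined model fits the Poisson-sampled data slightly *better* than
the generating truth, as expected at finite theta; its parameters
(`nu_1 = 1.53, nu_2 = 0.51, m_12 = 1.00, m_21 = 0.49, T = 0.49`) land
within about 3% of the true `1.5, 0.5, 1.0, 0.5, 0.5`.  The scripts in `examples/` walk through simulation
and likelihoods, a full GA fit, and the pipeline report with conversion to
individuals and years.

From a shell, the same functionality is exposed as a thin CLI:

```
demogen-ga simulate --scenario bottleneck_1pop --seed 5 --out obs.fs
demogen-ga fit --data obs.fs --config run.yaml --seed 2
```

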