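# biasdyn

Stochastic models of cultural transmission under combined **success
bias** and **prestige bias**, with the analytic machinery to treat the
resulting dynamics as a Wright–Fisher process with effective parameters.

## The problem

Social learners rarely copy at random. They may prefer role-models who
*are* successful (success bias) or role-models whom many others have
already copied (prestige bias). `biasdyn` is for modellers of cultural
evolution who want to ask: when the two biases mix, which one governs
the fate of an invading cultural trait, and on what time scale?

The model is a nested pair of stochastic processes. Within a
generation, N naive copiers choose role-models one at a time; copier i
chooses role-model j with probability proportional to

```
G_ij ∝ α · β(A_j + e_i) + (1 − α) · K_{i−1,j}
```

where `β(A) = b·exp(−(A − Â)² / 2J)` is a Gaussian success-bias
function peaked at the optimal trait Â, `e_i ~ N(0, η²)` is the
copier's estimation error, `K_{i−1,j}` is role-model j's current number
of copiers (its prestige), and the success-bias weight `α ∈ [0, 1]`
mixes the two (α = 1: pure success bias, α = 0: pure prestige).
Between generations the chosen traits become the next population, and
the composition performs a random walk to fixation or loss.

The package's analytic core rests on an exact equivalence: for
homogeneous α and shared error, the sequential choice process is a
Pólya urn with initial weights `o_j = (α/(1−α))·β(A_j + e)`, so the
final copier counts are Dirichlet-multinomial. Whole generations can
then be sampled in one draw, and the dichotomous (two-phenotype) model
maps onto the classical diffusion with

```
s = 1 − β(A)/β(Â)        (effective selection coefficient)
Ne = αN + (1 − α)        (effective population size)
π(x) = (1 − e^{−2sNe·x}) / (1 − e^{−2sNe})   (fixation probability)
```

Success bias plays the role of natural selection; prestige bias plays
the role of genetic drift — and, being a rich-get-richer process, it
*accelerates* fixation when fixation happens. Modules also cover
periodically changing environments (k generations favouring the
invader, l the resident, using the cycle-averaged selection
coefficient), conditional fixation times by quadrature, an exact
absorbing-Markov-chain oracle, and copiers that adaptively tune their
own α to minimise copying error.

## Worked example

Invasion of a favoured trait (Â = 1) into a resident population
(A = 0.9, so s ≈ 0.005) of N = 1000, comparing pure success bias with
strong prestige:

```python
import numpy as np
from biasdyn import (BiasParams, relative_success, effective_params,
                     fixation_probability, conditional_fixation_time,
                     run_fixation_experiment)

params = BiasParams(b=1.0, J=1.0, a_hat=1.0)
beta, s = relative_success(0.9, params)
print(f"relative success beta = {beta:.6f}, selection coefficient s = {s:.6f}")

for alpha in (1.0, 0.01):
    ep = effective_params(alpha, beta, N=1000)
    pi = fixation_probability(x=1/1000, s=ep.s, Ne=ep.Ne)
    T = conditional_fixation_time(x=1/1000, s=ep.s, Ne=ep.Ne)
    sim = run_fixation_experiment(N=1000, alpha=alpha, A=0.9, params=params,
                                  n_replicates=10_000, rng=7)
    print(f"alpha={alpha:<5} Ne={ep.Ne:<8.2f} pi_diffusion={pi:.5f} "
          f"pi_simulated={sim.fixation_prob.point:.5f} "
          f"[{sim.fixation_prob.lower:.5f}, {sim.fixation_prob.upper:.5f}]  "
          f"T_diffusion={T:.0f}")
```

Output:

```
relative success beta = 0.995012, selection coefficient s = 0.004988
alpha=1.0   Ne=1000.00  pi_diffusion=0.00993 pi_simulated=0.00930 [0.00760, 0.01138]  T_diffusion=1107
alpha=0.01  Ne=10.99    pi_diffusion=0.00106 pi_simulated=0.00100 [0.00054, 0.00184]  T_diffusion=22
```

With pure success bias a single invader fixes with probability ≈ 2s
(the classical haploid result) after ≈ 1100 generations. Strong
prestige (α = 0.01) shrinks Ne to ≈ 11: fixation becomes about ten
times rarer, but when it happens it takes only ≈ 22 generations — the
rich-get-richer acceleration. The simulated estimates (Wilson 95%
intervals) bracket the diffusion predictions in both regimes.

A command-line interface wraps the same machinery
(`biasdyn simulate | fixation | changing-env | optimal-alpha |
validate | analytic-curves`); parameters can come from a TOML config,
every stochastic command requires `--seed`, and outputs are CSV/JSON.

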