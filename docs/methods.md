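# Methods

## Model

`biasdyn` implements oblique cultural transmission in a population of
fixed size N with non-overlapping generations. Each generation, N
copiers sequentially choose one role-model each from the previous
generation and inherit that role-model's trait value. Copier i's
choice probabilities (its view of each role-model's *influence*) mix
two terms:

* a **success** term `β(A_j + e_i)`, the Gaussian bias function
  `β(A) = b·exp(−(A − Â)²/(2J))` evaluated at the copier's noisy
  estimate of role-model j's trait (`e_i ~ N(0, η²)`, one draw per
  copier, shared across the role-models that copier evaluates);
* a **prestige** term `K_{i−1,j}`, the number of earlier copiers in
  the same generation that already chose role-model j.

The success-bias weight `α_{i,j} ∈ [0, 1]` sets the mixture; the
numerators are normalised over role-models. Copiers always inherit the
*true* trait of their chosen role-model — estimation error distorts
choice, never transmission. A dichotomous variant tracks only the
count X of individuals carrying the optimal phenotype Â against a
resident phenotype A with relative success `β = β(A)/β(Â)`
(normalising by `β(Â)` makes the amplitude b irrelevant). A
deterministic blended variant (`blended_transmission`), in which each
copier adopts the success-weighted average of its estimates, is
provided for completeness; it is an averaging contraction and plays no
role in the fixation analyses.

Two degenerate regimes are defined by continuity: a copier whose
influence numerators are all zero (pure prestige before anyone has
chosen) picks uniformly at random, which makes α = 0 the
"first copier uniform, everyone else follows the crowd" process.

## Exact within-generation distribution

For homogeneous α and a shared error draw, the sequential process is
*exactly* a Pólya urn whose colours are role-models and whose initial
(real-valued) ball counts are `o_j = α′·β(A_j + e)` with
`α′ = α/(1 − α)`: each choice returns one extra ball of the chosen
colour. Consequently the final copier-count vector is
Dirichlet-multinomial (DMD) with the *unnormalised* weights as
concentrations. The unnormalised scale matters: the total
concentration `Σ o_j` controls the overdispersion relative to a
multinomial, which is precisely where the prestige strength enters; a
normalised parameterisation would lose `Ne = αN + (1 − α)`.

Three independent routes to the same distribution are kept and tested
against each other:

1. the sequential simulation itself (`run_choice_process`);
2. an exact dynamic-programming recurrence for one role-model's
   marginal count (`gbd_marginal_pmf`), the generalized-binomial view
   of the process — implemented as the DP rather than any
   θ-parameterised closed form, since the trial-correlation parameter
   never enters the quantities of interest;
3. direct DMD sampling (`sample_dmd`), gamma-normalised so it remains
   usable at the very small concentrations (≪ 1 per colour) produced
   by strong prestige, where off-the-shelf Dirichlet samplers
   underflow.

`α = 1` is everywhere a multinomial special case (no finite urn
weights). The marginal DP is checked exactly against the
beta-binomial; the joint distribution is checked by chi-square against
simulated count vectors; expected counts follow `E[K_N,j] = N·G_{1,j}`
(for α → 0 this is 1 for every role-model: prestige is frequency
independent). A likelihood shuffle test (`shuffle_test`) scores the
observed counts under the true concentration ordering against random
permutations; the test is defined so that data generated by the model
rank near the top (highest likelihood) — i.e. the true parameters fit
best — which is the direction that supports the approximation.

## Between-generation dynamics and diffusion limits

The dichotomous model's generation step aggregates the DMD over the
two phenotype classes into a beta-binomial transition
`X′ ~ BetaBin(N, α′X, α′(N−X)β)` with absorbing boundaries; the `dmd`
engine samples it in O(1) per generation, while the `full` engine runs
the N sequential choices (the two are distributionally identical under
homogeneity, which the tests verify by chi-square and by overlapping
fixation-probability CIs). The transition law has mean increment
`s·x(1−x) + O(s²)` with `s = 1 − β` and — exactly, at β = 1 —
variance `x(1−x)/Ne` with `Ne = αN + (1 − α)`. These are the drift and
diffusion terms of a Wright–Fisher diffusion, so the classical results
apply with (s, Ne):

* fixation probability `π(x) = (1 − e^{−2sNe·x})/(1 − e^{−2sNe})`,
  evaluated with `expm1` and exponent clipping at ±700 so it is stable
  for |Ne·s| up to ~10³; s = 0 returns x (removable singularity);
* conditional (on fixation) mean absorption time via the sojourn-time
  Green's function of the diffusion, h-transformed by π. With
  `a = 2·Ne·s` the two integrals are arranged so every exponential is
  bounded on the integration interval:

  `T(x) = C·[ ∫_x^1 (1−e^{−aξ})(1−e^{−a(1−ξ)})/(ξ(1−ξ)) dξ
            + r(x)·∫_0^x (e^{−aξ}−1)² e^{a(ξ−x)}/(ξ(1−ξ)) dξ ]`

  with `C = 2Ne/(a(1−e^{−a}))` and
  `r(x) = (1−e^{−a(1−x)})/(1−e^{−ax})`; adaptive quadrature
  (absolute tolerance 1e-8), closed form in the neutral case
  (`T(x) = 2Ne(1−x) − 2Ne((1−x)/x)(x + ln(1−x))`). The published
  integral expressions for this quantity are typeset ambiguously in
  the source material, so the correctness gate is agreement with the
  exact chain (below), not a transcription.

An **exact oracle** (`markov_oracle`) builds the full (N+1)-state
beta-binomial chain, solves the absorption system for fixation
probabilities and the conditioned (h-transformed) system for mean
fixation times. It is dense linear algebra, practical to N ≈ 300, and
anchors the diffusion formulas: at N = 50–100 and weak selection the
fixation probability agrees within 5% and the conditional time within
10%.

**Changing environments.** A periodic schedule favours the invader for
k generations and the resident for l. Flipping the environment moves
the bias optimum onto the resident trait; by the symmetry of the
Gaussian bias this makes the disfavoured phenotype's relative success
the reciprocal, `β_t ∈ {β, 1/β}`. The cycle-average selection
coefficient `s̄ = (1/n)Σ(1−β_t)` plugged into the constant-environment
formula gives the changing-environment fixation probability; it
reduces *exactly* to the constant case at l = 0 (this forced the
interpretation of the cycle sum as `Σ Ne(1−β_t)` rather than
`Σ N(1−β_t)`, which would not reduce). With the reciprocal swap a
k = l cycle cancels only to first order (`s̄ = −(1−β)²/(2β)`), which
is the intended weak-selection regime. Every replicate starts at cycle
position 1, invader favoured first. The approximation degrades when
fixation times are shorter than the cycle, i.e. for large s.

**Wright–Fisher reference.** The external check simulates a haploid
Wright–Fisher population of size round(Ne) with selection s. The
state is a real-valued frequency updated by
`Binomial(round(Ne), x/(x + (1−x)(1−s)))/round(Ne)`: after one step
the state is on the Ne-lattice, but the initial frequency may lie off
it. This is deliberate — comparisons start invasions at x₀ = 1/N with
N ≫ Ne (e.g. Ne ≈ 11 at α = 0.01, N = 1000), which an integer-count
chain of size 11 cannot represent.

## Adaptive success-bias weight

In the adaptive experiment each copier, before choosing, evaluates on
a 101-point grid the expected squared distance between the trait it
would copy and the optimum, using its own noisy estimates and the
current prestige counts, and adopts the minimising α (ties break to
the largest α, so an uninformative crowd leaves the copier on success
bias; the first copier's objective is provably α-independent). The
objective's candidate weights use the bias values β(estimate),
consistent with the influence that drives the actual choice; the
literal raw-trait weighting is available behind
`weight_form="literal"` but can produce negative "weights" for
standard-normal traits and is not the default. Realised error is
scored against the true chosen trait, `|A_chosen − Â|`, while the
optimisation sees only estimates.

Because the objective is a ratio of two functions affine in α, its
argmin always sits at an endpoint: each copier effectively asks
whether the crowd's current mean squared error beats a fresh
success-biased draw. Averaged over replicates this yields the
qualitative behaviour of interest — mean α* declines with copier
index, within-generation error declines, and the adaptive rule beats
every constant weight — all of which are tested. Quantitatively, at
the default study conditions (N = 200, standard-normal traits,
η ∈ {1e-4, 1e-3, 1e-2}, 300 replicates) the late-copier mean error
equilibrates at ≈ 0.48 (η-independent) against ≈ 0.70 for the best
constant weight, a ratio of ≈ 1.4. A much larger published gap
(≈ 0.046 vs > 0.74, a tenfold ratio) is *not* reproduced by this
choice rule, and we believe cannot be: an error of 0.046 at N = 200
corresponds to copying one of the few best role-models in the sample,
but the prestige term reinforces crowd members in proportion to their
popularity, not their quality, so no additive success/prestige mixture
concentrates choices on the crowd's best member. The corresponding
acceptance-level test encodes the published margins and is expected to
fail; it is retained unweakened as a record of the discrepancy.

## Study conditions and what the tests show

Synthetic inputs follow the study conditions throughout: initial
continuous populations are standard normal; the default bias function
has b = J = 1 with optimum Â = 1; fixation experiments use N = 1000,
a single invader (x₀ = 1/N), A = 0.9 or 0.8 (s ≈ 0.005 / 0.0198), 10⁴
replicates (2×10⁴ in the changing-environment runs, where success is
rare); the DMD validation uses N = 100 with 1000 replicates of the
full sequential process, homogeneous α = 0.5 and a shared estimation
error (η = 0.1) redrawn per replicate and paired with its own DMD
expectation; the adaptive-α experiment uses N = 200 and 300
replicates. The changing-environment check compares α ∈ {0.01, 1} at
k = 20, l = 80, where the analytic decrease with α spans two orders of
magnitude and the simulated estimates bracket both predictions.

Monte Carlo assertions use Wilson 95% intervals for probabilities,
normal intervals for conditional times, chi-square goodness of fit at
p > 0.001 with small expected bins pooled, and 3–3.5 standard-error
bands for means; stochastic tests are seeded and deterministic.
Replicate streams are spawned from a single root seed per experiment
(replicate i's stream does not depend on the total replicate count).
Runs that hit the generation cap (default 100·N) without absorbing are
counted as losses and reported in a censoring counter; absorption is
almost sure, so the cap only bounds runtime.

What passing tests do *not* show: the generator emulates the model's
own assumptions (normal traits, Gaussian bias, homogeneous α where the
approximations require it), so agreement between simulation and theory
validates the mathematics, not the model's fidelity to any empirical
cultural data. Heterogeneous α across copiers, non-Gaussian bias
functions, overlapping generations (Moran dynamics), mutation and
learning costs are out of scope.

## Known limitations

* The conditional-time quadrature targets weak selection
  (|Ne·s| ≲ 10³) and moderate x; accuracy is gated at 10% against the
  exact chain for N ≤ 100.
* The changing-environment formula inherits the weak-selection,
  long-fixation-time regime; for 1 − β ≳ 0.1 it underestimates
  simulated fixation probabilities.
* `markov_oracle` is dense O(N³); use the diffusion formulas beyond
  N ≈ 300.
* The full continuous-trait engine is O(N²) per generation; the DMD
  engine should be preferred whenever its homogeneity conditions hold.
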