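# Methods

## Model and assumptions

Patients arrive one at a time. Patient `n` presents a covariate
`Z_n ∈ {0, …, S−1}` drawn i.i.d. from a *known* law `q` (binary in the
standard setting; several or polychotomous covariates are folded into a
single stratum label by mixed-radix encoding, `S = M₁ × … × M_C`). Given
treatment `t ∈ {0, …, T}` (0 = control), the binary response is
`Y ~ Bernoulli(p_t(z))` with `logit p_t(z) = α_t + β_t z` — each arm has its
own intercept and covariate effect, so qualitative treatment–covariate
interactions are allowed. Outcomes are assumed observable before the next
allocation decision (for the sequential rule) or by the end of the current
block (for block rules). The covariate law is treated as a design constant
and never estimated.

Every (covariate level, treatment) pair is one **combination arm** with an
independent success rate `p_zt` carrying a conjugate Beta prior (Beta(1,1)
by default). This makes the covariate problem a classic `S(T+1)`-armed
bandit in which only the `T+1` arms matching the incoming patient's
covariate are playable. The optimal discounted-bandit solution would be
restless once covariates enter the state, so the package uses the Gittins
index of each combination arm as a (near-optimal) heuristic priority.

## Gittins index computation

The index of a Beta(s, f) arm at discount `d` is computed through the
calibration problem: play the arm against retiring on a constant reward
`λ` per period (worth `λ/(1−d)`); the index is the `λ` at which the two are
equally attractive. Numerics:

* **Backward induction** over the triangular lattice of posterior counts,
  truncated after `H` plays with boundary states priced at
  `max(λ, posterior mean)/(1−d)`. `H` is chosen so `d^H` is below the
  requested tolerance (917 plays at `d = 0.99`, tolerance `1e-4`); because
  the boundary price is itself within the (by then tiny) exploration bonus
  of the true value, the realized truncation error is orders of magnitude
  below `d^H/(1−d)`. Halving/doubling `H` moves the reference state
  `G(1,1) = 0.86986` by less than `1e-6`.
* **Single states** (`compute_gittins_index`) locate `λ` by bisection to a
  default tolerance of `1e-6`; non-integer counts are supported.
* **Whole tables** (`build_gittins_table`) are priced by a shared-`λ` grid
  sweep: one backward induction at a fixed `λ` decides *play vs retire*
  for every state simultaneously, i.e. whether each state's index exceeds
  `λ`. Sweeping a uniform grid with step equal to the construction
  tolerance (default `1e-4`) brackets every index to half a step; estimates
  are clamped from below at the posterior mean, which the index provably
  dominates. The depth-452 table needed for 450-patient trials builds in
  about a minute on one CPU and serializes to plain CSV bit-identically.
* **Monotonicity and ties.** The index is strictly increasing in `s` and
  strictly decreasing in `f`, but adjacent deep states may differ by less
  than the grid step (e.g. `(450,1)` vs `(451,1)` differ by ~5e-6), so a
  table at finite tolerance can tie them. Tables therefore guarantee
  monotonicity only up to the construction tolerance; selection ties break
  deterministically toward the lowest treatment index (control), with an
  optional seeded-uniform mode. At `d = 0` the index equals the posterior
  mean and is returned exactly.

## FLGI block probabilities

For block `j` the data are frozen at the posterior state reached after
block `j−1`. The block of `b` future patients is then rolled forward under
the deterministic Gittins rule: covariates drawn from `q`, the selected
arm's outcome drawn from its *current posterior mean* (posterior-predictive
lookahead), posteriors updated inside the rollout only. The probability
that arm `zt` is selected somewhere in the block, normalized by the
expected covariate-group size `b·q_z` and averaged over the first patient's
covariate, gives the block allocation probability.

Probabilities are stored **per covariate group**: `pi[z, t]` is the chance
that a patient with covariate `z` in this block receives treatment `t`, and
each row sums to 1 (the group-size-normalized block averages have exactly
this property after the first-covariate averaging; the raw conditionals,
which may individually exceed 1, are exposed separately by the exact
route). Patients in the block are then independent draws from their group's
row, so the realized within-block allocation is multinomial.

Two evaluation routes:

* **Exact enumeration** branches over every covariate draw and outcome —
  `(2S)^b` paths — and is used as the test oracle for small blocks; a
  configurable cap raises beyond roughly `b = 8`.
* **Monte-Carlo** simulates the block forward (default 100 replications,
  vectorized across replications with dense integer-indexed table lookups)
  and estimates each group's probabilities as pooled within-group
  allocation frequencies. This ratio estimator is consistent, normalizes
  exactly, and coincides with the expected-group-size normalization after
  the within-group renormalization that assignment applies anyway.

**CFLGI** pins the control probability at `1/(K+1)` in every covariate
group and renormalizes the experimental arms onto the remaining mass; if a
group's experimental mass is zero (possible with a one-patient lookahead),
the mass is spread uniformly over the experimental arms and logged.

## Comparator rules

* **ER**: probability `1/(T+1)` everywhere.
* **SPBD**: within each covariate stratum, permuted blocks of length `m`
  (drawing proportional to remaining slots, which is equivalent to a
  uniformly random block permutation). Exact balance at every block
  boundary per stratum.
* **CARA targets 1–4** use success-rate estimates per cell from the
  saturated per-arm logistic MLE (cell proportions), refreshed at each
  block boundary after a 50-patient equal-randomization burn-in. Writing
  `q_t = 1 − p_t`: target 1 is odds-proportional (`ρ_t ∝ p_t/q_t`), target
  2 success-proportional (`ρ_t ∝ p_t`); both extend to any number of arms.
  Targets 3 and 4 are two-arm only and use dispersion weights in the
  *crossed* orientation — `ρ₀ = √(p₁q₁)/(√(p₀q₀)+√(p₁q₁))` and
  `ρ₀ = √p₁·q₁/(√p₀·q₀+√p₁·q₁)` — so that a clearly superior experimental
  arm (response rate away from 1/2) receives the larger share. The
  uncrossed orientation would shift patients toward control in exactly
  those scenarios, against the ethical intent of the target family; both
  orientations exist in the literature and the crossed one is adopted here.
* **MLE degeneracy**: empty cells fall back to 0.5 and are flagged;
  separated cells (all successes/failures) get a +1/2 continuity
  correction. Estimates are clipped to `(1e-6, 1−1e-6)` before entering a
  target formula.
* **Thompson sampling** allocates within covariate group proportionally to
  `Pr(arm is best | data)^c`, the probability estimated from 10⁴ posterior
  draws (standard error ≈ 0.005, negligible against trial noise). The
  exponent defaults to `c = J/(2T)`, constant over the trial; it is a
  config field because the stage-increasing reading `c = j/(2T)` also
  appears in practice.
* Burn-in applies to the estimate-driven targets only; Thompson and the
  Gittins rules act on their priors from patient 1.

## Hypothesis testing

The parameter of interest is the covariate-adjusted treatment difference
`α_t − α_0`. Under the saturated per-arm model this contrast is identified
by the covariate-level-0 cells alone, so the **normal-cutoff test** is the
score-type two-proportion z-test (pooled variance under the null) between
arm and control within that stratum. For the bandit rules, whose allocation
is heavily imbalanced and adaptive, the package instead uses **Fisher's
exact test** on the pooled success/failure margins with a
simulation-calibrated cutoff: the largest threshold whose empirical
rejection rate under the design's null does not exceed the nominal level.
Multi-arm trials Bonferroni-correct `K = T` comparisons (`reject iff
p < α/K`); the per-covariate-group "marginal" powers test the group's best
arm against control within that subgroup. The combined measure (CM) counts
replications that both allocate at least a threshold share (0.85 two-arm,
0.75 three-arm) of covariate-0 patients to their best arm and reject at the
trial level.

## Randomness and reproducibility

One master generator spawns an independent substream per trial replication;
all Monte-Carlo lookaheads and posterior draws inside a replication use
that replication's stream. Identical seeds give bit-identical operating
characteristics; run manifests record the config, seed and the content
hash of the Gittins table used.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses 1000 replications for the equal-randomization
benchmark, 500 for the deterministic Gittins rule and 300 for FLGI with
block size 50 (Monte-Carlo lookahead of 100 per block). At these sizes the
Monte-Carlo standard error of each reported mean is well inside the
tolerance of the corresponding check (≈0.3 failures for ER, ≈0.6 for the
bandit rules, ≈0.01 for power), and the whole script runs in a few minutes
on one CPU.

## What the simulator does and does not emulate

The generator reproduces the idealized study conditions: i.i.d. covariates
from a known law, immediate binary outcomes, response rates constant over
time, and exchangeable patients within cells. It does not emulate delayed
or missing responses, accrual drift or time trends (which can inflate the
type-I error of any response-adaptive design), continuous covariates, or
estimation of the covariate distribution. Passing tests therefore certify
the allocation machinery and its operating characteristics under the
stated model, not robustness to those departures.

## Known limitations

* Exact FLGI enumeration is exponential in block size; beyond small blocks
  only the Monte-Carlo route is practical, adding (quantified, small)
  estimation noise to the allocation probabilities.
* Deterministic CARA GI is not randomized; it is included as the reference
  policy the randomized rules approximate, not as a recommendable design.
* The two-arm dispersion-weighted targets (3–4) have no principled
  multi-arm extension and raise for `T > 1`.
* Gittins tables assume integer-count states (integer priors); non-integer
  priors fall back to per-state computation, which is exact but slow inside
  the vectorized simulators.
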