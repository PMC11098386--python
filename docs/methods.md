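# Methods

## Model

The simulator couples a textbook statistical kernel to an evolutionary
population process.

**Statistical kernel.** Every experiment is an independent two-sample
*t*-test with per-group sample size equal to the researcher's effort
*E*, so under a true standardised effect *d* the statistic is
noncentral-*t* with df = 2*E* − 2 and noncentrality λ = *d*·√(*E*/2).
Draws use the defining construction *T* = (*Z* + λ)/√(*V*/df) with
*Z* ~ N(0,1) and *V* ~ χ²(df), which is exact for real-valued df and
reduces to the central *t* at λ = 0. Truth is modelled through a
minimally relevant effect size *d*<sub>min</sub> rather than a point
null: effects at or below *d*<sub>min</sub> count as true nulls. True
effects are exponential, so the null prior is
P[H₀] = 1 − exp(−*d*<sub>min</sub>/*d*₀), equivalently
*d*₀ = −*d*<sub>min</sub>/ln(1 − P[H₀]) (0.1243 for
*d*<sub>min</sub> = 0.2, P[H₀] = 0.8).

**Publication and truth rules.** An experiment with *k* tests is
published if any statistic clears the *uncorrected* two-sided critical
value at the scenario's α — the agents apply no multiplicity
correction, which is exactly the behavior under study. The simulator's
private truth bookkeeping is stricter: a publication is a true positive
only if some test has both a true effect ≥ *d*<sub>min</sub> and a
statistic clearing the Šidák-corrected critical value at
α<sub>S</sub> = 1 − (1 − α)^(1/k). Because α<sub>S</sub> ≤ α, a true
positive is always published. Ties at a critical value reject on strict
inequality (a zero-probability event for a continuous statistic).

**Population process.** Retirement is an independent Bernoulli(*p*<sub>retire</sub>)
event per researcher per step; replacements copy (effort, hypothesis
count) from a parent drawn uniformly from the top ⌈LM·N⌉ survivors by
publication count (ties broken by uniform random ordering) and mutate:
effort plus N(0, σ<sub>E</sub>) clipped to [E<sub>min</sub>, E<sub>max</sub>];
hypothesis count plus round(N(0, σ<sub>k</sub>)) clipped to
[k<sub>min</sub>, k<sub>max</sub>]. Evolution therefore acts purely
through selective replacement; no within-lifetime imitation is
modelled. Two observations support this reading: selection on a
noisy cumulative count needs long careers to be meaningful, and the
study design's 50000-step horizon only makes sense if adaptation is
turnover-limited — per-step imitation by every agent would equilibrate
the population within tens of steps.

A time step is synchronous: all experiments resolve against
beginning-of-step state, publications are credited, then retirement and
replacement restore the population to N, then survivors (not newborns)
age by one. Agents who skip their experiment still age and may retire.

## Parameters

| name | meaning | default |
|------|---------|--------:|
| `n_researchers` | population size N | 2000 |
| `effort_init` / `k_init` | initial effort / hypotheses per experiment | 20 / 1 |
| `effort_min`, `effort_max` | effort bounds (per-group sample size units) | 5, 500 |
| `k_min`, `k_max` | hypothesis-count bounds | 1, 50 |
| `sigma_effort`, `sigma_k` | mutation SDs of the two traits | 10, 2 |
| `prior_null` | P[H₀], prior probability of a true null | 0.8 |
| `d_min` | minimally relevant effect size (Cohen's d) | 0.2 |
| `eta` | effort cost rate in exp(−η[E − E<sub>min</sub>]) | 0.01 |
| `p_retire` | per-step retirement probability | 0.002 |
| `top_fraction` | fraction of the population forming the parent pool | 0.1 |
| `n_steps` / `n_replicates` | study horizon / replicates per cell | 50000 / 100 |

Effort is real-valued throughout (mutation is continuous), and df
= 2E − 2 is used unrounded; the kernel validates df > 0, although with
`effort_min` = 5 the bound cannot bind.

Two switches beyond the table:

* `two_sided` (default true) — the test is a two-sided point-null
  *t*-test; a one-sided reading ("T greater than the critical value")
  is runnable for comparison.
* `hierarchical_effects` (default true) — each researcher's personal
  scale *d<sub>i</sub>* is itself drawn from Exponential(*d*₀) and
  per-experiment effects from Exponential(*d<sub>i</sub>*). The flat
  alternative (*d<sub>i</sub>* ≡ *d*₀ for everyone) is the mode in
  which P[H₀] = 1 − exp(−*d*<sub>min</sub>/*d*₀) is exact; in the
  hierarchical default the marginal null prior is slightly higher
  (≈ 0.82 instead of 0.80 at the defaults) because small scales are
  oversampled. Offspring draw a fresh *d<sub>i</sub>*; effect-size luck
  is not heritable.

## Randomness and determinism

Each replicate owns a `numpy.random.SeedSequence`; an initialization
stream and a dynamics stream are spawned from it, and agent-level draws
consume the dynamics stream in fixed agent order, making every
replicate bit-reproducible from its seed. Grid cells seed from
(base_seed, prior index, scenario index, replicate index) so any cell
re-runs in isolation; the `match_scenario_seeds` option drops the
scenario index so replicate *r* is paired across scenarios — used for
cross-scenario contrasts (false-discovery counts, effort, productivity)
where pairing removes between-replicate noise without changing any
marginal distribution.

## Reported statistics

Two false-positive summaries are computed, and they are deliberately
distinct:

* **pooled rate** — Σ FP / (Σ TP + Σ FP) over the researchers alive at
  a step. One value per replicate at the final step is the histogrammed
  headline statistic. Undefined (NaN) until the first publication;
  replicates with no publications are excluded from histograms and
  counted.
* **per-agent median** — the median across living agents of each
  agent's career FP/(TP+FP), agents with zero publications excluded.
  This is the trajectory-panel version: "what does the typical
  researcher's record look like", robust to a few prolific outliers.

Trajectories are medians across living researchers within a replicate,
then arithmetic means across replicates (NaN-aware). Final
distributions: the FP-rate histogram uses bin width 0.025 on [0, 1]
(fine enough to resolve a cluster between 0.875 and 0.9); hypothesis
counts use unit-width integer bins; effort uses width-10 bins over the
observed range.

## Problem sizes and convergence

The full study design (N = 2000, 50000 steps, 100 replicates per cell,
three scenarios, three priors) is hours of compute on one core. The
package therefore ships a `reduced` preset — N = 200, 5000 steps,
20 replicates — used by the test suite and the acceptance script. The
reduced preset reproduces every qualitative contrast (ordering of the
three scenarios' false-positive rates, the effort/productivity cost of
hacking a 0.005 threshold, the persistence of multiple testing), but
evolution here is turnover-limited (expected career 1/*p*<sub>retire</sub>
= 500 steps, so a 5000-step run spans only ~10 generations) and the
evolved quantities are still drifting at the final step: diagnostic
runs at N = 200 show the multi-hypothesis α = 0.05 pooled FP rate
rising 0.75 → 0.81 between steps 5000 and 20000 (hypothesis counts
still climbing), and the α = 0.005 rate 0.43 → 0.49, both moving toward
the full-scale long-run values. Reduced-preset point estimates of
evolved quantities therefore sit systematically below their full-scale
counterparts, and passing tests at this scale demonstrate the
qualitative regime and the direction and rough size of the threshold
intervention's effects, not full-scale point values.

## Degenerate inputs and edge cases

* α is accepted on (0, 1]; α = 1 is the degenerate always-publish
  threshold (two-sided critical value 0), useful for sanity tests.
* `eta = 0` removes the effort cost (everyone experiments every step);
  very large `eta` freezes all experimentation.
* σ = 0 disables mutation of a trait; `p_retire` ∈ {0, 1} are valid.
* A retirement wave that empties the survivor pool raises
  `SimulationError` (possible only when `p_retire` = 1).
* `n_steps = 0` returns the initial state with empty trajectories.

## What the simulation does not model

Real P-hacking also includes flexible analysis choices on one dataset
(the "garden of forking paths"), selective exclusion of data,
peer-review error, replication attempts, and funding dynamics — none of
which are represented. The model isolates one mechanism: repeated
independent testing with selective publication under career selection
pressure. Conclusions about the 0.005 threshold transfer to real
literatures only to the extent that this mechanism dominates.
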