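"""Discrete-time simulation loop: scenarios, replicates, and run records.

Each time step is synchronous: every researcher independently decides
(with the effort-dependent probability) whether an experiment completes
this step; completed experiments draw true effect sizes, simulate the
noncentral-*t* statistics, and are classified against the scenario's
significance threshold; any significant statistic yields a publication.
Retirement and replacement then restore the population to size N, and
survivors age by one step.

Randomness discipline: each replicate owns a :class:`numpy.random.SeedSequence`
from which an initialization stream and a dynamics stream are spawned;
agent-level draws consume the dynamics stream in fixed agent order, so a
replicate is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from . import stats_kernel as sk
from .exceptions import ParameterError
from .population import Parameters, Population, init_population, retire, spawn_replacements

__all__ = [
    "Scenario",
    "SCENARIOS",
    "StepSummary",
    "RunRecord",
    "step",
    "run_replicate",
    "run_experiment_grid",
    "summarize_population",
]

_CANONICAL_ALPHA = {"single": 0.05, "multi_05": 0.05, "multi_005": 0.005}
_CANONICAL_MULTI = {"single": False, "multi_05": True, "multi_005": True}


@dataclass(frozen=True)
class Scenario:
    """Which testing regime is simulated.

    ``single`` pins every agent at one hypothesis per experiment
    (alpha 0.05); ``multi_05`` and ``multi_005`` allow the hypothesis
    count to evolve, at thresholds 0.05 and 0.005 respectively.  Custom
    names may carry any threshold in (0, 1].
    """

    name: str
    alpha: float
    multi_allowed: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.name in _CANONICAL_ALPHA:
            if self.alpha != _CANONICAL_ALPHA[self.name] or self.multi_allowed != _CANONICAL_MULTI[self.name]:
                raise ParameterError(
                    f"scenario {self.name!r} requires alpha={_CANONICAL_ALPHA[self.name]}, "
                    f"multi_allowed={_CANONICAL_MULTI[self.name]}"
                )


SCENARIOS: Mapping[str, Scenario] = {
    "single": Scenario("single", 0.05, False),
    "multi_05": Scenario("multi_05", 0.05, True),
    "multi_005": Scenario("multi_005", 0.005, True),
}


@dataclass(frozen=True)
class StepSummary:
    """Medians across living researchers at the end of one step."""

    effort_median: float
    k_median: float
    value_median: float
    # median across agents (with >= 1 publication) of career FP/(TP+FP)
    fp_agent_median: float
    # pooled running ratio sum(FP)/sum(TP+FP) over living researchers
    fp_pooled: float
    n_experiments: int
    n_publications: int


def summarize_population(pop: Population, n_experiments: int = 0, n_publications: int = 0) -> StepSummary:
    """Symmetric (agent-order-invariant) summary of the current population."""
    pubs = pop.n_true_pos + pop.n_false_pos
    has_pubs = pubs > 0
    if np.any(has_pubs):
        fp_agent = float(np.median(pop.n_false_pos[has_pubs] / pubs[has_pubs]))
        fp_pooled = float(pop.n_false_pos.sum() / pubs.sum())
    else:
        fp_agent = float("nan")
        fp_pooled = float("nan")
    return StepSummary(
        effort_median=float(np.median(pop.effort)),
        k_median=float(np.median(pop.n_hypotheses)),
        value_median=float(np.median(pop.value)),
        fp_agent_median=fp_agent,
        fp_pooled=fp_pooled,
        n_experiments=int(n_experiments),
        n_publications=int(n_publications),
    )


def _conduct_experiments(
    pop: Population, scenario: Scenario, params: Parameters, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve this step's experiments for all agents at once.

    Returns boolean arrays (experimented, published, true_positive) over
    the whole population.  All k tests of one agent share that agent's
    df and critical values, so those are computed per agent and repeated
    per test; per-test arrays are laid out as concatenated segments in
    agent order and reduced segment-wise.
    """
    n = pop.size
    experimented = rng.random(n) < sk.experiment_probability(pop.effort, params.effort_min, params.eta)
    published = np.zeros(n, dtype=bool)
    true_pos = np.zeros(n, dtype=bool)
    idx = np.nonzero(experimented)[0]
    if idx.size == 0:
        return experimented, published, true_pos

    k = pop.n_hypotheses[idx]
    df = 2.0 * pop.effort[idx] - 2.0
    t_crit = np.asarray(sk.critical_t(scenario.alpha, df, params.two_sided))
    t_crit_corr = np.asarray(sk.critical_t(sk.sidak_alpha(scenario.alpha, k), df, params.two_sided))

    # per-test flat arrays, segmented by agent
    owner = np.repeat(np.arange(idx.size), k)
    d = rng.exponential(pop.d_scale[idx][owner])
    effort_t = pop.effort[idx][owner]
    df_t = 2.0 * effort_t - 2.0
    lam = d * np.sqrt(effort_t / 2.0)
    t = (rng.standard_normal(d.size) + lam) / np.sqrt(rng.chisquare(df_t) / df_t)
    evidence = np.abs(t) if params.two_sided else t

    starts = np.zeros(idx.size, dtype=np.intp)
    np.cumsum(k[:-1], out=starts[1:])
    pub_seg = np.add.reduceat(evidence > t_crit[owner], starts) > 0
    tp_seg = np.add.reduceat((evidence > t_crit_corr[owner]) & (d >= params.d_min), starts) > 0

    published[idx] = pub_seg
    true_pos[idx] = tp_seg
    return experimented, published, true_pos


def step(
    pop: Population, scenario: Scenario, params: Parameters, rng: np.random.Generator
) -> StepSummary:
    """Advance the population by one time step, in place.

    Order within the step: experiments and publications resolve first
    (synchronously, against beginning-of-step state), then retirement
    and replacement restore the population size, then survivors age.
    """
    experimented, published, true_pos = _conduct_experiments(pop, scenario, params, rng)
    pop.value[published] += 1
    pop.n_true_pos[true_pos] += 1
    pop.n_false_pos[published & ~true_pos] += 1

    retiring = retire(pop, params.p_retire, rng)
    newborn_mask = np.zeros(pop.size, dtype=bool)
    if retiring.size:
        newborn_mask[retiring] = True
        survivors = pop.take(~newborn_mask)
        newborns = spawn_replacements(survivors, retiring.size, params, scenario, rng)
        pop.assign(retiring, newborns)
    pop.age[~newborn_mask] += 1

    return summarize_population(pop, experimented.sum(), published.sum())


_TRAJECTORY_FIELDS = ("effort", "n_hypotheses", "value", "fp_agent", "fp_pooled")


@dataclass
class RunRecord:
    """One replicate's per-step summaries and final-state snapshot."""

    scenario: str
    prior_null: float
    seed: tuple
    n_steps: int
    trajectory: dict[str, np.ndarray] = field(repr=False)
    final: Population = field(repr=False)

    @property
    def final_fp_count(self) -> int:
        return int(self.final.n_false_pos.sum())

    @property
    def final_tp_count(self) -> int:
        return int(self.final.n_true_pos.sum())

    @property
    def final_pub_count(self) -> int:
        return self.final_fp_count + self.final_tp_count


def run_replicate(params: Parameters, scenario: Scenario, seed) -> RunRecord:
    """Run one seeded replicate of ``params.n_steps`` steps.

    ``seed`` may be an int, a tuple of ints, or a ``SeedSequence``; it
    fully determines the run.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, dyn_ss = ss.spawn(2)
    pop = init_population(params, scenario, np.random.default_rng(init_ss))
    rng = np.random.default_rng(dyn_ss)

    traj = {name: np.empty(params.n_steps) for name in _TRAJECTORY_FIELDS}
    for t_idx in range(params.n_steps):
        s = step(pop, scenario, params, rng)
        traj["effort"][t_idx] = s.effort_median
        traj["n_hypotheses"][t_idx] = s.k_median
        traj["value"][t_idx] = s.value_median
        traj["fp_agent"][t_idx] = s.fp_agent_median
        traj["fp_pooled"][t_idx] = s.fp_pooled

    entropy = ss.entropy if isinstance(ss.entropy, tuple) else (ss.entropy,)
    return RunRecord(
        scenario=scenario.name,
        prior_null=params.prior_null,
        seed=tuple(int(e) for e in entropy),
        n_steps=params.n_steps,
        trajectory=traj,
        final=pop,
    )


def run_experiment_grid(
    params: Parameters,
    scenarios: Iterable[Scenario],
    priors: Iterable[float],
    n_replicates: int | None = None,
    base_seed: int | None = None,
    match_scenario_seeds: bool = False,
    progress=None,
) -> dict[tuple[str, float, int], RunRecord]:
    """Run the full (scenario x prior x replicate) design.

    Cell seeds derive deterministically from ``base_seed`` and the cell's
    indices, so any single cell can be re-run in isolation.  With
    ``match_scenario_seeds=True`` the scenario index is dropped from the
    seed so that replicate *r* shares its random stream across scenarios,
    enabling paired cross-scenario comparisons.

    ``progress``, if given, is called once per completed replicate with
    the cell key (e.g. for logging).
    """
    scenarios = list(scenarios)
    priors = list(priors)
    if not scenarios or not priors:
        raise ParameterError("need at least one scenario and one prior")
    n_replicates = params.n_replicates if n_replicates is None else n_replicates
    base_seed = params.base_seed if base_seed is None else base_seed

    records: dict[tuple[str, float, int], RunRecord] = {}
    for p_idx, prior in enumerate(priors):
        cell_params = params.with_overrides(prior_null=prior, n_replicates=n_replicates, base_seed=base_seed)
        for s_idx, scen in enumerate(scenarios):
            for rep in range(n_replicates):
                entropy = (base_seed, p_idx, rep) if match_scenario_seeds else (base_seed, p_idx, s_idx, rep)
                rec = run_replicate(cell_params, scen, np.random.SeedSequence(entropy))
                records[(scen.name, prior, rep)] = rec
                if progress is not None:
                    progress((scen.name, prior, rep))
    return records
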