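"""Agent state and evolutionary birth-death dynamics.

A population of ``N`` researchers is stored column-wise (one numpy array
per state variable) for vectorized stepping.  Each researcher carries:

* ``effort`` — drives both productivity (via the decreasing
  effort-to-experiment-probability curve) and statistical power (via
  ``df = 2E - 2`` and the noncentrality parameter);
* ``n_hypotheses`` — how many tests are run per experiment, the
  P-hacking trait;
* ``value`` — cumulative publication count, the fitness currency;
* ``age`` — time steps active (bookkeeping only);
* ``d_scale`` — the researcher's personal effect-size scale, from which
  per-experiment true effects are drawn;
* ``n_true_pos`` / ``n_false_pos`` — career publication tallies, with
  ``value = n_true_pos + n_false_pos`` at all times.

Researchers retire independently at a fixed per-step probability and are
replaced by offspring of the currently most-published agents, with
Gaussian mutation of the two method traits. Evolution therefore acts
purely through selective replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .exceptions import ParameterError, SimulationError
from .stats_kernel import scale_from_prior

__all__ = ["Parameters", "Researcher", "Population", "init_population", "retire", "spawn_replacements"]


@dataclass(frozen=True)
class Parameters:
    """Model parameters. Defaults are the published full-scale configuration.

    ``n_researchers`` (N), initial/min/max effort and hypothesis counts,
    mutation standard deviations, the effect-size prior, the effort-cost
    rate ``eta``, the retirement rate, and the top fraction of the
    population eligible to seed replacements.
    """

    n_researchers: int = 2000
    effort_init: float = 20.0
    k_init: int = 1
    effort_min: float = 5.0
    k_min: int = 1
    effort_max: float = 500.0
    k_max: int = 50
    sigma_effort: float = 10.0
    sigma_k: float = 2.0
    prior_null: float = 0.8
    d_min: float = 0.2
    eta: float = 0.01
    p_retire: float = 0.002
    top_fraction: float = 0.1
    # study design
    n_steps: int = 50_000
    n_replicates: int = 100
    base_seed: int = 0
    # modelling switches
    hierarchical_effects: bool = True
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.n_researchers < 1:
            raise ParameterError("n_researchers must be >= 1")
        if not self.effort_min <= self.effort_init <= self.effort_max:
            raise ParameterError("effort_init must lie in [effort_min, effort_max]")
        if self.effort_min <= 1:
            raise ParameterError("effort_min must be > 1 (df = 2E - 2 must stay positive)")
        if self.k_min > self.k_max or not self.k_min <= self.k_init <= self.k_max:
            raise ParameterError("need k_min <= k_init <= k_max")
        if self.k_min < 1:
            raise ParameterError("k_min must be >= 1")
        if not 0.0 < self.prior_null < 1.0:
            raise ParameterError("prior_null must be in (0, 1)")
        if self.d_min <= 0:
            raise ParameterError("d_min must be > 0")
        if self.eta < 0 or self.sigma_effort < 0 or self.sigma_k < 0:
            raise ParameterError("eta, sigma_effort and sigma_k must be >= 0")
        if not 0.0 <= self.p_retire <= 1.0:
            raise ParameterError("p_retire must be in [0, 1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ParameterError("top_fraction must be in (0, 1]")
        if self.n_steps < 0 or self.n_replicates < 1:
            raise ParameterError("n_steps must be >= 0 and n_replicates >= 1")

    @property
    def d0(self) -> float:
        """Exponential effect-size scale implied by (d_min, prior_null)."""
        return scale_from_prior(self.d_min, self.prior_null)

    def with_overrides(self, **kwargs) -> "Parameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Researcher:
    """Read-only view of one agent's state vector."""

    effort: float
    n_hypotheses: int
    value: int
    age: int
    d_scale: float
    n_true_pos: int
    n_false_pos: int


@dataclass
class Population:
    """Column-wise store of N researchers."""

    effort: np.ndarray
    n_hypotheses: np.ndarray
    value: np.ndarray
    age: np.ndarray
    d_scale: np.ndarray
    n_true_pos: np.ndarray
    n_false_pos: np.ndarray

    @property
    def size(self) -> int:
        return self.effort.size

    def researcher(self, i: int) -> Researcher:
        return Researcher(
            float(self.effort[i]), int(self.n_hypotheses[i]), int(self.value[i]),
            int(self.age[i]), float(self.d_scale[i]),
            int(self.n_true_pos[i]), int(self.n_false_pos[i]),
        )

    def copy(self) -> "Population":
        return Population(*(getattr(self, f.name).copy() for f in fields(self)))

    def take(self, idx) -> "Population":
        """New population holding the agents at ``idx`` (copying)."""
        return Population(*(getattr(self, f.name)[idx].copy() for f in fields(self)))

    def assign(self, idx, other: "Population") -> None:
        """Overwrite the agents at ``idx`` with the agents of ``other``, in order."""
        for f in fields(self):
            getattr(self, f.name)[idx] = getattr(other, f.name)


def _draw_d_scales(n: int, params: Parameters, rng: np.random.Generator) -> np.ndarray:
    # Hierarchical mode: each researcher's personal scale is itself an
    # exponential draw with mean d0, so per-experiment effects are
    # exponential given the researcher. Flat mode pins every scale at d0,
    # for which the prior-null formula is exact.
    if params.hierarchical_effects:
        return rng.exponential(params.d0, size=n)
    return np.full(n, params.d0)


def init_population(params: Parameters, scenario, rng: np.random.Generator) -> Population:
    """All-identical-methods starting population.

    Every agent starts at the initial effort and hypothesis count (the
    latter forced to 1 when the scenario forbids multiple hypotheses),
    with zero publications and a freshly drawn personal effect-size scale.
    """
    n = params.n_researchers
    k0 = params.k_init if scenario.multi_allowed else 1
    return Population(
        effort=np.full(n, float(params.effort_init)),
        n_hypotheses=np.full(n, k0, dtype=np.int64),
        value=np.zeros(n, dtype=np.int64),
        age=np.zeros(n, dtype=np.int64),
        d_scale=_draw_d_scales(n, params, rng),
        n_true_pos=np.zeros(n, dtype=np.int64),
        n_false_pos=np.zeros(n, dtype=np.int64),
    )


def retire(population: Population, p_retire: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of researchers retiring this step (independent Bernoulli draws)."""
    if not 0.0 <= p_retire <= 1.0:
        raise ParameterError("p_retire must be in [0, 1]")
    return np.nonzero(rng.random(population.size) < p_retire)[0]


def spawn_replacements(
    survivors: Population,
    n_new: int,
    params: Parameters,
    scenario,
    rng: np.random.Generator,
) -> Population:
    """Create ``n_new`` entrants descended from the top-published survivors.

    Parents are drawn uniformly (with replacement) from the top
    ``ceil(top_fraction * N)`` survivors ranked by publication count,
    ties broken by uniform random ordering.  Offspring copy the parent's
    method traits and mutate them — effort by a ``N(0, sigma_effort)``
    perturbation clipped to its bounds, hypothesis count by a rounded
    ``N(0, sigma_k)`` perturbation clipped to its bounds (held at 1 when
    the scenario forbids multiple hypotheses) — and start their careers
    from scratch: zero publications, age zero, fresh personal scale.
    """
    if n_new < 0:
        raise ParameterError("n_new must be >= 0")
    if survivors.size == 0:
        raise SimulationError("cannot spawn replacements from an empty survivor pool")
    if n_new == 0:
        return survivors.take(np.array([], dtype=np.intp))

    # rank by value, random tie-break: shuffle first, then stable-sort desc
    perm = rng.permutation(survivors.size)
    order = perm[np.argsort(-survivors.value[perm], kind="stable")]
    pool_size = min(math.ceil(params.top_fraction * params.n_researchers), survivors.size)
    pool = order[:pool_size]
    parents = pool[rng.integers(0, pool_size, size=n_new)]

    effort = np.clip(
        survivors.effort[parents] + rng.normal(0.0, params.sigma_effort, size=n_new)
        if params.sigma_effort > 0 else survivors.effort[parents].copy(),
        params.effort_min, params.effort_max,
    )
    if scenario.multi_allowed:
        jump = np.rint(rng.normal(0.0, params.sigma_k, size=n_new)).astype(np.int64) \
            if params.sigma_k > 0 else 0
        k = np.clip(survivors.n_hypotheses[parents] + jump, params.k_min, params.k_max)
    else:
        k = np.ones(n_new, dtype=np.int64)

    zeros = np.zeros(n_new, dtype=np.int64)
    return Population(
        effort=effort,
        n_hypotheses=np.asarray(k, dtype=np.int64),
        value=zeros.copy(),
        age=zeros.copy(),
        d_scale=_draw_d_scales(n_new, params, rng),
        n_true_pos=zeros.copy(),
        n_false_pos=zeros.copy(),
    )
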