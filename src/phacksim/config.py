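"""Run configuration: presets, YAML loading, validation.

A :class:`RunConfig` bundles the model :class:`~phacksim.population.Parameters`
with the study design — which scenarios and priors to run, the output
directory, the seed, and a scale preset.  Two presets are provided:

* ``full`` — the published study design: N=2000 researchers, 50000
  steps, 100 replicates per cell;
* ``reduced`` — a desk-scale design preserving the qualitative regime:
  N=200, 5000 steps, 20 replicates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .engine import SCENARIOS, Scenario
from .exceptions import ParameterError
from .population import Parameters

__all__ = ["RunConfig", "PRESETS", "load_config"]

PRESETS = {
    "full": dict(n_researchers=2000, n_steps=50_000, n_replicates=100),
    "reduced": dict(n_researchers=200, n_steps=5_000, n_replicates=20),
}

_PARAM_FIELDS = {f.name for f in dc_fields(Parameters)}


@dataclass
class RunConfig:
    """A fully resolved run configuration."""

    params: Parameters
    scenarios: tuple[Scenario, ...] = tuple(SCENARIOS.values())
    priors: tuple[float, ...] = (0.9, 0.8, 0.5)
    outdir: Path = Path("phacksim_out")
    preset: str = "full"
    match_scenario_seeds: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not self.scenarios:
            raise ParameterError("at least one scenario is required")
        if not self.priors:
            raise ParameterError("at least one prior is required")
        for p in self.priors:
            if not 0.0 < p < 1.0:
                raise ParameterError(f"prior_null must be in (0, 1), got {p}")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "scenarios": [
                {"name": s.name, "alpha": s.alpha, "multi_allowed": s.multi_allowed}
                for s in self.scenarios
            ],
            "priors": list(self.priors),
            "outdir": str(self.outdir),
            "preset": self.preset,
            "match_scenario_seeds": self.match_scenario_seeds,
        }

    def config_hash(self) -> str:
        """Stable hash of everything that determines the outputs (outdir excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _resolve_scenarios(names) -> tuple[Scenario, ...]:
    out = []
    for name in names:
        if isinstance(name, Scenario):
            out.append(name)
        elif name in SCENARIOS:
            out.append(SCENARIOS[name])
        else:
            raise ParameterError(
                f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
            )
    return tuple(out)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file and/or overrides.

    The file (and the keyword overrides, which win) may set any model
    parameter by name, plus ``scenarios`` (list of names), ``priors``,
    ``outdir``, ``preset``, and ``match_scenario_seeds``.  Omitted model
    parameters take the published defaults; the preset (default
    ``full``) fills in population size, step count and replicate count
    unless explicitly overridden.  Unknown keys are rejected.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    raw.update(overrides)

    known_top = {"scenarios", "priors", "outdir", "preset", "match_scenario_seeds"}
    unknown = set(raw) - known_top - _PARAM_FIELDS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")

    preset = raw.pop("preset", "full")
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")

    param_kwargs = dict(PRESETS[preset])
    param_kwargs.update({k: raw.pop(k) for k in list(raw) if k in _PARAM_FIELDS})
    params = Parameters(**param_kwargs)

    kwargs = {}
    if "scenarios" in raw:
        kwargs["scenarios"] = _resolve_scenarios(raw.pop("scenarios"))
    if "priors" in raw:
        priors = raw.pop("priors")
        kwargs["priors"] = tuple(priors) if isinstance(priors, (list, tuple)) else (float(priors),)
    if "outdir" in raw:
        kwargs["outdir"] = Path(raw.pop("outdir"))
    if "match_scenario_seeds" in raw:
        kwargs["match_scenario_seeds"] = bool(raw.pop("match_scenario_seeds"))
    return RunConfig(params=params, preset=preset, **kwargs)
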