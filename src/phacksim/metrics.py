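"""Aggregation of run records into the study's reported quantities.

Three families of summaries:

* per-step **median trajectories** (median across the 2000 living
  researchers within each replicate, then averaged across replicates);
* the replicate-level **final false-positive publication rate** — the
  pooled ratio cumulative FP / (TP + FP) over the researchers alive at
  the final step, one value per replicate, shown as a histogram;
* pooled **final distributions** of the hypothesis count and effort over
  all replicates x researchers.

Two distinct false-positive summaries are emitted on purpose: the
replicate-level pooled ratio just described, and a per-agent version
(median across living agents of each agent's career FP/(TP+FP), agents
with no publications excluded) used in the trajectory panels. They
answer different questions — "what fraction of the literature is false"
versus "what does the typical researcher's record look like".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import RunRecord
from .exceptions import InvalidInputError
from .population import Population

__all__ = [
    "TrajectorySummary",
    "FinalDistributions",
    "cumulative_fp_rate",
    "replicate_fp_rates",
    "median_trajectory",
    "final_histograms",
    "trajectory_frame",
    "histogram_frame",
]


def cumulative_fp_rate(final_population: Population) -> float:
    """Pooled false-positive publication rate of the living researchers.

    ``sum(FP) / (sum(TP) + sum(FP))`` over the current population;
    agents without publications contribute nothing to either sum.
    Returns NaN when no researcher has published (the rate is undefined;
    callers exclude such replicates from histograms and count them).
    """
    fp = int(final_population.n_false_pos.sum())
    pubs = fp + int(final_population.n_true_pos.sum())
    if pubs == 0:
        return float("nan")
    return fp / pubs


@dataclass(frozen=True)
class TrajectorySummary:
    """Replicate-averaged median trajectory of one field."""

    field: str
    values: np.ndarray  # length n_steps
    n_replicates: int

    def __len__(self) -> int:
        return self.values.size


def median_trajectory(records: Sequence[RunRecord] | Mapping, field: str) -> TrajectorySummary:
    """Average the per-replicate median trajectories of ``field``.

    Within each replicate the per-step value is already the median
    across living researchers; this averages those arithmetically across
    replicates, ignoring steps where a replicate's value is undefined
    (NaN, e.g. the false-positive ratio before the first publication).
    """
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    if not recs:
        raise InvalidInputError("no records supplied")
    n_steps = recs[0].n_steps
    if any(r.n_steps != n_steps for r in recs):
        raise InvalidInputError("records must share n_steps")
    if field not in recs[0].trajectory:
        raise InvalidInputError(
            f"unknown field {field!r}; available: {sorted(recs[0].trajectory)}"
        )
    stacked = np.vstack([r.trajectory[field] for r in recs])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0) if stacked.size else np.empty(0)
    return TrajectorySummary(field=field, values=mean, n_replicates=len(recs))


@dataclass(frozen=True)
class FinalDistributions:
    """Binned final-step distributions across replicates.

    ``fp_rate`` bins the one-per-replicate pooled false-positive rate;
    ``n_hypotheses`` and ``effort`` pool every researcher over every
    replicate.  Each histogram is (edges, counts) with
    ``len(edges) == len(counts) + 1``.
    """

    fp_rate_edges: np.ndarray
    fp_rate_counts: np.ndarray
    n_undefined_fp: int  # replicates with zero publications, excluded above
    k_edges: np.ndarray
    k_counts: np.ndarray
    effort_edges: np.ndarray
    effort_counts: np.ndarray


def final_histograms(
    records: Sequence[RunRecord] | Mapping,
    fp_bin_width: float = 0.025,
    effort_bin_width: float = 10.0,
) -> FinalDistributions:
    """Histogram the final-step state across a cell's replicates.

    The false-positive-rate histogram spans [0, 1] with the given bin
    width (default 0.025, fine enough to resolve a cluster between
    0.875 and 0.9); the hypothesis-count histogram uses unit-width
    integer bins; effort bins span the observed range.
    """
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    if not recs:
        raise InvalidInputError("no records supplied")

    rates = np.array([cumulative_fp_rate(r.final) for r in recs])
    defined = rates[~np.isnan(rates)]
    n_bins = int(np.ceil(1.0 / fp_bin_width))
    fp_edges = np.linspace(0.0, n_bins * fp_bin_width, n_bins + 1)
    fp_counts, _ = np.histogram(defined, bins=fp_edges)

    k_all = np.concatenate([r.final.n_hypotheses for r in recs])
    k_edges = np.arange(k_all.min() - 0.5, k_all.max() + 1.5)
    k_counts, _ = np.histogram(k_all, bins=k_edges)

    e_all = np.concatenate([r.final.effort for r in recs])
    lo = np.floor(e_all.min() / effort_bin_width) * effort_bin_width
    hi = np.ceil(e_all.max() / effort_bin_width) * effort_bin_width
    hi = max(hi, lo + effort_bin_width)
    e_edges = np.arange(lo, hi + effort_bin_width / 2, effort_bin_width)
    e_counts, _ = np.histogram(e_all, bins=e_edges)

    return FinalDistributions(
        fp_rate_edges=fp_edges,
        fp_rate_counts=fp_counts,
        n_undefined_fp=int(np.isnan(rates).sum()),
        k_edges=k_edges,
        k_counts=k_counts,
        effort_edges=e_edges,
        effort_counts=e_counts,
    )


def replicate_fp_rates(records: Sequence[RunRecord] | Mapping) -> np.ndarray:
    """One pooled final false-positive rate per replicate (NaN where undefined)."""
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    if not recs:
        raise InvalidInputError("no records supplied")
    return np.array([cumulative_fp_rate(r.final) for r in recs])


def trajectory_frame(records: Sequence[RunRecord] | Mapping,
                     fields: Sequence[str] = ("effort", "n_hypotheses", "value", "fp_agent", "fp_pooled"),
                     ) -> pd.DataFrame:
    """Tidy (step, field, value) frame of replicate-averaged trajectories."""
    parts = []
    for f in fields:
        ts = median_trajectory(records, f)
        parts.append(pd.DataFrame({
            "step": np.arange(1, len(ts) + 1),
            "field": f,
            "value": ts.values,
        }))
    return pd.concat(parts, ignore_index=True)


def histogram_frame(dists: FinalDistributions) -> pd.DataFrame:
    """Tidy (field, bin_lo, bin_hi, count) frame of the final histograms."""
    rows = []
    for name, edges, counts in (
        ("fp_rate", dists.fp_rate_edges, dists.fp_rate_counts),
        ("n_hypotheses", dists.k_edges, dists.k_counts),
        ("effort", dists.effort_edges, dists.effort_counts),
    ):
        rows.append(pd.DataFrame({
            "field": name,
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
        }))
    return pd.concat(rows, ignore_index=True)
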