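"""Rendering of saved output tables as figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import read_table  # noqa: E402

__all__ = ["plot_trajectory_table", "plot_histogram_table"]

_PANEL_FIELDS = ("effort", "n_hypotheses", "fp_agent", "value")
_LABELS = {
    "effort": "median effort",
    "n_hypotheses": "median hypotheses per experiment",
    "fp_agent": "median agent FP rate",
    "fp_pooled": "pooled FP rate",
    "value": "median publications",
}


def plot_trajectory_table(csv_path: str | Path, out_path: str | Path) -> Path:
    """Four-panel trajectory figure (effort, hypotheses, FP rate, value)."""
    df = read_table(csv_path)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, fieldname in zip(axes.ravel(), _PANEL_FIELDS):
        sub = df[df["field"] == fieldname]
        ax.plot(sub["step"], sub["value"], lw=0.8)
        ax.set_ylabel(_LABELS.get(fieldname, fieldname))
    for ax in axes[1]:
        ax.set_xlabel("time step")
    fig.suptitle(Path(csv_path).stem)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)


def plot_histogram_table(csv_path: str | Path, out_path: str | Path) -> Path:
    """Three-panel final-distribution figure (FP rate, hypotheses, effort)."""
    df = read_table(csv_path)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, fieldname in zip(axes, ("fp_rate", "n_hypotheses", "effort")):
        sub = df[df["field"] == fieldname]
        widths = sub["bin_hi"] - sub["bin_lo"]
        ax.bar(sub["bin_lo"], sub["count"], width=widths, align="edge")
        ax.set_xlabel(_LABELS.get(fieldname, fieldname))
        ax.set_ylabel("count")
    fig.suptitle(Path(csv_path).stem)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
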