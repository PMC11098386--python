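"""Serialization of simulation outputs: CSV tables plus a JSON manifest.

Every CSV begins with comment lines embedding the configuration hash and
the base seed, so a table can always be traced back to the exact run
that produced it; ``manifest.json`` stores the full configuration, the
per-cell seeds, and the package version, which together reproduce the
outputs byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .config import RunConfig
from .engine import RunRecord
from .metrics import final_histograms, histogram_frame, trajectory_frame

__all__ = ["write_cell_outputs", "write_manifest", "read_table"]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by this module (skipping the comment header)."""
    return pd.read_csv(path, comment="#")


def _cell_tag(scenario: str, prior: float) -> str:
    return f"{scenario}_{prior:g}".replace(".", "p")


def write_cell_outputs(
    outdir: str | Path,
    records: Mapping[tuple[str, float, int], RunRecord],
    cfg: RunConfig,
) -> list[Path]:
    """Write one trajectory table and one histogram table per (scenario, prior) cell."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    seed = cfg.params.base_seed
    written: list[Path] = []
    cells = sorted({(s, p) for s, p, _ in records})
    for scenario, prior in cells:
        cell = [r for (s, p, _), r in sorted(records.items()) if s == scenario and p == prior]
        tag = _cell_tag(scenario, prior)
        tpath = outdir / f"trajectory_{tag}.csv"
        _write_table(trajectory_frame(cell), tpath, chash, seed)
        hpath = outdir / f"final_hist_{tag}.csv"
        _write_table(histogram_frame(final_histograms(cell)), hpath, chash, seed)
        written += [tpath, hpath]
    return written


def write_manifest(
    outdir: str | Path,
    records: Mapping[tuple[str, float, int], RunRecord],
    cfg: RunConfig,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "phacksim",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "cells": [
            {"scenario": s, "prior_null": p, "replicate": r, "seed_entropy": list(rec.seed)}
            for (s, p, r), rec in sorted(records.items())
        ],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
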