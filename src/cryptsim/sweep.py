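"""Factorial parameter sweeps and their on-disk products.

A sweep runs replicates at each combination of the varied keys and
writes per-condition tables: replicate summaries, survival tables,
mutator-fixation fractions, mutation-per-day burden, crypt fitness, and
spatial mutator agreement, plus a manifest from which every output can
be regenerated byte-identically.

Two constraint modes for crypt-size sweeps mirror the two tissue-design
views: ``fixed_crypt_count`` holds the grid and lets total stem-cell
number vary; ``fixed_total_stem_cells`` holds ``n_crypts x crypt_size``
constant by resizing the grid (most-square factorization; a non-integer
crypt count is an error rather than an approximation).

The special key ``turnover_multiplier`` scales ``base_division_rate``
and ``base_loss_rate`` jointly (stem-cell turnover is varied "in
unison"); every other key must be a SimulationParams field.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import run_replicates, summary_frame, derive_seeds
from .params import SimulationParams, serialize_params
from .stats import (km_cumulative_hazard, mutator_fixed_fraction,
                    mutator_agreement_by_distance, crypt_fitness,
                    turnover_and_burden_metrics)

__all__ = ["SweepSpec", "run_sweep", "grid_for_total"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}
#: Derived sweep keys that are not SimulationParams fields.
DERIVED_KEYS = {"turnover_multiplier"}

CONSTRAINT_MODES = ("fixed_crypt_count", "fixed_total_stem_cells")


@dataclass(frozen=True)
class SweepSpec:
    """A factorial sweep: base params, varied keys, and run settings."""

    base: SimulationParams
    varied: Mapping[str, Sequence[Any]]
    replicates: int = 50
    seed: int = 0
    constraint_mode: str = "fixed_crypt_count"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.constraint_mode not in CONSTRAINT_MODES:
            raise ValueError(f"constraint_mode must be one of {CONSTRAINT_MODES}")
        if not self.varied:
            raise ValueError("sweep must vary at least one key")
        for key, values in self.varied.items():
            if key not in _PARAM_FIELDS and key not in DERIVED_KEYS:
                raise ValueError(f"unknown sweep key {key!r}")
            if len(values) == 0:
                raise ValueError(f"empty value list for sweep key {key!r}")

    def conditions(self) -> list[dict[str, Any]]:
        keys = list(self.varied)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.varied[k] for k in keys))]

    def params_for(self, condition: Mapping[str, Any]) -> SimulationParams:
        """Materialize one condition's params, applying the constraint."""
        changes: dict[str, Any] = {}
        for key, value in condition.items():
            if key == "turnover_multiplier":
                changes["base_division_rate"] = self.base.base_division_rate * value
                changes["base_loss_rate"] = self.base.base_loss_rate * value
            else:
                changes[key] = value
        p = self.base.replace(**changes)
        if (self.constraint_mode == "fixed_total_stem_cells"
                and "crypt_size" in condition):
            rows, cols = grid_for_total(self.base.total_stem_cells, p.crypt_size)
            p = p.replace(grid_rows=rows, grid_cols=cols)
        return p


def grid_for_total(total_stem_cells: int, crypt_size: int) -> tuple[int, int]:
    """Most-square (rows, cols) grid with rows*cols*crypt_size == total.

    Raises when the total is not divisible by the crypt size (the
    constant-total constraint is enforced, never approximated).
    """
    if total_stem_cells % crypt_size != 0:
        raise ValueError(
            f"total of {total_stem_cells} stem cells cannot be partitioned "
            f"into crypts of {crypt_size} (non-integer crypt count)")
    n_crypts = total_stem_cells // crypt_size
    rows = int(math.isqrt(n_crypts))
    while n_crypts % rows != 0:
        rows -= 1
    return rows, n_crypts // rows


def _condition_label(condition: Mapping[str, Any]) -> str:
    return "__".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                     for k, v in condition.items())


def run_sweep(spec: SweepSpec, out_dir: str | Path | None = None,
              *, save_events: bool = False, progress: bool = False,
              **run_kwargs) -> dict[str, dict]:
    """Execute every condition of ``spec``; optionally write tables.

    Returns a mapping condition-label -> dict with the per-condition
    products (params, replicate summary frame, survival table, and the
    scalar outcome statistics).  When ``out_dir`` is given, each
    condition gets a subdirectory of CSV/TSV files with a provenance
    header, and a ``manifest.json`` records everything needed to
    regenerate them.
    """
    from . import __version__

    out_root = Path(out_dir) if out_dir is not None else None
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "base_params": serialize_params(spec.base),
        "varied": {k: list(v) for k, v in spec.varied.items()},
        "replicates": spec.replicates,
        "seed": spec.seed,
        "constraint_mode": spec.constraint_mode,
        "conditions": {},
    }
    results: dict[str, dict] = {}
    cond_seeds = derive_seeds(spec.seed, len(spec.conditions()))
    for cond, cond_seed in zip(spec.conditions(), cond_seeds):
        label = _condition_label(cond)
        params = spec.params_for(cond)
        runs = run_replicates(params, spec.replicates, cond_seed,
                              progress=progress,
                              record_events=save_events, **run_kwargs)
        summary = summary_frame(runs)
        flags = summary["endpoint"] == "initiation"
        survival = km_cumulative_hazard(summary["endpoint_time_days"], flags)
        mutator_fracs = [mutator_fixed_fraction(r.final_tissue_snapshot)
                         for r in runs]
        turnover = pd.DataFrame([turnover_and_burden_metrics(r) for r in runs])
        fitness = [float(r.final_tissue_snapshot["mean_fitness"].mean())
                   if len(r.final_tissue_snapshot) else float("nan")
                   for r in runs]
        agreement = _pooled_agreement(runs)
        stats = {
            "incidence": float(flags.mean()),
            "mutator_fixed_fraction_mean":
                float(np.nanmean(mutator_fracs)) if mutator_fracs else float("nan"),
            "mutations_per_day_mean": float(turnover["mutations_per_day"].mean()),
            "divisions_per_day_mean": float(turnover["divisions_per_day"].mean()),
            "crypt_births_total": int(turnover["crypt_births"].sum()),
            "crypt_deaths_total": int(turnover["crypt_deaths"].sum()),
            "crypt_fitness_mean": float(np.nanmean(fitness)),
        }
        results[label] = {
            "condition": cond,
            "params": params,
            "seed": cond_seed,
            "runs": runs,
            "summary": summary,
            "survival": survival,
            "turnover": turnover,
            "agreement": agreement,
            "stats": stats,
        }
        manifest["conditions"][label] = {
            "condition": cond, "seed": cond_seed,
            "params": serialize_params(params), "stats": stats,
        }
        if out_root is not None:
            _write_condition(out_root / label, params, results[label])
    if out_root is not None:
        with open(out_root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results


def _pooled_agreement(runs) -> pd.DataFrame:
    """Agreement-by-distance pooled over replicates (pair-weighted)."""
    counts: dict[int, int] = {}
    agree: dict[int, float] = {}
    for r in runs:
        if len(r.final_tissue_snapshot) < 2:
            continue
        table = mutator_agreement_by_distance(r.final_tissue_snapshot)
        for _, row in table.iterrows():
            d = int(row["distance_class"])
            counts[d] = counts.get(d, 0) + int(row["n_pairs"])
            agree[d] = agree.get(d, 0.0) + row["agreement"] * row["n_pairs"]
    rows = [{"distance_class": d, "n_pairs": counts[d],
             "agreement": agree[d] / counts[d]} for d in sorted(counts)]
    return pd.DataFrame(rows, columns=["distance_class", "n_pairs", "agreement"])


def _write_condition(cond_dir: Path, params: SimulationParams,
                     bundle: dict) -> None:
    from .params import provenance_header

    cond_dir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(params)
    for name, frame in (("summary.csv", bundle["summary"]),
                        ("survival.csv", bundle["survival"]),
                        ("turnover.csv", bundle["turnover"]),
                        ("agreement.csv", bundle["agreement"])):
        with open(cond_dir / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    with open(cond_dir / "stats.json", "w") as fh:
        json.dump(bundle["stats"], fh, indent=2)
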