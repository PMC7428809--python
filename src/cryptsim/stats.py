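"""Outcome statistics over simulation replicates.

Covers the model's reporting surface: time-to-initiation survival
analysis (Kaplan-Meier product-limit survival with cumulative hazard
``H(t) = -ln S(t)``; Nelson-Aalen available for comparison), the
fraction of crypts with a fixed mutator population, spatial mutator
agreement by lattice distance class, genotype-intrinsic crypt fitness,
and crypt turnover / mutational-burden summaries.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import fitness_multiplier
from .hexgrid import hex_distance
from .params import SimulationParams
from .tissue import Crypt

__all__ = [
    "km_cumulative_hazard",
    "mutator_fixed_fraction",
    "mutator_agreement_by_distance",
    "crypt_fitness",
    "turnover_and_burden_metrics",
    "population_time_average",
    "incidence",
]

SURVIVAL_COLUMNS = ("time", "n_at_risk", "n_events", "n_censored",
                    "survival", "cumulative_hazard")


def km_cumulative_hazard(times: Sequence[float], event_flags: Sequence[bool],
                         *, method: str = "kaplan-meier") -> pd.DataFrame:
    """Survival table with cumulative hazard from replicate endpoints.

    ``times`` are endpoint times; ``event_flags`` mark which are events
    (initiations) versus censorings.  Default is the Kaplan-Meier
    product-limit estimate with ``H(t) = -ln S(t)``; where the survival
    estimate reaches 0 (all subjects experience the event) the hazard is
    reported as ``inf``.  ``method="nelson-aalen"`` gives the
    Nelson-Aalen cumulative hazard with ``S(t) = exp(-H(t))``.
    """
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if times.shape != flags.shape:
        raise ValueError("times and event_flags must have equal length")
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")

    from lifelines import KaplanMeierFitter, NelsonAalenFitter

    if method == "kaplan-meier":
        fitter = KaplanMeierFitter()
        fitter.fit(times, event_observed=flags)
        surv = fitter.survival_function_.iloc[:, 0]
        table = fitter.event_table
        # drop the t=0 anchor row unless an observation sits at 0
        keep = surv.index > 0 if 0 not in times else surv.index >= 0
        surv = surv[keep]
        with np.errstate(divide="ignore"):
            hazard = -np.log(surv.to_numpy())
    elif method == "nelson-aalen":
        fitter = NelsonAalenFitter(nelson_aalen_smoothing=False)
        fitter.fit(times, event_observed=flags)
        haz = fitter.cumulative_hazard_.iloc[:, 0]
        table = fitter.event_table
        keep = haz.index > 0 if 0 not in times else haz.index >= 0
        surv = np.exp(-haz[keep])
        hazard = haz[keep].to_numpy()
    else:
        raise ValueError(f"unknown method {method!r}")

    table = table.reindex(surv.index)
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "n_at_risk": table["at_risk"].to_numpy(dtype=int),
        "n_events": table["observed"].to_numpy(dtype=int),
        "n_censored": table["censored"].to_numpy(dtype=int),
        "survival": np.asarray(surv, dtype=float),
        "cumulative_hazard": hazard,
    })
    return out.reset_index(drop=True)


def incidence(results: Iterable) -> float:
    """Fraction of replicates ending in tumor initiation."""
    results = list(results)
    return sum(r.endpoint == "initiation" for r in results) / len(results)


def mutator_fixed_fraction(snapshot: pd.DataFrame) -> float:
    """Proportion of living crypts whose every stem cell is a mutator.

    ``snapshot`` is a final-tissue summary (one row per living crypt
    with a ``mutator_fixed`` column).  Returns NaN when no crypt is
    alive (undefined; excluded from averages by the caller).
    """
    if len(snapshot) == 0:
        return float("nan")
    return float(snapshot["mutator_fixed"].sum()) / len(snapshot)


def mutator_agreement_by_distance(snapshot: pd.DataFrame) -> pd.DataFrame:
    """Pairwise fixed-mutator agreement by exact hex distance class.

    For each lattice distance ``d >= 1``, over all unordered pairs of
    living crypts at that distance: the fraction whose fixed-mutator
    statuses agree (both fixed or neither).  Distance classes with no
    pairs are omitted.  Requires at least two living crypts.
    """
    if len(snapshot) < 2:
        raise ValueError("need >= 2 living crypts for agreement")
    coords = list(zip(snapshot["q"].astype(int), snapshot["r"].astype(int)))
    status = snapshot["mutator_fixed"].to_numpy(dtype=bool)
    counts: dict[int, int] = {}
    agree: dict[int, int] = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(coords), 2):
        d = hex_distance(a, b)
        counts[d] = counts.get(d, 0) + 1
        if status[i] == status[j]:
            agree[d] = agree.get(d, 0) + 1
    rows = [{"distance_class": d, "n_pairs": counts[d],
             "agreement": agree.get(d, 0) / counts[d]}
            for d in sorted(counts)]
    return pd.DataFrame(rows, columns=["distance_class", "n_pairs", "agreement"])


def crypt_fitness(crypt: Crypt, p: SimulationParams) -> float:
    """Genotype-intrinsic fitness: mean division minus loss rate.

    Averaged over the crypt's living cells using only mutation-derived
    rate factors; transient homeostatic feedback and dead-neighbor
    release are excluded so fitness is comparable across architectures.
    """
    if not crypt.alive or crypt.n_cells == 0:
        raise ValueError("crypt_fitness is undefined for a dead crypt")
    k = p.fitness_factor
    total = 0.0
    for cell in crypt.cells:
        div = p.base_division_rate * fitness_multiplier(
            cell.n_beneficial_div, cell.n_deleterious_div, k)
        loss = p.base_loss_rate * fitness_multiplier(
            cell.n_deleterious_surv, cell.n_beneficial_surv, k)
        total += div - loss
    return total / crypt.n_cells


def turnover_and_burden_metrics(result) -> dict:
    """Crypt turnover and mutational-burden summary of one replicate.

    Returns crypt birth/death counts, mean crypt lifespan (NaN when no
    crypt died), mutation and division events per day, and the
    time-weighted mean number of living stem cells per crypt.
    """
    births = [rec for rec in result.turnover_log if rec[0] == "crypt_birth"]
    deaths = [rec for rec in result.turnover_log if rec[0] == "crypt_death"]
    lifespans = [rec[1] - rec[6] for rec in deaths]
    duration = max(result.endpoint_time, np.finfo(float).tiny)
    return {
        "crypt_births": len(births),
        "crypt_deaths": len(deaths),
        "mean_crypt_lifespan_days": (float(np.mean(lifespans)) if lifespans
                                     else float("nan")),
        "mutations_per_day": result.total_mutations / duration,
        "divisions_per_day": result.total_divisions / duration,
        "mean_stem_cells_per_crypt": result.mean_cells_per_crypt_tw,
        "mean_stem_cells_total": result.mean_cells_tw,
    }


def population_time_average(result, t_start: float, t_end: float) -> float:
    """Time-weighted mean of the living-cell count over a window.

    Requires the replicate to have been run with ``record_events=True``
    (the per-event log reconstructs the population trajectory).  The
    population is piecewise constant between events; the window mean is
    the integral of the trajectory over ``[t_start, t_end]`` divided by
    the window length.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if not result.event_log:
        raise ValueError("population_time_average needs record_events=True")
    p = result.params
    n = p.n_slots * p.crypt_size
    t_prev = 0.0
    integral = 0.0
    end = min(t_end, result.endpoint_time)
    for rec in result.event_log:
        t, kind = rec[0], rec[1]
        lo, hi = max(t_prev, t_start), min(t, end)
        if hi > lo:
            integral += n * (hi - lo)
        if kind == "symmetric_division":
            n += 1
        elif kind == "cell_loss":
            n -= 1
        t_prev = t
        if t_prev >= end:
            break
    if t_prev < end:
        integral += n * (end - max(t_prev, t_start))
    return integral / (t_end - t_start)
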