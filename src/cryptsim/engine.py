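"""Discrete-event simulation engine and replicate driver.

``run`` advances a :class:`~cryptsim.tissue.Tissue` by competing
exponential clocks over all living stem cells until one of four
endpoints: *initiation* (a stem cell accumulates the configured number
of tumor-suppressor-gene hits), *tissue_death* (every crypt extinct),
*uncontrolled_proliferation* (optional; a crypt reaches the uncontrolled
threshold), or *censored* at ``max_days``.

Two execution paths produce the same dynamics: a compiled kernel
(default; see :mod:`cryptsim._kernel`) used for full runs, and a pure
Python reference path built from the public :func:`next_event` /
:func:`apply_event` operations, kept for inspection and cross-checks.
Identical ``(params, seed)`` give bit-identical results within a path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from . import _kernel as K
from ._kernel import run_kernel
from .dynamics import CATEGORIES, MutationEvent, category_from_uniform
from .hexgrid import slot_coordinate
from .params import SimulationParams
from .tissue import Tissue

__all__ = ["RunResult", "Event", "run", "run_replicates", "next_event",
           "apply_event", "cell_rate_arrays", "derive_seeds"]

_KIND_NAMES = {K.KIND_SYM: "symmetric_division",
               K.KIND_LOSS: "cell_loss",
               K.KIND_ASYM: "asymmetric_division"}

EVENT_LOG_COLUMNS = ("time", "event_kind", "q", "r", "cell_id",
                     "n_cells_after", "mutation_category", "tsg_hits_after")
TURNOVER_COLUMNS = ("event", "time", "q", "r", "parent_q", "parent_r",
                    "created_time")

SUMMARY_COLUMNS = ("seed", "endpoint", "endpoint_time_days",
                   "initiating_cell_was_mutator", "n_living_crypts_final",
                   "mutator_fixed_crypts_final", "total_mutations",
                   "total_divisions", "n_general_mutations", "n_tsg_hits",
                   "crypt_births", "crypt_deaths", "mean_cells_per_crypt_tw")

_RNG_BUFFER = 1 << 16
_MUTLOG_CAP = 8192


@dataclass
class RunResult:
    """Outcome and bookkeeping of one simulation replicate."""

    endpoint: str
    endpoint_time: float
    initiating_cell_was_mutator: Optional[bool]
    seed: int
    params: SimulationParams
    n_symmetric_divisions: int
    n_asymmetric_divisions: int
    n_losses: int
    n_general_mutations: int
    n_tsg_hits: int
    mean_cells_tw: float
    mean_cells_per_crypt_tw: float
    n_living_crypts_final: int
    mutator_fixed_crypts_final: int
    final_tissue_snapshot: pd.DataFrame
    turnover_log: list = field(default_factory=list)
    event_log: list = field(default_factory=list)
    mutation_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    mutation_ints: np.ndarray = field(
        default_factory=lambda: np.empty((0, 4), dtype=np.int64))

    @property
    def total_divisions(self) -> int:
        return self.n_symmetric_divisions + self.n_asymmetric_divisions

    @property
    def total_mutations(self) -> int:
        """All fitness/mutator/TSG mutation events."""
        return self.n_general_mutations + self.n_tsg_hits

    @property
    def crypt_births(self) -> int:
        return sum(1 for rec in self.turnover_log if rec[0] == "crypt_birth")

    @property
    def crypt_deaths(self) -> int:
        return sum(1 for rec in self.turnover_log if rec[0] == "crypt_death")

    @property
    def mutation_log(self) -> pd.DataFrame:
        cols = self.params.grid_cols
        rows = self.params.grid_rows
        slots = self.mutation_ints[:, 2]
        return pd.DataFrame({
            "time": self.mutation_times,
            "category": [CATEGORIES[c] for c in self.mutation_ints[:, 0]],
            "cell_id": self.mutation_ints[:, 1],
            "q": slots % cols if len(slots) else slots,
            "r": slots // cols if len(slots) else slots,
            "tsg_hits_after": self.mutation_ints[:, 3],
        })

    @property
    def mutation_events(self) -> list[MutationEvent]:
        cols = self.params.grid_cols
        return [
            MutationEvent(CATEGORIES[int(c)], float(t), int(cid),
                          (int(s) % cols, int(s) // cols))
            for t, (c, cid, s, _) in zip(self.mutation_times, self.mutation_ints)
        ]

    @property
    def event_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.event_log, columns=EVENT_LOG_COLUMNS)

    @property
    def turnover_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.turnover_log, columns=TURNOVER_COLUMNS)

    def summary_row(self) -> dict:
        return {
            "seed": self.seed,
            "endpoint": self.endpoint,
            "endpoint_time_days": self.endpoint_time,
            "initiating_cell_was_mutator": self.initiating_cell_was_mutator,
            "n_living_crypts_final": self.n_living_crypts_final,
            "mutator_fixed_crypts_final": self.mutator_fixed_crypts_final,
            "total_mutations": self.total_mutations,
            "total_divisions": self.total_divisions,
            "n_general_mutations": self.n_general_mutations,
            "n_tsg_hits": self.n_tsg_hits,
            "crypt_births": self.crypt_births,
            "crypt_deaths": self.crypt_deaths,
            "mean_cells_per_crypt_tw": self.mean_cells_per_crypt_tw,
        }


def _pack_params(p: SimulationParams, *, thin: bool, record_all: bool,
                 uncontrolled: bool) -> tuple[np.ndarray, np.ndarray]:
    PF = np.zeros(K.PF_N)
    PI = np.zeros(K.PI_N, dtype=np.int64)
    PF[K.PF_R_DIV] = p.base_division_rate
    PF[K.PF_RATIO] = p.asym_to_sym_ratio
    PF[K.PF_R_LOSS] = p.base_loss_rate
    PF[K.PF_K_SIZE] = float(p.crypt_size)
    PF[K.PF_INV_DEV] = 0.0 if math.isinf(p.crypt_deviation) else 1.0 / p.crypt_deviation
    PF[K.PF_DIV_BASE] = p.division_effect_base
    PF[K.PF_LOSS_BASE] = p.loss_effect_base
    PF[K.PF_DEAD_MULT] = p.dead_neighbor_division_multiplier
    PF[K.PF_DIV_MIN] = p.division_min_time
    PF[K.PF_LOSS_MIN] = p.loss_min_time
    PF[K.PF_MAX_DAYS] = p.max_days
    PF[K.PF_G_BASE] = min(p.mutation_rate, p.mutation_rate_max)
    PF[K.PF_G_MUT] = min(p.mutation_rate * p.mutator_factor, p.mutation_rate_max)
    PF[K.PF_TAU_BASE] = min(p.tsg_mutation_rate, p.tsg_mutation_rate_max)
    PF[K.PF_TAU_MUT] = min(p.tsg_mutation_rate * p.mutator_factor,
                           p.tsg_mutation_rate_max)
    PF[K.PF_DEL_FRAC] = p.deleterious_fraction
    PF[K.PF_DEL_SPLIT0] = p.deleterious_split[0]
    PF[K.PF_BEN0] = p.beneficial_split[0]
    PF[K.PF_BEN01] = p.beneficial_split[0] + p.beneficial_split[1]
    PF[K.PF_BIF_THRESHOLD] = p.bifurcation_factor * p.crypt_size
    PF[K.PF_UNCONTROLLED_CELLS] = p.uncontrolled_threshold * p.crypt_size
    PF[K.PF_K_FIT] = p.fitness_factor
    PF[K.PF_INV_K] = 1.0 / p.fitness_factor
    PI[K.PI_N_SLOTS] = p.n_slots
    PI[K.PI_TSG_THRESHOLD] = p.tsg_hits_for_initiation
    PI[K.PI_THIN] = 1 if thin else 0
    PI[K.PI_RECORD_ALL] = 1 if record_all else 0
    PI[K.PI_UNCONTROLLED_ON] = 1 if uncontrolled else 0
    return PF, PI


def run(params: SimulationParams, seed: int, *, record_events: bool = False,
        thin_asymmetric: bool = True,
        enable_uncontrolled_endpoint: bool = False,
        use_kernel: bool = True) -> RunResult:
    """Simulate one replicate to its endpoint.

    Parameters
    ----------
    params, seed
        Model parameters and the seed of the replicate's generator.
        Identical ``(params, seed)`` give bit-identical results.
    record_events
        Keep the full per-event log (time, kind, crypt, cell,
        population after).  Off by default: full-length runs produce
        hundreds of thousands of events.
    thin_asymmetric
        Integrate out asymmetric divisions that produce no mutation
        (statistically exact for exponential waiting times); their
        number is still counted.  Disable to schedule every asymmetric
        division explicitly.
    enable_uncontrolled_endpoint
        End the run when a crypt reaches ``uncontrolled_threshold x
        crypt_size`` cells.  Disabled by default; the threshold is
        tracked as bookkeeping otherwise.
    """
    if use_kernel:
        return _run_kernel(params, seed, record_events, thin_asymmetric,
                           enable_uncontrolled_endpoint)
    return _run_python(params, seed, record_events, thin_asymmetric,
                       enable_uncontrolled_endpoint)


def _finalize(params, seed, tissue, endpoint, endpoint_time, init_mutator,
              counters, integrals, event_log, mut_t, mut_i) -> RunResult:
    snapshot = tissue.snapshot()
    duration = max(endpoint_time, np.finfo(float).tiny)
    return RunResult(
        endpoint=endpoint,
        endpoint_time=endpoint_time,
        initiating_cell_was_mutator=init_mutator,
        seed=seed,
        params=params,
        n_symmetric_divisions=int(counters["sym"]),
        n_asymmetric_divisions=int(counters["asym"]),
        n_losses=int(counters["loss"]),
        n_general_mutations=int(counters["general"]),
        n_tsg_hits=int(counters["tsg"]),
        mean_cells_tw=integrals["cells"] / duration,
        mean_cells_per_crypt_tw=integrals["per_crypt"] / duration,
        n_living_crypts_final=int(tissue.living_crypt_count),
        mutator_fixed_crypts_final=int(snapshot["mutator_fixed"].sum())
        if len(snapshot) else 0,
        final_tissue_snapshot=snapshot,
        turnover_log=list(tissue.turnover_log),
        event_log=event_log,
        mutation_times=mut_t,
        mutation_ints=mut_i,
    )


def _run_kernel(params, seed, record_events, thin, uncontrolled) -> RunResult:
    rng = np.random.default_rng(seed)
    tissue = Tissue(params)
    PF, PI = _pack_params(params, thin=thin, record_all=record_events,
                          uncontrolled=uncontrolled)
    n_slots = params.n_slots
    S = np.zeros(K.S_N, dtype=np.int64)
    S[K.S_N_CELLS] = tissue.n_cells_total
    S[K.S_LIVING] = n_slots
    S[K.S_NEXT_ID] = tissue.next_cell_id
    T = np.zeros(K.T_N)
    U = rng.random(_RNG_BUFFER)
    DF = np.zeros(n_slots)
    LF = np.zeros(n_slots)
    scr = [np.zeros(tissue.capacity) for _ in range(3)]
    MEMB = np.zeros(tissue.capacity, dtype=np.int64)
    mut_t = np.zeros(_MUTLOG_CAP)
    mut_i = np.zeros((_MUTLOG_CAP, K.ML_COLS), dtype=np.int64)
    info_f = np.zeros(4)
    info_i = np.zeros(K.II_N, dtype=np.int64)
    event_log: list[tuple] = []
    mut_chunks_t: list[np.ndarray] = []
    mut_chunks_i: list[np.ndarray] = []
    endpoint = None
    init_mutator = None

    while endpoint is None:
        status = run_kernel(
            tissue.nbd, tissue.nbs, tissue.ndd, tissue.nds, tissue.mut,
            tissue.tsg, tissue.crypt_of, tissue.cell_id, tissue.birth_t,
            tissue.div_fit, tissue.loss_fit,
            tissue.crypt_counts, tissue.dead, tissue.dead_neighbors,
            tissue.nbr_flat, tissue.nbr_start,
            PF, PI, S, T, U,
            DF, LF, scr[0], scr[1], scr[2], MEMB,
            mut_t, mut_i, info_f, info_i)

        # drain the mutation-log buffer
        m = S[K.S_MUT_COUNT]
        drained = slice(0, m)
        if m:
            mut_chunks_t.append(mut_t[drained].copy())
            mut_chunks_i.append(mut_i[drained].copy())
            S[K.S_MUT_COUNT] = 0
        tissue.n_cells_total = int(S[K.S_N_CELLS])
        tissue.next_cell_id = int(S[K.S_NEXT_ID])
        tissue.living_crypt_count = int(S[K.S_LIVING])
        tissue.current_time = float(T[K.T_TIME])

        if status == K.REFILL:
            U[:] = rng.random(_RNG_BUFFER)
            S[K.S_BUF_POS] = 0
            continue
        if status == K.GROW:
            tissue.grow()
            scr = [np.zeros(tissue.capacity) for _ in range(3)]
            MEMB = np.zeros(tissue.capacity, dtype=np.int64)
            continue
        if status == K.MUTLOG_FULL:
            continue

        t_now = float(info_f[0])
        flags = int(info_i[K.II_FLAGS])
        if flags & K.FLAG_EXTINCTION or status == K.TISSUE_DEAD:
            tissue._register_extinction(int(info_i[K.II_EXTINCT_SLOT]), t_now)
        if flags & K.FLAG_BIFURCATION:
            tissue._register_birth(int(info_i[K.II_BIF_TARGET]),
                                   int(info_i[K.II_BIF_PARENT]), t_now)
        if record_events and status in (K.EVENT, K.INITIATION, K.TISSUE_DEAD,
                                        K.UNCONTROLLED):
            slot = int(info_i[K.II_SLOT])
            q, r = slot % params.grid_cols, slot // params.grid_cols
            if m and flags & K.FLAG_MUTATION:
                category = CATEGORIES[int(mut_chunks_i[-1][0, 0])]
            else:
                category = "-"
            event_log.append((t_now, _KIND_NAMES[int(info_i[K.II_KIND])],
                              q, r, int(info_i[K.II_CELL_ID]),
                              int(info_i[K.II_N_AFTER]), category,
                              int(info_i[K.II_TSG_AFTER])))

        if status == K.CENSORED:
            endpoint = "censored"
            endpoint_time = params.max_days
        elif status == K.INITIATION:
            endpoint = "initiation"
            endpoint_time = t_now
            init_mutator = bool(info_i[K.II_INIT_MUTATOR])
        elif status == K.TISSUE_DEAD:
            endpoint = "tissue_death"
            endpoint_time = t_now
        elif status == K.UNCONTROLLED:
            endpoint = "uncontrolled_proliferation"
            endpoint_time = t_now

    counters = {"sym": T[K.T_N_SYM], "asym": T[K.T_N_ASYM],
                "loss": T[K.T_N_LOSS], "general": T[K.T_N_GENERAL_MUT],
                "tsg": T[K.T_N_TSG_MUT]}
    integrals = {"cells": T[K.T_INT_CELLS], "per_crypt": T[K.T_INT_PER_CRYPT]}
    all_t = (np.concatenate(mut_chunks_t) if mut_chunks_t
             else np.empty(0))
    all_i = (np.concatenate(mut_chunks_i) if mut_chunks_i
             else np.empty((0, K.ML_COLS), dtype=np.int64))
    return _finalize(params, seed, tissue, endpoint, endpoint_time,
                     init_mutator, counters, integrals, event_log,
                     all_t, all_i)


# ----------------------------------------------------------------------
# pure Python reference path (public per-event operations)
# ----------------------------------------------------------------------

class Event(NamedTuple):
    """One scheduled event: absolute time, kind, and the affected cell."""

    time: float
    kind: str
    cell_id: int
    coordinate: tuple[int, int]
    cell_index: int
    #: True when drawn from the thinned asymmetric clock (mutation
    #: guaranteed at application).
    conditioned: bool = False


def cell_rate_arrays(tissue: Tissue, *, thin: bool = False
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-cell (symmetric, loss, asymmetric) clock rates."""
    p = tissue.params
    n = tissue.n_cells_total
    inv_dev = 0.0 if math.isinf(p.crypt_deviation) else 1.0 / p.crypt_deviation
    counts = tissue.crypt_counts.astype(float)
    deficit = np.maximum(0.0, p.crypt_size - counts)
    DF = np.where(deficit > 0, p.division_effect_base ** (deficit * inv_dev), 1.0)
    DF *= p.dead_neighbor_division_multiplier ** tissue.dead_neighbors
    excess = np.maximum(0.0, counts - p.crypt_size)
    LF = np.where((excess > 0) & (tissue.dead_neighbors == 0),
                  p.loss_effect_base ** (excess * inv_dev), 1.0)
    crypt = tissue.crypt_of[:n]
    s = p.base_division_rate * tissue.div_fit[:n] * DF[crypt]
    loss = p.base_loss_rate * tissue.loss_fit[:n] * LF[crypt]
    a = p.asym_to_sym_ratio * s
    if thin:
        g = np.where(tissue.mut[:n] == 1,
                     min(p.mutation_rate * p.mutator_factor, p.mutation_rate_max),
                     min(p.mutation_rate, p.mutation_rate_max))
        tau = np.where(tissue.mut[:n] == 1,
                       min(p.tsg_mutation_rate * p.mutator_factor,
                           p.tsg_mutation_rate_max),
                       min(p.tsg_mutation_rate, p.tsg_mutation_rate_max))
        a = a * (g + tau - g * tau)
    return s, loss, a


def next_event(tissue: Tissue, rng: np.random.Generator, *,
               thin_asymmetric: bool = False) -> Event:
    """Sample the next event by competing exponential clocks.

    Each cell runs three clocks at its current effective rates; waiting
    times are floored at the configured minimum times.  Returns the
    absolute event time.  Raises if the tissue has no living cells.
    """
    if tissue.n_cells_total < 1:
        raise ValueError("no living stem cells; tissue is dead")
    p = tissue.params
    s, loss, a = cell_rate_arrays(tissue, thin=thin_asymmetric)
    sums = (float(s.sum()), float(loss.sum()), float(a.sum()))
    floors = (p.division_min_time, p.loss_min_time, p.division_min_time)
    times = [max(rng.exponential(1.0 / R), f) if R > 0 else np.inf
             for R, f in zip(sums, floors)]
    k = int(np.argmin(times))
    # floored tie between the division kinds: rate-proportional choice
    if k == 0 and times[2] == times[0] and np.isfinite(times[0]):
        if rng.random() * (sums[0] + sums[2]) >= sums[0]:
            k = 2
    rates = (s, loss, a)[k]
    cum = np.cumsum(rates)
    i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    i = min(i, len(rates) - 1)
    kind = ("symmetric_division", "cell_loss", "asymmetric_division")[k]
    slot = int(tissue.crypt_of[i])
    return Event(time=tissue.current_time + times[k], kind=kind,
                 cell_id=int(tissue.cell_id[i]),
                 coordinate=slot_coordinate(slot, tissue.grid_rows,
                                            tissue.grid_cols),
                 cell_index=i,
                 conditioned=(k == 2 and thin_asymmetric))


def _mutate_opportunity(tissue: Tissue, i: int, rng: np.random.Generator,
                        t: float, *, conditioned: bool = False
                        ) -> list[MutationEvent]:
    """One mutation opportunity on the cell at flat index ``i``."""
    p = tissue.params
    factor = p.mutator_factor if tissue.mut[i] else 1.0
    g = min(p.mutation_rate * factor, p.mutation_rate_max)
    tau = min(p.tsg_mutation_rate * factor, p.tsg_mutation_rate_max)
    if conditioned:
        p_any = g + tau - g * tau
        u = rng.random() * p_any
        do_general = u < g
        do_tsg = not (u < g * (1.0 - tau))
    else:
        do_general = rng.random() < g
        do_tsg = rng.random() < tau
    out: list[MutationEvent] = []
    slot = int(tissue.crypt_of[i])
    coord = slot_coordinate(slot, tissue.grid_rows, tissue.grid_cols)
    if do_general:
        category = category_from_uniform(rng.random(), p)
        if category == "deleterious_div":
            tissue.ndd[i] += 1
        elif category == "deleterious_surv":
            tissue.nds[i] += 1
        elif category == "beneficial_div":
            tissue.nbd[i] += 1
        elif category == "beneficial_surv":
            tissue.nbs[i] += 1
        else:
            tissue.mut[i] = 1
        tissue.refresh_fitness_cache(i)
        out.append(MutationEvent(category, t, int(tissue.cell_id[i]), coord))
    if do_tsg:
        if tissue.tsg[i] < p.tsg_hits_for_initiation:
            tissue.tsg[i] += 1
        out.append(MutationEvent("tsg_hit", t, int(tissue.cell_id[i]), coord))
    return out


def apply_event(tissue: Tissue, event: Event, rng: np.random.Generator
                ) -> list[MutationEvent]:
    """Apply ``event`` to the tissue; returns the mutations it produced.

    Symmetric division replaces the cell by two daughters inheriting its
    state, each with one mutation opportunity, then checks crypt fission.
    Asymmetric division leaves the population unchanged but gives the
    retained stem cell one opportunity.  Loss removes the cell and marks
    the crypt extinct if emptied.  Raises on a stale event (the cell no
    longer exists at its index).
    """
    i = event.cell_index
    if i >= tissue.n_cells_total or int(tissue.cell_id[i]) != event.cell_id:
        raise ValueError(f"stale event: cell {event.cell_id} not at index {i}")
    tissue.current_time = event.time
    out: list[MutationEvent] = []
    if event.kind == "symmetric_division":
        j = tissue.append_daughter(i, event.time)
        for cell in (i, j):
            out.extend(_mutate_opportunity(tissue, cell, rng, event.time))
        tissue.try_bifurcate(event.coordinate, rng)
    elif event.kind == "cell_loss":
        slot = tissue.remove_cell(i)
        if tissue.crypt_counts[slot] == 0:
            tissue.mark_extinct(event.coordinate, event.time)
    elif event.kind == "asymmetric_division":
        out.extend(_mutate_opportunity(tissue, i, rng, event.time,
                                       conditioned=event.conditioned))
    else:  # pragma: no cover
        raise ValueError(event.kind)
    return out


def _run_python(params, seed, record_events, thin, uncontrolled) -> RunResult:
    rng = np.random.default_rng(seed)
    tissue = Tissue(params)
    counters = {"sym": 0, "asym": 0, "loss": 0, "general": 0, "tsg": 0}
    integrals = {"cells": 0.0, "per_crypt": 0.0}
    event_log: list[tuple] = []
    mut_t: list[float] = []
    mut_i: list[tuple] = []
    endpoint = None
    endpoint_time = params.max_days
    init_mutator = None
    from .dynamics import CATEGORY_CODE

    while endpoint is None:
        ev = next_event(tissue, rng, thin_asymmetric=thin)
        n_before = tissue.n_cells_total
        living = tissue.living_crypt_count
        dt_capped = min(ev.time, params.max_days) - tissue.current_time
        integrals["cells"] += n_before * dt_capped
        integrals["per_crypt"] += (n_before / living) * dt_capped
        if thin:
            s, _, a_thin = cell_rate_arrays(tissue, thin=True)
            lam = (params.asym_to_sym_ratio * float(s.sum())
                   - float(a_thin.sum())) * dt_capped
            counters["asym"] += int(rng.poisson(lam)) if lam > 0 else 0
        if ev.time >= params.max_days:
            tissue.current_time = params.max_days
            endpoint = "censored"
            endpoint_time = params.max_days
            break
        muts = apply_event(tissue, ev, rng)
        if ev.kind == "symmetric_division":
            counters["sym"] += 1
        elif ev.kind == "cell_loss":
            counters["loss"] += 1
        else:
            counters["asym"] += 1
        for mev in muts:
            if mev.category == "tsg_hit":
                counters["tsg"] += 1
            else:
                counters["general"] += 1
            idx = None
            try:
                idx = tissue.index_of_cell_id(mev.cell_id)
            except KeyError:  # pragma: no cover - cannot die same event
                pass
            tsg_after = int(tissue.tsg[idx]) if idx is not None else -1
            slot = (mev.crypt_coordinate[1] * params.grid_cols
                    + mev.crypt_coordinate[0])
            mut_t.append(mev.time)
            mut_i.append((CATEGORY_CODE[mev.category], mev.cell_id, slot,
                          tsg_after))
            if (mev.category == "tsg_hit" and idx is not None
                    and tissue.tsg[idx] >= params.tsg_hits_for_initiation):
                endpoint = "initiation"
                endpoint_time = ev.time
                init_mutator = bool(tissue.mut[idx])
        if record_events:
            slot = (ev.coordinate[1] * params.grid_cols + ev.coordinate[0])
            category = muts[0].category if muts else "-"
            n_after = int(tissue.crypt_counts[slot])
            try:
                idx = tissue.index_of_cell_id(ev.cell_id)
                tsg_after = int(tissue.tsg[idx])
            except KeyError:
                tsg_after = -1
            event_log.append((ev.time, ev.kind, ev.coordinate[0],
                              ev.coordinate[1], ev.cell_id, n_after,
                              category, tsg_after))
        if endpoint is not None:
            break
        if tissue.living_crypt_count == 0:
            endpoint = "tissue_death"
            endpoint_time = ev.time
        elif uncontrolled and (tissue.crypt_counts.max()
                               >= params.uncontrolled_threshold * params.crypt_size):
            endpoint = "uncontrolled_proliferation"
            endpoint_time = ev.time

    return _finalize(params, seed, tissue, endpoint, endpoint_time,
                     init_mutator, counters, integrals, event_log,
                     np.asarray(mut_t), np.asarray(mut_i, dtype=np.int64
                                                   ).reshape(-1, 4))


# ----------------------------------------------------------------------
# replicates
# ----------------------------------------------------------------------

def derive_seeds(base_seed: int, n: int) -> list[int]:
    """``n`` mutually distinct per-replicate seeds derived from one seed."""
    ss = np.random.SeedSequence(base_seed)
    need = n
    words = ss.generate_state(max(2 * n, 8), dtype=np.uint64) % (2 ** 31)
    out: list[int] = []
    seen: set[int] = set()
    k = len(words)
    while len(out) < need:
        for w in words:
            v = int(w)
            if v not in seen:
                seen.add(v)
                out.append(v)
                if len(out) == need:
                    break
        else:
            k *= 2
            words = ss.generate_state(k, dtype=np.uint64)[len(words):] % (2 ** 31)
            continue
        break
    return out


def run_replicates(params: SimulationParams, n_replicates: int,
                   base_seed: int, *, out_path=None, progress: bool = False,
                   **run_kwargs) -> list[RunResult]:
    """Independent replicates with derived, mutually distinct seeds.

    ``out_path`` streams one summary row per replicate to a CSV as runs
    complete.  Results are order-stable in the derived-seed order.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1 (got {n_replicates})")
    seeds = derive_seeds(base_seed, n_replicates)
    results: list[RunResult] = []
    fh = None
    if out_path is not None:
        fh = open(out_path, "w")
        fh.write(",".join(SUMMARY_COLUMNS) + "\n")
    try:
        for idx, s in enumerate(seeds):
            res = run(params, s, **run_kwargs)
            results.append(res)
            if fh is not None:
                row = res.summary_row()
                fh.write(",".join(str(row[c]) for c in SUMMARY_COLUMNS) + "\n")
                fh.flush()
            if progress:  # pragma: no cover - cosmetic
                print(f"replicate {idx + 1}/{n_replicates}: "
                      f"{res.endpoint} at {res.endpoint_time:.1f} d")
    finally:
        if fh is not None:
            fh.close()
    return results


def summary_frame(results: list[RunResult]) -> pd.DataFrame:
    """One row per replicate, in run order."""
    return pd.DataFrame([r.summary_row() for r in results],
                        columns=SUMMARY_COLUMNS)
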