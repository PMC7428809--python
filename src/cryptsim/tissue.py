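"""Tissue state: stem cells grouped into crypts on the hex lattice.

The tissue is stored struct-of-arrays for speed: one flat set of numpy
arrays holds every living stem cell (mutation counts, mutator flag, TSG
hits, crypt membership), densely packed in ``[0, n_cells_total)``.  Cell
removal swaps the last cell into the hole; order carries no meaning.
Crypt-level bookkeeping (per-slot population, dead flags, dead-neighbor
counts) is kept incrementally and can be recounted from scratch for
verification.  :class:`Crypt` objects carry slot metadata (coordinate,
lifetimes) and expose object views of their cells for analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import hexgrid
from .dynamics import StemCellState, fitness_multiplier
from .params import SimulationParams

__all__ = ["Crypt", "Tissue", "TurnoverRecord"]

#: Turnover log row: (event, time, q, r, parent_q, parent_r, created_time)
TurnoverRecord = tuple


@dataclass
class Crypt:
    """One lattice slot's current (or most recent) crypt."""

    coordinate: tuple[int, int]
    slot: int
    created_time: float
    alive: bool = True
    extinct_time: Optional[float] = None
    _tissue: "Tissue" = None  # back-reference, set by Tissue

    @property
    def n_cells(self) -> int:
        return 0 if not self.alive else int(self._tissue.crypt_counts[self.slot])

    @property
    def cells(self) -> list[StemCellState]:
        """Object views (copies) of this crypt's living stem cells."""
        return [self._tissue.cell_state(i) for i in self._tissue.crypt_cell_indices(self.slot)]

    @property
    def n_dead_neighbors(self) -> int:
        return int(self._tissue.dead_neighbors[self.slot])

    @property
    def mutator_fixed(self) -> bool:
        """True iff every living stem cell carries the mutator phenotype."""
        t = self._tissue
        idx = t.crypt_cell_indices(self.slot)
        return len(idx) > 0 and bool(t.mut[idx].all())


class Tissue:
    """Hexagonal grid of crypt slots plus the flat stem-cell arrays."""

    def __init__(self, params: SimulationParams):
        self.params = params
        self.grid_rows = params.grid_rows
        self.grid_cols = params.grid_cols
        self.n_slots = params.n_slots
        self.current_time = 0.0
        self.nbr_flat, self.nbr_start = hexgrid.neighbor_csr(
            params.grid_rows, params.grid_cols)

        n0 = self.n_slots * params.crypt_size
        cap = max(256, 2 * n0 + 64)
        self._alloc(cap)
        # Every slot starts with crypt_size unmutated cells at t = 0.
        self.n_cells_total = n0
        self.next_cell_id = n0
        self.cell_id[:n0] = np.arange(n0)
        for s in range(self.n_slots):
            self.crypt_of[s * params.crypt_size:(s + 1) * params.crypt_size] = s
        self.div_fit[:n0] = 1.0
        self.loss_fit[:n0] = 1.0

        self.crypt_counts = np.full(self.n_slots, params.crypt_size, dtype=np.int64)
        self.dead = np.zeros(self.n_slots, dtype=np.uint8)
        self.dead_neighbors = np.zeros(self.n_slots, dtype=np.int64)
        self.living_crypt_count = self.n_slots
        self.crypts: list[Crypt] = []
        for s in range(self.n_slots):
            c = Crypt(coordinate=hexgrid.slot_coordinate(s, self.grid_rows, self.grid_cols),
                      slot=s, created_time=0.0, _tissue=self)
            self.crypts.append(c)
        self.turnover_log: list[TurnoverRecord] = []

    def _alloc(self, cap: int) -> None:
        self.capacity = cap
        z = lambda dt: np.zeros(cap, dtype=dt)
        self.nbd, self.nbs = z(np.int32), z(np.int32)
        self.ndd, self.nds = z(np.int32), z(np.int32)
        self.mut = z(np.uint8)
        self.tsg = z(np.uint8)
        self.crypt_of = z(np.int64)
        self.cell_id = z(np.int64)
        self.birth_t = z(np.float64)
        self.div_fit = z(np.float64)
        self.loss_fit = z(np.float64)

    _CELL_ARRAYS = ("nbd", "nbs", "ndd", "nds", "mut", "tsg", "crypt_of",
                    "cell_id", "birth_t", "div_fit", "loss_fit")

    def grow(self) -> None:
        """Double the cell-array capacity, preserving contents."""
        old = {name: getattr(self, name) for name in self._CELL_ARRAYS}
        self._alloc(self.capacity * 2)
        for name, arr in old.items():
            getattr(self, name)[:len(arr)] = arr

    # ------------------------------------------------------------------
    # views and bookkeeping
    # ------------------------------------------------------------------
    @property
    def slots(self) -> dict[tuple[int, int], Crypt]:
        """Mapping coordinate -> current Crypt (dead slots keep the
        most recent extinct crypt, flagged ``alive=False``)."""
        return {c.coordinate: c for c in self.crypts}

    def crypt_cell_indices(self, slot: int) -> np.ndarray:
        n = self.n_cells_total
        return np.nonzero(self.crypt_of[:n] == slot)[0]

    def cell_state(self, i: int) -> StemCellState:
        """Object copy of the cell stored at flat index ``i``."""
        return StemCellState(
            n_beneficial_div=int(self.nbd[i]),
            n_beneficial_surv=int(self.nbs[i]),
            n_deleterious_div=int(self.ndd[i]),
            n_deleterious_surv=int(self.nds[i]),
            is_mutator=bool(self.mut[i]),
            tsg_hits=int(self.tsg[i]),
            unique_id=int(self.cell_id[i]),
            birth_time=float(self.birth_t[i]),
        )

    def index_of_cell_id(self, cell_id: int) -> int:
        n = self.n_cells_total
        hits = np.nonzero(self.cell_id[:n] == cell_id)[0]
        if len(hits) == 0:
            raise KeyError(f"no living cell with id {cell_id}")
        return int(hits[0])

    def refresh_fitness_cache(self, i: int) -> None:
        k = self.params.fitness_factor
        self.div_fit[i] = fitness_multiplier(int(self.nbd[i]), int(self.ndd[i]), k)
        self.loss_fit[i] = fitness_multiplier(int(self.nds[i]), int(self.nbs[i]), k)

    def recount_dead_neighbors(self) -> np.ndarray:
        """Dead-neighbor counts recomputed from scratch (for checks)."""
        out = np.zeros(self.n_slots, dtype=np.int64)
        for s in range(self.n_slots):
            nbrs = self.nbr_flat[self.nbr_start[s]:self.nbr_start[s + 1]]
            out[s] = int(self.dead[nbrs].sum())
        return out

    def _refresh_dead_neighbors(self) -> None:
        self.dead_neighbors[:] = self.recount_dead_neighbors()

    # ------------------------------------------------------------------
    # cell add/remove
    # ------------------------------------------------------------------
    def append_daughter(self, parent: int, t: float) -> int:
        """Append a copy of cell ``parent`` (symmetric division birth)."""
        if self.n_cells_total >= self.capacity:
            self.grow()
        j = self.n_cells_total
        for name in ("nbd", "nbs", "ndd", "nds", "mut", "tsg", "crypt_of",
                     "div_fit", "loss_fit"):
            getattr(self, name)[j] = getattr(self, name)[parent]
        self.cell_id[j] = self.next_cell_id
        self.birth_t[j] = t
        self.next_cell_id += 1
        self.n_cells_total += 1
        self.crypt_counts[self.crypt_of[j]] += 1
        return j

    def remove_cell(self, i: int) -> int:
        """Remove cell ``i`` (swap-with-last); returns its slot."""
        slot = int(self.crypt_of[i])
        last = self.n_cells_total - 1
        if i != last:
            for name in self._CELL_ARRAYS:
                arr = getattr(self, name)
                arr[i] = arr[last]
        self.n_cells_total = last
        self.crypt_counts[slot] -= 1
        return slot

    # ------------------------------------------------------------------
    # crypt lifecycle
    # ------------------------------------------------------------------
    def mark_extinct(self, coordinate: tuple[int, int], t: float) -> None:
        """Flag the emptied crypt at ``coordinate`` dead at time ``t``.

        Every living neighbor's dead-neighbor count rises by one
        (releasing its loss feedback); a crypt-lifespan record is
        appended to the turnover log.  Raises if the crypt still holds
        living cells.
        """
        slot = hexgrid.slot_index(coordinate, self.grid_rows, self.grid_cols)
        if self.crypt_counts[slot] != 0:
            raise ValueError(
                f"crypt at {coordinate} still has {self.crypt_counts[slot]} cells")
        if self.dead[slot]:
            raise ValueError(f"slot {coordinate} is already dead")
        self.dead[slot] = 1
        self.living_crypt_count -= 1
        self._refresh_dead_neighbors()
        self._register_extinction(slot, t)

    def _register_extinction(self, slot: int, t: float) -> None:
        crypt = self.crypts[slot]
        crypt.alive = False
        crypt.extinct_time = t
        q, r = crypt.coordinate
        self.turnover_log.append(
            ("crypt_death", t, q, r, None, None, crypt.created_time))

    def try_bifurcate(self, coordinate: tuple[int, int],
                      rng: np.random.Generator) -> Optional[tuple[int, int]]:
        """Fission the crypt at ``coordinate`` into an adjacent dead slot.

        Requires ``n_cells >= bifurcation_factor * crypt_size`` and at
        least one dead neighboring slot; otherwise no change.  A uniform
        random half (``floor(n/2)``) of the stem cells move, with their
        full mutation states, into a new crypt at a uniformly chosen
        dead neighbor.  Returns the new crypt's coordinate, or None.
        """
        p = self.params
        slot = hexgrid.slot_index(coordinate, self.grid_rows, self.grid_cols)
        if self.dead[slot]:
            raise ValueError(f"crypt at {coordinate} is not alive")
        n = int(self.crypt_counts[slot])
        if n < p.bifurcation_factor * p.crypt_size:
            return None
        nbrs = self.nbr_flat[self.nbr_start[slot]:self.nbr_start[slot + 1]]
        dead_nbrs = nbrs[self.dead[nbrs] == 1]
        if len(dead_nbrs) == 0:
            return None
        target = int(rng.choice(dead_nbrs))
        members = self.crypt_cell_indices(slot)
        movers = rng.choice(members, size=n // 2, replace=False)
        self.crypt_of[movers] = target
        self.crypt_counts[slot] -= len(movers)
        self.crypt_counts[target] += len(movers)
        self.dead[target] = 0
        self.living_crypt_count += 1
        self._refresh_dead_neighbors()
        self._register_birth(target, slot, self.current_time)
        return self.crypts[target].coordinate

    def _register_birth(self, slot: int, parent_slot: int, t: float) -> None:
        coord = hexgrid.slot_coordinate(slot, self.grid_rows, self.grid_cols)
        crypt = Crypt(coordinate=coord, slot=slot, created_time=t, _tissue=self)
        self.crypts[slot] = crypt
        pq, pr = self.crypts[parent_slot].coordinate
        q, r = coord
        self.turnover_log.append(("crypt_birth", t, q, r, pq, pr, t))

    # ------------------------------------------------------------------
    # summaries
    # ------------------------------------------------------------------
    def snapshot(self):
        """Per-living-crypt summary as a pandas DataFrame."""
        import pandas as pd

        p = self.params
        rows = []
        for crypt in self.crypts:
            if not crypt.alive:
                continue
            idx = self.crypt_cell_indices(crypt.slot)
            q, r = crypt.coordinate
            fit = (p.base_division_rate * self.div_fit[idx]
                   - p.base_loss_rate * self.loss_fit[idx])
            rows.append({
                "q": q, "r": r,
                "n_cells": len(idx),
                "mutator_fixed": bool(self.mut[idx].all()) and len(idx) > 0,
                "n_mutator_cells": int(self.mut[idx].sum()),
                "max_tsg_hits": int(self.tsg[idx].max()) if len(idx) else 0,
                "mean_beneficial_div": float(self.nbd[idx].mean()),
                "mean_beneficial_surv": float(self.nbs[idx].mean()),
                "mean_deleterious_div": float(self.ndd[idx].mean()),
                "mean_deleterious_surv": float(self.nds[idx].mean()),
                "mean_fitness": float(fit.mean()),
                "created_time": crypt.created_time,
            })
        return pd.DataFrame(
            rows, columns=["q", "r", "n_cells", "mutator_fixed",
                           "n_mutator_cells", "max_tsg_hits",
                           "mean_beneficial_div", "mean_beneficial_surv",
                           "mean_deleterious_div", "mean_deleterious_surv",
                           "mean_fitness", "created_time"])
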