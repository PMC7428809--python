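"""Per-cell rate laws, multiplicative fitness, and the mutation model.

A stem cell's behavior is a competition of exponential clocks: symmetric
division (birth), asymmetric division (no population change, one mutation
opportunity), and loss (death/differentiation).  Rates combine three
multiplicative ingredients:

* genotype: each beneficial mutation multiplies the affected rate by the
  fitness factor ``k`` (divisions up, loss down); each deleterious
  mutation applies the reciprocal;
* within-crypt homeostatic feedback: the division rate gains a factor
  ``division_effect_base ** ((crypt_size - n_cells) / crypt_deviation)``
  when the crypt is below target, and the loss rate the analogous factor
  when above target;
* between-crypt release: while a crypt borders >= 1 dead slot, its loss
  feedback is suppressed and its division rate gains one factor of
  ``dead_neighbor_division_multiplier`` per dead neighbor, letting it
  grow toward the fission threshold.

Mutations arrive per division opportunity: a general (fitness or mutator)
coin and an independent tumor-suppressor-gene coin, both capped, both
scaled ``mutator_factor``-fold in mutator cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import SimulationParams

__all__ = [
    "CellRates",
    "MutationEvent",
    "StemCellState",
    "CATEGORIES",
    "fitness_multiplier",
    "effective_rates",
    "cell_mutation_rate",
    "sample_mutation",
    "sample_loss_time",
]

#: Closed set of mutation-event categories, ordered by category code.
CATEGORIES = (
    "deleterious_div",
    "deleterious_surv",
    "beneficial_div",
    "beneficial_surv",
    "mutator",
    "tsg_hit",
)
CATEGORY_CODE = {name: i for i, name in enumerate(CATEGORIES)}


@dataclass
class StemCellState:
    """Mutational state of one stem cell; determines its rates."""

    n_beneficial_div: int = 0
    n_beneficial_surv: int = 0
    n_deleterious_div: int = 0
    n_deleterious_surv: int = 0
    is_mutator: bool = False
    tsg_hits: int = 0
    unique_id: int = 0
    birth_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_beneficial_div", "n_beneficial_surv",
                     "n_deleterious_div", "n_deleterious_surv", "tsg_hits"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer (got {v})")


@dataclass(frozen=True)
class CellRates:
    """Effective exponential-clock rates of one cell, per day."""

    symmetric_division_rate: float
    asymmetric_division_rate: float
    loss_rate: float


@dataclass(frozen=True)
class MutationEvent:
    """One mutation acquired at a division opportunity."""

    category: str
    time: float
    cell_id: int
    crypt_coordinate: tuple[int, int]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown mutation category {self.category!r}")


def fitness_multiplier(n_beneficial: int, n_deleterious: int,
                       k_fitness: float) -> float:
    """Multiplicative fitness of ``n`` beneficial and deleterious mutations.

    ``k_fitness ** n_beneficial * (1 / k_fitness) ** n_deleterious``; each
    mutation contributes one constant factor, so effects compose exactly.
    """
    if n_beneficial < 0 or n_deleterious < 0:
        raise ValueError("mutation counts must be non-negative")
    if n_beneficial != int(n_beneficial) or n_deleterious != int(n_deleterious):
        raise ValueError("mutation counts must be integers")
    if not k_fitness > 0:
        raise ValueError(f"k_fitness must be > 0 (got {k_fitness})")
    return k_fitness ** int(n_beneficial) * (1.0 / k_fitness) ** int(n_deleterious)


def division_feedback(n_cells: int, p: SimulationParams) -> float:
    """Division-rate multiplier when the crypt is below its target size."""
    deficit = max(0.0, p.crypt_size - n_cells)
    if deficit == 0.0:
        return 1.0
    return p.division_effect_base ** (deficit / p.crypt_deviation)


def loss_feedback(n_cells: int, n_dead_neighbors: int, p: SimulationParams) -> float:
    """Loss-rate multiplier when the crypt exceeds its target size.

    Suppressed entirely (multiplier 1) while any neighboring slot is dead:
    the vacancy releases the apoptotic signal so the crypt can expand.
    """
    if n_dead_neighbors > 0:
        return 1.0
    excess = max(0.0, n_cells - p.crypt_size)
    if excess == 0.0:
        return 1.0
    return p.loss_effect_base ** (excess / p.crypt_deviation)


def effective_rates(cell: StemCellState, n_cells: int, n_dead_neighbors: int,
                    p: SimulationParams) -> CellRates:
    """Current clock rates of ``cell`` in a crypt of ``n_cells`` members."""
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1 (got {n_cells})")
    if n_dead_neighbors < 0:
        raise ValueError(f"n_dead_neighbors must be >= 0 (got {n_dead_neighbors})")
    k = p.fitness_factor
    div_fit = fitness_multiplier(cell.n_beneficial_div, cell.n_deleterious_div, k)
    # Deleterious survival mutations raise the loss rate by k per hit;
    # beneficial survival mutations lower it by 1/k per hit.
    loss_fit = fitness_multiplier(cell.n_deleterious_surv, cell.n_beneficial_surv, k)
    sym = (p.base_division_rate * div_fit * division_feedback(n_cells, p)
           * p.dead_neighbor_division_multiplier ** n_dead_neighbors)
    loss = (p.base_loss_rate * loss_fit
            * loss_feedback(n_cells, n_dead_neighbors, p))
    return CellRates(
        symmetric_division_rate=sym,
        asymmetric_division_rate=p.asym_to_sym_ratio * sym,
        loss_rate=loss,
    )


def cell_mutation_rate(cell: StemCellState, p: SimulationParams) -> tuple[float, float]:
    """(general, TSG) mutation probabilities per division opportunity.

    Mutator cells have both rates scaled ``mutator_factor``-fold, each
    capped at its configured maximum.
    """
    factor = p.mutator_factor if cell.is_mutator else 1.0
    general = min(p.mutation_rate * factor, p.mutation_rate_max)
    tsg = min(p.tsg_mutation_rate * factor, p.tsg_mutation_rate_max)
    return general, tsg


def category_from_uniform(u: float, p: SimulationParams) -> str:
    """Map a uniform deviate to a general-mutation category.

    Deleterious with probability ``deleterious_fraction`` (then split
    between proliferation and survival), otherwise beneficial-branch
    (proliferation / survival / mutator split).
    """
    d = p.deleterious_fraction
    if u < d:
        return "deleterious_div" if u < d * p.deleterious_split[0] else "deleterious_surv"
    b = (u - d) / (1.0 - d) if d < 1.0 else 0.0
    if b < p.beneficial_split[0]:
        return "beneficial_div"
    if b < p.beneficial_split[0] + p.beneficial_split[1]:
        return "beneficial_surv"
    return "mutator"


def apply_category(cell: StemCellState, category: str) -> None:
    """Mutate ``cell`` in place according to a category label."""
    if category == "deleterious_div":
        cell.n_deleterious_div += 1
    elif category == "deleterious_surv":
        cell.n_deleterious_surv += 1
    elif category == "beneficial_div":
        cell.n_beneficial_div += 1
    elif category == "beneficial_surv":
        cell.n_beneficial_surv += 1
    elif category == "mutator":
        # A mutator mutation in an existing mutator has no further effect.
        cell.is_mutator = True
    elif category == "tsg_hit":
        cell.tsg_hits += 1
    else:  # pragma: no cover
        raise ValueError(category)


def sample_mutation(cell: StemCellState, p: SimulationParams,
                    rng: np.random.Generator, *, time: float = 0.0,
                    crypt_coordinate: tuple[int, int] = (0, 0),
                    ) -> list[MutationEvent]:
    """Draw the mutations acquired at one division opportunity.

    Two independent coins: a general fitness/mutator mutation with the
    cell's (capped) general rate, and a TSG hit with its (capped) TSG
    rate.  The cell state is updated in place; the emitted events record
    what happened (a mutator event on an existing mutator is still
    recorded, though it changes nothing).
    """
    general, tsg = cell_mutation_rate(cell, p)
    events: list[MutationEvent] = []
    if rng.random() < general:
        category = category_from_uniform(rng.random(), p)
        apply_category(cell, category)
        events.append(MutationEvent(category, time, cell.unique_id, crypt_coordinate))
    if rng.random() < tsg:
        apply_category(cell, "tsg_hit")
        events.append(MutationEvent("tsg_hit", time, cell.unique_id, crypt_coordinate))
    return events


def sample_loss_time(loss_rate_background: float, loss_rate_feedback: float,
                     rng: np.random.Generator, *, min_time: float = 0.0) -> float:
    """Minimum of two competing exponential loss clocks, floored.

    Equivalent in distribution to a single exponential with the summed
    rate.  Returns +inf when both rates are zero (no event).
    """
    if loss_rate_background < 0 or loss_rate_feedback < 0:
        raise ValueError("loss rates must be >= 0")
    total = loss_rate_background + loss_rate_feedback
    if total == 0.0:
        return float("inf")
    t1 = rng.exponential(1.0 / loss_rate_background) if loss_rate_background > 0 else float("inf")
    t2 = rng.exponential(1.0 / loss_rate_feedback) if loss_rate_feedback > 0 else float("inf")
    return max(min(t1, t2), min_time)
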