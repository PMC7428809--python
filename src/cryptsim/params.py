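"""Model parameters, validation, and config I/O.

The parameter set mirrors the baseline table of the crypt metapopulation
model: per-cell birth/death rates, homeostatic feedback constants, the
mutation model (general and tumor-suppressor-gene rates with caps, the
mutator multiplier), crypt fission constants, and the lattice dimensions.
All downstream modules consume a single frozen :class:`SimulationParams`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "SimulationParams",
    "RunSettings",
    "load_params",
    "load_config",
    "serialize_params",
    "validate_params",
    "ParamError",
]

#: Keys allowed in a config document beyond SimulationParams fields.
RUN_KEYS = ("replicates", "seed", "out_dir")

_SPLIT_TOL = 1e-12


class ParamError(ValueError):
    """Raised for unparseable or out-of-range configuration input."""


@dataclass(frozen=True)
class SimulationParams:
    """Complete parameterization of one simulation condition.

    Rates are per cell per day; times are days; probabilities are per
    stem-cell division (one "opportunity").
    """

    #: Maximum simulated duration in days (80 years).
    max_days: float = 29220.0
    #: Symmetric (self-renewing) division rate per stem cell per day.
    base_division_rate: float = 0.05
    #: Asymmetric divisions occur at this multiple of the symmetric rate.
    asym_to_sym_ratio: float = 20.0
    #: Background stem-cell loss (death/differentiation) rate per day.
    base_loss_rate: float = 0.04878
    #: General (fitness/mutator) mutation probability per division.
    mutation_rate: float = 5e-4
    #: Cap on the general mutation probability (binds for mutators).
    mutation_rate_max: float = 5e-2
    #: Tumor-suppressor-gene hit probability per division.
    tsg_mutation_rate: float = 5e-7
    #: Cap on the TSG hit probability.
    tsg_mutation_rate_max: float = 5e-5
    #: Fold increase of both mutation rates in a mutator cell.
    mutator_factor: float = 100.0
    #: Transient-amplifying cells per stem cell (reporting only; the TA
    #: compartment is implicit and contributes no dynamics or mutations).
    ta_cells_per_stem: int = 2048
    #: Floor on sampled division waiting times, days.
    division_min_time: float = 0.05
    #: Floor on sampled loss waiting times, days.
    loss_min_time: float = 0.0
    #: Homeostatic target number of stem cells per crypt.
    crypt_size: int = 10
    #: Scale of the feedback response (divides the deviation exponent).
    crypt_deviation: float = 2.0
    #: A crypt fissions once it holds this multiple of crypt_size cells.
    bifurcation_factor: float = 2.0
    #: Base of the loss-feedback exponent (cells above target).
    loss_effect_base: float = 2.0
    #: Base of the division-feedback exponent (cells below target).
    division_effect_base: float = 2.0
    #: Division-rate multiplier applied once per dead neighboring crypt.
    dead_neighbor_division_multiplier: float = 2.0
    #: Crypts at this multiple of crypt_size count as uncontrolled growth.
    uncontrolled_threshold: float = 4.0
    #: TSG hits in one cell that constitute tumor initiation.
    tsg_hits_for_initiation: int = 2
    #: Proportion of non-neutral mutations that are deleterious.
    deleterious_fraction: float = 0.5
    #: Split of beneficial mutations into (proliferation, survival, mutator).
    beneficial_split: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: Split of deleterious mutations into (proliferation, survival).
    deleterious_split: tuple[float, float] = (0.5, 0.5)
    #: Multiplicative fitness effect of one beneficial mutation; a
    #: deleterious mutation applies the reciprocal 1/fitness_factor.
    fitness_factor: float = 1.01
    #: Lattice dimensions (axial-parallelogram hex grid).
    grid_rows: int = 5
    grid_cols: int = 5

    def __post_init__(self) -> None:
        violations = validate_params(self)
        if violations:
            raise ParamError("; ".join(violations))

    @property
    def deleterious_factor(self) -> float:
        """Reciprocal fitness effect of one deleterious mutation.

        Always derived as 1/fitness_factor so the two can never disagree.
        """
        return 1.0 / self.fitness_factor

    @property
    def n_slots(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def total_stem_cells(self) -> int:
        """Initial (homeostatic) stem-cell count of the whole tissue."""
        return self.n_slots * self.crypt_size

    def replace(self, **changes: Any) -> "SimulationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class RunSettings:
    """Run-level settings that accompany params in a config file."""

    replicates: int = 1
    seed: int = 0
    out_dir: str | None = None


def _nonneg(name: str, v: float, out: list[str]) -> None:
    if not math.isfinite(v):
        out.append(f"{name} must be finite (got {v})")
    elif v < 0:
        out.append(f"{name} must be >= 0 (got {v})")


def _prob(name: str, v: float, out: list[str]) -> None:
    if not 0.0 <= v <= 1.0:
        out.append(f"{name} must be in [0, 1] (got {v})")


def validate_params(p: SimulationParams) -> list[str]:
    """Return a list of invariant violations (empty iff params are valid).

    Violations are returned, never raised, so callers can report them all.
    """
    out: list[str] = []
    for name in (
        "max_days",
        "base_division_rate",
        "asym_to_sym_ratio",
        "base_loss_rate",
        "mutator_factor",
        "division_min_time",
        "loss_min_time",
        "bifurcation_factor",
        "loss_effect_base",
        "division_effect_base",
        "dead_neighbor_division_multiplier",
        "uncontrolled_threshold",
    ):
        _nonneg(name, getattr(p, name), out)
    # crypt_deviation may be +inf (disables feedback) but not <= 0.
    if not p.crypt_deviation > 0:
        out.append(f"crypt_deviation must be > 0 (got {p.crypt_deviation})")
    for name in (
        "mutation_rate",
        "mutation_rate_max",
        "tsg_mutation_rate",
        "tsg_mutation_rate_max",
        "deleterious_fraction",
    ):
        _prob(name, getattr(p, name), out)
    if p.mutator_factor < 1.0:
        out.append(
            f"mutator_factor must be >= 1 so it never lowers the mutation "
            f"rate (got {p.mutator_factor})"
        )
    if not p.fitness_factor > 0:
        out.append(f"fitness_factor must be > 0 (got {p.fitness_factor})")
    if p.crypt_size < 1:
        out.append(f"crypt_size must be >= 1 (got {p.crypt_size})")
    if p.ta_cells_per_stem < 0:
        out.append(f"ta_cells_per_stem must be >= 0 (got {p.ta_cells_per_stem})")
    if p.tsg_hits_for_initiation < 1:
        out.append(
            f"tsg_hits_for_initiation must be >= 1 (got {p.tsg_hits_for_initiation})"
        )
    if p.grid_rows < 1 or p.grid_cols < 1:
        out.append(
            f"grid_rows x grid_cols must be >= 1 (got {p.grid_rows}x{p.grid_cols})"
        )
    for name, n_parts in (("beneficial_split", 3), ("deleterious_split", 2)):
        split = getattr(p, name)
        if len(split) != n_parts:
            out.append(f"{name} must have {n_parts} entries (got {len(split)})")
            continue
        if any(x < 0 for x in split):
            out.append(f"{name} entries must be >= 0 (got {split})")
        if abs(sum(split) - 1.0) > _SPLIT_TOL:
            out.append(f"{name} must sum to 1 within {_SPLIT_TOL} (got sum {sum(split)})")
    return out


_INT_FIELDS = {"ta_cells_per_stem", "crypt_size", "tsg_hits_for_initiation",
               "grid_rows", "grid_cols"}
_TUPLE_FIELDS = {"beneficial_split", "deleterious_split"}
_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}


def _coerce(key: str, value: Any) -> Any:
    if key in _TUPLE_FIELDS:
        if not isinstance(value, (list, tuple)):
            raise ParamError(f"{key} must be a list of proportions (got {value!r})")
        return tuple(float(v) for v in value)
    if key in _INT_FIELDS:
        iv = int(value)
        if iv != value:
            raise ParamError(f"{key} must be an integer (got {value!r})")
        return iv
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ParamError(f"{key} must be numeric (got {value!r})")
    return float(value)


def load_config(config_text: str) -> tuple[SimulationParams, RunSettings]:
    """Parse a flat YAML key-value document into params and run settings.

    Unknown keys are rejected; unspecified keys take the baseline defaults.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ParamError(f"config does not parse as YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ParamError("config must be a flat key-value mapping")
    unknown = sorted(set(doc) - _PARAM_FIELDS - set(RUN_KEYS))
    if unknown:
        raise ParamError(f"unknown config keys: {', '.join(unknown)}")
    run_kwargs: dict[str, Any] = {}
    if "replicates" in doc:
        run_kwargs["replicates"] = int(doc["replicates"])
    if "seed" in doc:
        run_kwargs["seed"] = int(doc["seed"])
    if "out_dir" in doc and doc["out_dir"] is not None:
        run_kwargs["out_dir"] = str(doc["out_dir"])
    kwargs = {k: _coerce(k, v) for k, v in doc.items() if k in _PARAM_FIELDS}
    try:
        params = SimulationParams(**kwargs)
    except ParamError:
        raise
    return params, RunSettings(**run_kwargs)


def load_params(config_text: str) -> SimulationParams:
    """Parse a flat YAML document into :class:`SimulationParams`."""
    return load_config(config_text)[0]


def serialize_params(p: SimulationParams) -> str:
    """Serialize params to YAML such that load_params round-trips exactly."""
    doc = {}
    for f in dataclasses.fields(SimulationParams):
        v = getattr(p, f.name)
        if isinstance(v, tuple):
            v = list(v)
        doc[f.name] = v
    return yaml.safe_dump(doc, sort_keys=True)


def provenance_header(p: SimulationParams, prefix: str = "# ") -> str:
    """Params serialized as comment lines for embedding in output files."""
    body = serialize_params(p).rstrip("\n").replace("\n", f"\n{prefix}")
    return f"{prefix}{body}\n"
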