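"""Reaction-network data model for discrete-state stochastic kinetics.

A :class:`ModelSpec` is a closed description of a continuous-time Markov
jump process: integer molecule counts per species, reactions with one of a
small vocabulary of hazard (propensity) laws, and optional time-triggered
events that reset species counts or rate parameters mid-simulation (used for
in-silico interventions such as an antibody bolus).

Hazard kinds
------------
``zeroth_order``
    constant rate ``k`` (production from a constant source).
``first_order``
    ``k * n`` for a single reactant with count ``n``.
``second_order_homodimer``
    ``k * n * (n - 1) / 2`` — collision of two identical molecules.
``second_order_hetero``
    ``k * n_a * n_b`` — collision of two distinct species.
``hill_growth``
    ``k * n * m**2 / (h**2 + m**2)`` — saturating aggregate growth, where
    ``n`` is the count of the building block, ``m`` the aggregate size and
    ``h`` the half-saturation size.  Growth is impossible while ``m == 0``.
``first_order_scaled_by_species``
    ``k * n * m / m0`` — first-order decay whose effective rate constant is
    modulated by a second species ``m`` normalised to a reference count
    ``m0`` (enzyme-coupled clearance).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence


class HazardKind(str, enum.Enum):
    ZEROTH_ORDER = "zeroth_order"
    FIRST_ORDER = "first_order"
    SECOND_ORDER_HOMODIMER = "second_order_homodimer"
    SECOND_ORDER_HETERO = "second_order_hetero"
    HILL_GROWTH = "hill_growth"
    FIRST_ORDER_SCALED = "first_order_scaled_by_species"


class ConfigurationError(ValueError):
    """A model specification is internally inconsistent."""


class StateCorruptionError(RuntimeError):
    """A species count became negative (should never happen for a valid spec)."""


@dataclass(frozen=True)
class SpeciesState:
    """One molecular species and its initial copy number.

    ``constant`` species (the Source/Sink bookkeeping pools) never change
    count when reactions fire.
    """

    name: str
    count: int = 0
    constant: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigurationError(f"species {self.name!r} has negative count")


class ParameterSet(dict):
    """Mapping of rate-parameter name to value (SI units, seconds-based).

    A thin ``dict`` subclass so parameter sets serialise naturally; units for
    the standard amyloid parameters are recorded in :data:`PARAMETER_UNITS`.
    """

    def updated(self, **changes: float) -> "ParameterSet":
        new = ParameterSet(self)
        new.update(changes)
        return new


#: Units of the standard parameter vocabulary (documentation, not enforced).
PARAMETER_UNITS: Mapping[str, str] = {
    "k_prod": "molecules s^-1",
    "k_deg": "s^-1",
    "k_dimer": "molecules^-1 s^-1",
    "k_dedimer": "s^-1",
    "k_pf": "molecules^-1 s^-1",
    "k_pg": "s^-1",
    "k_pghalf": "molecules",
    "k_disagg": "s^-1",
    "k_degNep": "s^-1",
    "Nep0": "molecules",
    "k_binantiAbDim": "molecules^-1 s^-1",
    "k_binantiAbMon": "molecules^-1 s^-1",
    "k_prodantiAb": "molecules s^-1",
}


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    ``reactants``/``products`` map species name to (non-negative) stoichiometry.
    ``rate_param`` names the rate constant in the model's :class:`ParameterSet`.
    ``modifier`` is the second species entering the hazard for the Hill and
    enzyme-scaled kinds (and the second collision partner for
    ``second_order_hetero`` when it is not listed as a reactant).
    ``aux_param`` names the auxiliary constant (half-saturation size for
    ``hill_growth``, reference count for ``first_order_scaled_by_species``).
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kind: HazardKind
    rate_param: str
    modifier: str | None = None
    aux_param: str | None = None

    def net_change(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for sp, n in self.products.items():
            delta[sp] = delta.get(sp, 0) + n
        for sp, n in self.reactants.items():
            delta[sp] = delta.get(sp, 0) - n
        return delta


@dataclass(frozen=True)
class TimedEvent:
    """Assignments applied atomically when simulated time crosses ``time`` (s)."""

    time: float
    species_assignments: Mapping[str, int] = field(default_factory=dict)
    parameter_assignments: Mapping[str, float] = field(default_factory=dict)


@dataclass
class ModelSpec:
    """Complete specification of one stochastic model variant."""

    name: str
    species: Sequence[SpeciesState]
    parameters: ParameterSet
    reactions: Sequence[Reaction]
    events: Sequence[TimedEvent] = field(default_factory=tuple)
    plaque_threshold: int = 30
    variant: str = ""

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        self.events = tuple(sorted(self.events, key=lambda e: e.time))
        self.parameters = ParameterSet(self.parameters)

    # -- lookup helpers -------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def get_species(self, name: str) -> SpeciesState:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def initial_state(self) -> dict[str, int]:
        return {s.name: s.count for s in self.species}

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- derived copies -------------------------------------------------
    def with_parameters(self, **changes: float) -> "ModelSpec":
        return replace(self, parameters=self.parameters.updated(**changes))

    def with_initial_count(self, species: str, count: int) -> "ModelSpec":
        new = tuple(
            replace(s, count=count) if s.name == species else s for s in self.species
        )
        if species not in self.species_names:
            raise KeyError(species)
        return replace(self, species=new)


def hazard(
    reaction: Reaction,
    state: Mapping[str, int],
    params: Mapping[str, float],
) -> float:
    """Instantaneous stochastic rate (s^-1) of ``reaction`` in ``state``.

    This is the reference (pure-Python) evaluation; the simulation engine
    compiles the same laws to machine code and is cross-checked against this
    function in the test suite.
    """
    for sp, n in reaction.reactants.items():
        c = state[sp]
        if c < 0:
            raise StateCorruptionError(f"negative count for {sp!r}: {c}")
        if c < n:
            return 0.0
    k = params[reaction.rate_param]
    kind = reaction.kind
    if kind is HazardKind.ZEROTH_ORDER:
        return k
    if kind is HazardKind.FIRST_ORDER:
        (sp,) = reaction.reactants
        return k * state[sp]
    if kind is HazardKind.SECOND_ORDER_HOMODIMER:
        (sp,) = reaction.reactants
        n = state[sp]
        return k * n * (n - 1) * 0.5
    if kind is HazardKind.SECOND_ORDER_HETERO:
        names = list(reaction.reactants)
        if len(names) == 1 and reaction.modifier is not None:
            names.append(reaction.modifier)
        a, b = names
        return k * state[a] * state[b]
    if kind is HazardKind.HILL_GROWTH:
        (sp,) = reaction.reactants
        m = state[reaction.modifier]
        if m < 0:
            raise StateCorruptionError(f"negative count for {reaction.modifier!r}")
        h = params[reaction.aux_param]
        return k * state[sp] * m * m / (h * h + m * m) if m > 0 else 0.0
    if kind is HazardKind.FIRST_ORDER_SCALED:
        (sp,) = reaction.reactants
        m = state[reaction.modifier]
        if m < 0:
            raise StateCorruptionError(f"negative count for {reaction.modifier!r}")
        m0 = params[reaction.aux_param]
        return k * state[sp] * m / m0
    raise ConfigurationError(f"unknown hazard kind {kind!r}")


def validate(spec: ModelSpec) -> list[str]:
    """Return a list of human-readable violations (empty iff the spec is sound).

    Checks reference resolution, stoichiometry and rate signs, and event
    ordering/targets.  Violations are returned rather than raised so callers
    can report them all at once.
    """
    problems: list[str] = []
    names = set(spec.species_names)
    if len(names) != len(spec.species):
        problems.append("duplicate species names")
    if spec.plaque_threshold <= 0:
        problems.append("plaque_threshold must be positive")
    for pname, value in spec.parameters.items():
        if not math.isfinite(value) or value < 0:
            problems.append(f"parameter {pname} is negative or non-finite: {value}")
    seen_rids: set[str] = set()
    for r in spec.reactions:
        if r.id in seen_rids:
            problems.append(f"duplicate reaction id {r.id}")
        seen_rids.add(r.id)
        for sp, n in {**r.reactants, **r.products}.items():
            if sp not in names:
                problems.append(f"reaction {r.id}: unknown species {sp!r}")
            if n < 0:
                problems.append(f"reaction {r.id}: negative stoichiometry for {sp}")
        if r.modifier is not None and r.modifier not in names:
            problems.append(f"reaction {r.id}: unknown modifier {r.modifier!r}")
        if r.rate_param not in spec.parameters:
            problems.append(f"reaction {r.id}: unknown rate parameter {r.rate_param!r}")
        if r.kind in (HazardKind.HILL_GROWTH, HazardKind.FIRST_ORDER_SCALED):
            if r.modifier is None:
                problems.append(f"reaction {r.id}: {r.kind.value} requires a modifier")
            if r.aux_param is None or r.aux_param not in spec.parameters:
                problems.append(
                    f"reaction {r.id}: {r.kind.value} requires a known aux_param"
                )
    prev = -math.inf
    for ev in spec.events:
        if ev.time < 0:
            problems.append(f"event at t={ev.time}: negative trigger time")
        if ev.time < prev:
            problems.append("events not time-ordered")  # pragma: no cover - sorted in init
        prev = ev.time
        for sp in ev.species_assignments:
            if sp not in names:
                problems.append(f"event at t={ev.time}: unknown species {sp!r}")
        for p in ev.parameter_assignments:
            if p not in spec.parameters:
                problems.append(f"event at t={ev.time}: unknown parameter {p!r}")
    return problems
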