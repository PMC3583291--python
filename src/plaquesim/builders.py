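"""Constructors for the three amyloid-beta turnover/aggregation models.

Model 1 is a bare immigration-death process for the free Abeta monomer pool
near one brain cell (production from APP processing, first-order clearance).
Model 2 adds reversible dimerisation, nucleation of an aggregate from two
dimers, saturating (Hill) aggregate growth by monomer addition, first-order
disaggregation, and an optional neprilysin-coupled clearance whose effective
rate declines with age as the enzyme pool decays.  Model 3 is Model 2 with
aggregate growth and disaggregation routed through dimers instead of
monomers.

Default parameter values are the published calibration for Model 2; the
dimer-growth variant was never published with its own fitted values, so it
reuses the same set (every value can be overridden).
"""

from __future__ import annotations

from .model import (
    ConfigurationError,
    HazardKind,
    ModelSpec,
    ParameterSet,
    Reaction,
    SpeciesState,
)

#: Normal (efficient) first-order clearance rate of Abeta monomers, s^-1.
K_DEG_NORMAL = 2.1e-5
#: Clearance rate measured in Alzheimer's disease patients, s^-1.
K_DEG_AD = 1.5e-5

#: Calibrated rate constants for the aggregation model (Model 2).
MODEL2_DEFAULTS = ParameterSet(
    k_prod=1.86e-5,
    k_deg=K_DEG_NORMAL,
    k_dimer=1.2e-7,
    k_dedimer=8.5e-6,
    k_pf=2.8e-6,
    k_pg=5.7e-3,
    k_pghalf=4.0,
    k_disagg=5.4e-5,
    k_degNep=0.0,
    Nep0=1000.0,
)

#: Neprilysin decay rate giving ~30% enzyme loss by age 60 (declining variant).
K_DEGNEP_DECLINING = 1.8e-10

MODEL2_VARIANTS = ("normal", "constant_impaired", "declining")


def build_model1(k_deg: float = K_DEG_NORMAL, k_prod: float = 1.86e-5) -> ModelSpec:
    """Monomer turnover only: Source -> Abeta -> Sink.

    The stationary law of the resulting process is Poisson(k_prod/k_deg).
    Initial local monomer count is 1.
    """
    if k_deg <= 0 or k_prod <= 0:
        raise ConfigurationError("rates for the turnover model must be positive")
    species = (
        SpeciesState("Abeta", 1),
        SpeciesState("Source", 1, constant=True),
        SpeciesState("Sink", 0, constant=True),
    )
    reactions = (
        Reaction(
            "AbetaProduction", {"Source": 1}, {"Source": 1, "Abeta": 1},
            HazardKind.ZEROTH_ORDER, "k_prod",
        ),
        Reaction(
            "AbetaDegradation", {"Abeta": 1}, {"Sink": 1},
            HazardKind.FIRST_ORDER, "k_deg",
        ),
    )
    return ModelSpec(
        name="model1",
        species=species,
        parameters=ParameterSet(k_prod=k_prod, k_deg=k_deg),
        reactions=reactions,
        variant="normal" if abs(k_deg - K_DEG_NORMAL) < 1e-12 else "custom",
    )


def _aggregation_reactions(degradation: Reaction, growth: Reaction,
                           disagg: Reaction) -> tuple[Reaction, ...]:
    return (
        Reaction(
            "AbetaProduction", {"Source": 1}, {"Source": 1, "Abeta": 1},
            HazardKind.ZEROTH_ORDER, "k_prod",
        ),
        degradation,
        Reaction(
            "Dimerisation", {"Abeta": 2}, {"AbDim": 1},
            HazardKind.SECOND_ORDER_HOMODIMER, "k_dimer",
        ),
        Reaction(
            "Dedimerisation", {"AbDim": 1}, {"Abeta": 2},
            HazardKind.FIRST_ORDER, "k_dedimer",
        ),
        # Nucleation of a new aggregate from two dimers.  AbP counts the
        # monomer units held in aggregates, so the nascent aggregate has
        # size 4 (mass-conserving).
        Reaction(
            "PlaqueFormation", {"AbDim": 2}, {"AbP": 4},
            HazardKind.SECOND_ORDER_HOMODIMER, "k_pf",
        ),
        growth,
        disagg,
        Reaction(
            "NeprilysinDegradation", {"Nep": 1}, {"Sink": 1},
            HazardKind.FIRST_ORDER, "k_degNep",
        ),
    )


def _model2_species() -> tuple[SpeciesState, ...]:
    return (
        SpeciesState("Abeta", 0),
        SpeciesState("AbDim", 0),
        SpeciesState("AbP", 0),
        SpeciesState("Nep", 1000),
        SpeciesState("Source", 1, constant=True),
        SpeciesState("Sink", 0, constant=True),
    )


def _degradation_for_variant(variant: str) -> tuple[Reaction, ParameterSet]:
    """Clearance reaction and parameter overrides for a Model 2/3 variant."""
    params = ParameterSet(MODEL2_DEFAULTS)
    if variant == "normal":
        degradation = Reaction(
            "AbetaDegradation", {"Abeta": 1}, {"Sink": 1},
            HazardKind.FIRST_ORDER, "k_deg",
        )
    elif variant == "constant_impaired":
        degradation = Reaction(
            "AbetaDegradation", {"Abeta": 1}, {"Sink": 1},
            HazardKind.FIRST_ORDER, "k_deg",
        )
        params["k_deg"] = K_DEG_AD
    elif variant == "declining":
        # Effective clearance k_deg * Nep/Nep0 starts at the normal rate and
        # decays with the enzyme pool, reaching the AD-like rate around age 60.
        degradation = Reaction(
            "AbetaDegradation", {"Abeta": 1}, {"Sink": 1},
            HazardKind.FIRST_ORDER_SCALED, "k_deg",
            modifier="Nep", aux_param="Nep0",
        )
        params["k_degNep"] = K_DEGNEP_DECLINING
    else:
        raise ConfigurationError(
            f"unknown variant {variant!r}; expected one of {MODEL2_VARIANTS}"
        )
    return degradation, params


def build_model2(variant: str = "normal", **overrides: float) -> ModelSpec:
    """Full aggregation network (8 reactions) with monomer-mediated growth."""
    degradation, params = _degradation_for_variant(variant)
    growth = Reaction(
        "PlaqueGrowth", {"Abeta": 1}, {"AbP": 1},
        HazardKind.HILL_GROWTH, "k_pg", modifier="AbP", aux_param="k_pghalf",
    )
    disagg = Reaction(
        "Disaggregation", {"AbP": 1}, {"Abeta": 1},
        HazardKind.FIRST_ORDER, "k_disagg",
    )
    params.update(overrides)
    return ModelSpec(
        name="model2",
        species=_model2_species(),
        parameters=params,
        reactions=_aggregation_reactions(degradation, growth, disagg),
        variant=variant,
    )


def build_model3(variant: str = "declining", **overrides: float) -> ModelSpec:
    """Aggregation network with dimer-mediated growth and disaggregation.

    Aggregates grow by addition of dimers (hazard k_pg * AbDim * Hill(AbP),
    +2 monomer units per firing) and disaggregation releases dimers (-2
    units).  Aggregate size stays even, so the two-unit disaggregation step
    never underflows.  No published parameter set exists for this variant;
    the Model 2 defaults are reused and fully overridable.
    """
    degradation, params = _degradation_for_variant(variant)
    growth = Reaction(
        "PlaqueGrowth", {"AbDim": 1}, {"AbP": 2},
        HazardKind.HILL_GROWTH, "k_pg", modifier="AbP", aux_param="k_pghalf",
    )
    disagg = Reaction(
        "Disaggregation", {"AbP": 2}, {"AbDim": 1},
        HazardKind.FIRST_ORDER, "k_disagg",
    )
    missing = [k for k in overrides if k not in params]
    if missing:
        raise ConfigurationError(f"unknown parameters: {missing}")
    params.update(overrides)
    return ModelSpec(
        name="model3",
        species=_model2_species(),
        parameters=params,
        reactions=_aggregation_reactions(degradation, growth, disagg),
        variant=variant,
    )
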