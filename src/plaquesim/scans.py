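"""Single-parameter scans and the Latin-hypercube global calibration scan.

``scan_parameter`` reruns an ensemble for each value of one rate constant and
summarises plaque outcomes (prevalence at a reference age with its 95% band,
median lag time, mean final plaque size).  ``lhs_sample`` draws stratified
parameter sets for the global scan, and ``global_scan_filter`` applies the
two-stage elimination used to calibrate the aggregation model: candidate
sets must produce few plaque-bearing cells under normal clearance but an
appreciable, late-onset plaque burden once clearance declines with age.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from .analysis import (
    ensemble_plaque_metrics,
    prevalence_ci_half_width,
    prevalence_curve,
)
from .builders import MODEL2_DEFAULTS
from .engine import simulate_ensemble
from .model import ModelSpec, ParameterSet
from .units import YEAR_SECONDS

__all__ = [
    "ScanPoint",
    "ScanResult",
    "scan_parameter",
    "LhsDesign",
    "lhs_sample",
    "FilterDecision",
    "GlobalScanResult",
    "global_scan_filter",
    "stage1_rule",
    "stage2_rule",
]


def _derive_seed(base_seed: int, *tokens: object) -> int:
    """Deterministic sub-seed from a root seed and arbitrary labels.

    Seeds depend on (base_seed, label) only — never on the position of a
    value within a scan — so scan results are invariant to scan order.
    """
    h = zlib.crc32(repr(tokens).encode())
    return int(np.random.SeedSequence([int(base_seed), h]).generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class ScanPoint:
    value: float
    prevalence: float  # % of cells associated with plaques at the reference age
    ci_half_width: float
    median_lag_years: float | None  # over plaque-bearing cells
    mean_final_size: float | None  # over plaque-bearing cells
    n_cells: int
    seed: int


@dataclass
class ScanResult:
    parameter: str
    points: list[ScanPoint]
    reference_age_years: float
    base_seed: int

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])

    @property
    def prevalences(self) -> np.ndarray:
        return np.array([p.prevalence for p in self.points])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "parameter": self.parameter,
                    "value": p.value,
                    "prevalence_percent": p.prevalence,
                    "ci_half_width": p.ci_half_width,
                    "median_lag_years": p.median_lag_years,
                    "mean_final_size": p.mean_final_size,
                    "n_cells": p.n_cells,
                    "seed": p.seed,
                }
                for p in self.points
            ]
        )


def summarise_ensemble(ensemble, reference_age_years: float = 100.0) -> dict:
    """Plaque summary of one ensemble: prevalence at the reference age with
    its 95% half-width, median lag and mean final size over plaque cells."""
    metrics = ensemble_plaque_metrics(ensemble)
    curve = prevalence_curve(ensemble)
    p = curve.at_age(reference_age_years)
    lags = [m.lag_time_years for m in metrics if m.has_plaque]
    finals = [m.final_size for m in metrics if m.has_plaque]
    return {
        "prevalence": p,
        "ci_half_width": prevalence_ci_half_width(p, len(metrics)),
        "median_lag_years": float(np.median(lags)) if lags else None,
        "mean_final_size": float(np.mean(finals)) if finals else None,
        "n_cells": len(metrics),
    }


def scan_parameter(
    base_spec: ModelSpec,
    name: str,
    values: Sequence[float],
    n_cells: int = 500,
    base_seed: int = 0,
    t_max: float = 100 * YEAR_SECONDS,
    n_records: int = 500,
    reference_age_years: float = 100.0,
) -> ScanResult:
    """Independent ensembles for each value of one parameter.

    Each value gets its own deterministic seed derived from
    ``(base_seed, name, value)``, so rerunning a subset or permuting the
    value list reproduces identical per-value results.
    """
    if name not in base_spec.parameters:
        raise KeyError(f"unknown parameter {name!r}")
    points = []
    for v in values:
        if v < 0:
            raise ValueError(f"parameter values must be non-negative, got {v}")
        seed = _derive_seed(base_seed, name, float(v))
        ens = simulate_ensemble(
            base_spec.with_parameters(**{name: float(v)}),
            n_cells=n_cells,
            base_seed=seed,
            t_max=t_max,
            n_records=n_records,
        )
        s = summarise_ensemble(ens, reference_age_years)
        points.append(
            ScanPoint(
                value=float(v),
                prevalence=s["prevalence"],
                ci_half_width=s["ci_half_width"],
                median_lag_years=s["median_lag_years"],
                mean_final_size=s["mean_final_size"],
                n_cells=s["n_cells"],
                seed=seed,
            )
        )
    return ScanResult(
        parameter=name,
        points=points,
        reference_age_years=reference_age_years,
        base_seed=int(base_seed),
    )


#: Parameters held fixed in the global scan (measured values).
LHS_FIXED = ("k_prod", "k_deg")
#: Parameters constrained to [1/2, 2] x default (experimentally anchored).
LHS_HALF_TO_TWICE = ("k_pf", "k_pg")
#: Parameters allowed to vary over two orders of magnitude around the default.
LHS_TWO_DECADES = ("k_dimer", "k_dedimer", "k_pghalf", "k_disagg")


@dataclass
class LhsDesign:
    """Latin-hypercube design over the free aggregation parameters.

    Each sampled parameter's range is split into ``n_sets`` equiprobable
    strata on a log scale (rate constants span orders of magnitude), one
    sample per stratum, independently permuted across parameters.
    """

    n_sets: int = 100
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = MODEL2_DEFAULTS
        bounds = dict(self.bounds)
        for p in LHS_HALF_TO_TWICE:
            bounds.setdefault(p, (defaults[p] / 2.0, defaults[p] * 2.0))
        for p in LHS_TWO_DECADES:
            bounds.setdefault(p, (defaults[p] / 10.0, defaults[p] * 10.0))
        self.bounds = bounds
        fixed = dict(self.fixed)
        for p in LHS_FIXED:
            fixed.setdefault(p, defaults[p])
        self.fixed = fixed
        for p, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError(f"invalid bounds for {p}: ({lo}, {hi})")


def lhs_sample(design: LhsDesign) -> list[ParameterSet]:
    """Draw the design: one :class:`ParameterSet` per hypercube row.

    Marginals are log-uniform within each parameter's bounds; fixed
    parameters are copied verbatim into every set.
    """
    names = sorted(design.bounds)
    sampler = qmc.LatinHypercube(d=len(names), seed=design.seed)
    unit = sampler.random(n=design.n_sets)
    out = []
    for row in unit:
        ps = ParameterSet(MODEL2_DEFAULTS)
        ps.update(design.fixed)
        for u, name in zip(row, names):
            lo, hi = design.bounds[name]
            ps[name] = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        out.append(ps)
    return out


def stage1_rule(prevalence_100: float, threshold: float = 30.0) -> bool:
    """Keep a set after the normal-clearance screen?  Eliminated when more
    than ``threshold`` % of cells produce plaques by age 100 (the generous
    30% cut compensates for the small stage-1 ensemble)."""
    return prevalence_100 <= threshold


def stage2_rule(
    prevalence_100: float,
    prevalence_50: float,
    min_p100: float = 10.0,
    max_p50: float = 15.0,
) -> bool:
    """Keep a set after the declining-clearance screen?  Eliminated when the
    age-100 burden is below ``min_p100`` % or the age-50 burden exceeds
    ``max_p50`` % (plaques must be common late but rare early)."""
    return prevalence_100 >= min_p100 and prevalence_50 <= max_p50


@dataclass
class FilterDecision:
    set_index: int
    stage: int
    prevalence_100: float
    prevalence_50: float | None
    kept: bool
    seed: int


@dataclass
class GlobalScanResult:
    retained: list[ParameterSet]
    retained_indices: list[int]
    audit_trail: list[FilterDecision]

    def to_audit_json(self) -> list[dict]:
        return [
            {
                "set_index": d.set_index,
                "stage": d.stage,
                "prevalence_100": d.prevalence_100,
                "prevalence_50": d.prevalence_50,
                "kept": d.kept,
                "seed": d.seed,
            }
            for d in self.audit_trail
        ]


def global_scan_filter(
    sets: Sequence[ParameterSet],
    stage1_runs: int = 10,
    stage2_runs: int = 100,
    base_seed: int = 0,
    build=None,
    n_records: int = 500,
) -> GlobalScanResult:
    """Two-stage elimination of candidate parameter sets.

    Stage 1 simulates each set under normal (constant) clearance with a small
    ensemble and drops sets whose age-100 plaque prevalence exceeds 30%.
    Stage 2 simulates the survivors under declining clearance with a larger
    ensemble and drops sets below 10% prevalence at age 100 or above 15% at
    age 50.  Every decision is recorded with its measured percentages.
    """
    from .builders import build_model2

    if build is None:
        build = build_model2
    audit: list[FilterDecision] = []
    survivors: list[int] = []

    def overrides(ps: Mapping[str, float]) -> dict[str, float]:
        # the clearance variant controls k_degNep; candidate sets supply the rest
        return {k: v for k, v in ps.items() if k != "k_degNep"}

    for i, ps in enumerate(sets):
        seed = _derive_seed(base_seed, "stage1", i)
        spec = build("normal", **overrides(ps))
        ens = simulate_ensemble(spec, stage1_runs, base_seed=seed,
                                n_records=n_records)
        p100 = prevalence_curve(ens).at_age(100.0)
        kept = stage1_rule(p100)
        audit.append(FilterDecision(i, 1, p100, None, kept, seed))
        if kept:
            survivors.append(i)
    retained: list[int] = []
    for i in survivors:
        seed = _derive_seed(base_seed, "stage2", i)
        spec = build("declining", **overrides(sets[i]))
        ens = simulate_ensemble(spec, stage2_runs, base_seed=seed,
                                n_records=n_records)
        curve = prevalence_curve(ens)
        p100, p50 = curve.at_age(100.0), curve.at_age(50.0)
        kept = stage2_rule(p100, p50)
        audit.append(FilterDecision(i, 2, p100, p50, kept, seed))
        if kept:
            retained.append(i)
    return GlobalScanResult(
        retained=[ParameterSet(sets[i]) for i in retained],
        retained_indices=retained,
        audit_trail=audit,
    )
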