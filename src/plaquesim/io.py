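"""Serialisation: run configurations, trajectory CSVs, ensemble manifests.

A run is reproducible from its configuration plus seed alone; manifests
embed a content hash of the resolved model specification so silent drift in
parameters or reactions is detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .builders import build_model1, build_model2, build_model3
from .engine import EnsembleResult, Trajectory
from .model import (
    HazardKind,
    ModelSpec,
    ParameterSet,
    Reaction,
    SpeciesState,
    TimedEvent,
)
from .units import YEAR_SECONDS

__all__ = [
    "RunConfig",
    "load_config",
    "build_from_config",
    "spec_to_dict",
    "spec_from_dict",
    "spec_hash",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_ensemble",
]


# ---------------------------------------------------------------------------
# ModelSpec <-> plain dict
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "name": spec.name,
        "variant": spec.variant,
        "plaque_threshold": spec.plaque_threshold,
        "species": [
            {"name": s.name, "count": s.count, "constant": s.constant}
            for s in spec.species
        ],
        "parameters": dict(spec.parameters),
        "reactions": [
            {
                "id": r.id,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "kind": r.kind.value,
                "rate_param": r.rate_param,
                "modifier": r.modifier,
                "aux_param": r.aux_param,
            }
            for r in spec.reactions
        ],
        "events": [
            {
                "time": e.time,
                "species_assignments": dict(e.species_assignments),
                "parameter_assignments": dict(e.parameter_assignments),
            }
            for e in spec.events
        ],
    }


def spec_from_dict(d: Mapping[str, Any]) -> ModelSpec:
    return ModelSpec(
        name=d["name"],
        variant=d.get("variant", ""),
        plaque_threshold=int(d.get("plaque_threshold", 30)),
        species=[
            SpeciesState(s["name"], int(s["count"]), bool(s.get("constant", False)))
            for s in d["species"]
        ],
        parameters=ParameterSet(d["parameters"]),
        reactions=[
            Reaction(
                id=r["id"],
                reactants={k: int(v) for k, v in r["reactants"].items()},
                products={k: int(v) for k, v in r["products"].items()},
                kind=HazardKind(r["kind"]),
                rate_param=r["rate_param"],
                modifier=r.get("modifier"),
                aux_param=r.get("aux_param"),
            )
            for r in d["reactions"]
        ],
        events=[
            TimedEvent(
                float(e["time"]),
                {k: int(v) for k, v in e.get("species_assignments", {}).items()},
                {k: float(v) for k, v in e.get("parameter_assignments", {}).items()},
            )
            for e in d.get("events", [])
        ],
    )


def spec_hash(spec: ModelSpec) -> str:
    """Stable content hash of a resolved model specification."""
    blob = json.dumps(spec_to_dict(spec), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation experiment."""

    model: str = "model2"  # model1 | model2 | model3
    variant: str = "normal"
    k_deg: float | None = None  # model1 only
    parameters: dict = field(default_factory=dict)  # overrides
    t_max_years: float = 100.0
    record_points: int = 500
    n_cells: int = 100
    seed: int = 0
    intervention: dict | None = None  # kind / age_years / plan kwargs
    plaque_threshold: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def build_from_config(cfg: RunConfig) -> ModelSpec:
    from .interventions import InterventionPlan, apply_intervention

    if cfg.model == "model1":
        spec = build_model1(**({"k_deg": cfg.k_deg} if cfg.k_deg else {}))
        if cfg.parameters:
            spec = spec.with_parameters(**cfg.parameters)
    elif cfg.model == "model2":
        spec = build_model2(cfg.variant, **cfg.parameters)
    elif cfg.model == "model3":
        spec = build_model3(cfg.variant, **cfg.parameters)
    else:
        raise ValueError(f"unknown model {cfg.model!r}")
    if cfg.plaque_threshold is not None:
        spec.plaque_threshold = int(cfg.plaque_threshold)
    if cfg.intervention:
        iv = dict(cfg.intervention)
        plan = InterventionPlan(
            kind=iv.pop("kind"),
            administration_age_years=float(iv.pop("age_years")),
            **iv,
        )
        spec = apply_intervention(spec, plan)
    return spec


# ---------------------------------------------------------------------------
# trajectory / ensemble output
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """One row per record time: time_s, time_years, species counts, firing
    counters.  Provenance (model id, seed) goes in ``#`` header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# plaquesim {__version__}\n")
        fh.write(f"# model_id: {traj.model_id}\n")
        fh.write(f"# seed: {traj.seed}\n")
        traj.to_dataframe().to_csv(fh, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    species = [c for c in df.columns if c not in ("time_s", "time_years")
               and not c.startswith("fired_")]
    reactions = [c[len("fired_"):] for c in df.columns if c.startswith("fired_")]
    return Trajectory(
        record_times=df["time_s"].to_numpy(float),
        counts=df[species].to_numpy(np.int64),
        firing_counts=df[[f"fired_{r}" for r in reactions]].to_numpy(np.int64)
        if reactions
        else np.zeros((len(df), 0), np.int64),
        species_names=tuple(species),
        reaction_ids=tuple(reactions),
        seed=int(meta.get("seed", -1)),
        model_id=meta.get("model_id", ""),
    )


def write_ensemble(ens: EnsembleResult, out_dir: str | Path,
                   write_trajectories: bool = True) -> Path:
    """Write per-cell trajectory CSVs plus a JSON manifest with the seeds
    and the spec hash; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if write_trajectories:
        width = len(str(ens.n_cells - 1))
        for i, tr in enumerate(ens):
            write_trajectory_csv(tr, out_dir / f"cell_{i:0{width}d}.csv")
    manifest = {
        "package_version": __version__,
        "model": spec_to_dict(ens.spec),
        "spec_hash": spec_hash(ens.spec),
        "base_seed": ens.base_seed,
        "cell_seeds": [int(s) for s in ens.seeds],
        "n_cells": ens.n_cells,
        "t_max_s": float(ens.trajectories[0].record_times[-1]),
        "t_max_years": float(ens.trajectories[0].record_times[-1] / YEAR_SECONDS),
        "record_points": int(len(ens.trajectories[0].record_times)),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
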