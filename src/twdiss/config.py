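"""Structured configuration files (YAML or JSON) for Transwell runs.

A run file has up to six sections; every key is optional and falls back
to the fluticasone-propionate defaults::

    geometry: {membrane_area: 4.52, filter_volume: 0.118, ...}
    drug:     {permeability: 0.289, diffusion_coefficient: 0.022284,
               density: 1.37, shape_factor: 1.0}
    medium:   {solubility: 5.3, label: "0.5% Tween 80"}
    schedule: {times_min: [10, 20, ...], sample_volume: 0.5}
    run:      {donor_volume: 0.58, receptor_volume: match,
               initial_amount: 23.0, correction_factor: 0.0244,
               psd: stages.csv}          # omit psd for a solution run
    solver:   {method: LSODA, rtol: 1e-9, atol: 1e-12}

``receptor_volume: match`` derives the receptor fill hydrostatically from
the donor volume; a ``psd`` entry names a stage-deposition CSV resolved
relative to the config file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .geometry import ApparatusGeometry, match_receptor_volume
from .particles import build_psd, read_stage_table
from .simulate import (
    DrugProperties,
    ExperimentConfig,
    MediumProperties,
    SamplingSchedule,
    SolverSettings,
)

_SECTIONS = {"geometry", "drug", "medium", "schedule", "run", "solver"}


def _build(section: Mapping[str, Any], cls, **coerce):
    data = dict(section)
    for key, fn in coerce.items():
        if key in data:
            data[key] = fn(data[key])
    return cls(**data)


def config_from_dict(
    data: Mapping[str, Any], base_dir: str | Path = "."
) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a parsed config mapping."""
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    geometry = ApparatusGeometry.from_dict(data.get("geometry", {}))
    drug = _build(data.get("drug", {}), DrugProperties)
    medium = _build(
        data.get("medium", {"solubility": 5.3, "label": "0.5% Tween 80"}),
        MediumProperties,
    )
    schedule = _build(data.get("schedule", {}), SamplingSchedule, times_min=tuple)
    solver = _build(data.get("solver", {}), SolverSettings)
    run = dict(data.get("run", {}))
    psd = None
    if run.get("psd"):
        stages = read_stage_table(Path(base_dir) / run.pop("psd"))
        psd = build_psd(
            stages,
            delivered_mass=float(run.get("initial_amount", 23.0)),
            density=drug.density,
            shape_factor=drug.shape_factor,
        )
    else:
        run.pop("psd", None)
    donor = float(run.get("donor_volume", 0.58))
    receptor = run.get("receptor_volume", 1.5)
    if receptor == "match":
        receptor = match_receptor_volume(donor, geometry)
    config = ExperimentConfig(
        donor_volume=donor,
        receptor_volume=float(receptor),
        initial_amount=float(run.get("initial_amount", 23.0)),
        psd=psd,
        correction_factor=float(run.get("correction_factor", 0.0244)),
        drug=drug,
        medium=medium,
        schedule=schedule,
        geometry=geometry,
        solver=solver,
    )
    config.validate()
    return config


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML or JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data, base_dir=path.parent)
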