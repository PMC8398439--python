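"""Scripted simulation studies over the Transwell design space.

Five sweeps probe how assay design choices shape the observed transfer
kinetics of a polydisperse sample: medium solubility, donor/receptor
volumes (hydrostatically matched), sampling volume, particle-size
resolution, and the dose-dependent "mass effect".  Each runner is a pure
function of a base configuration — the base is never mutated — and a
seed-free deterministic computation, so re-running a scenario reproduces
its outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import match_receptor_volume
from .metrics import F1F2Result, TransferProfile, f1_f2, fit_weibull
from .particles import scale_psd
from .simulate import ExperimentConfig, TransferResult, simulate

#: Mass-effect scenario volume sets (V_d, V_r, V_s) in mL: small volumes,
#: large volumes with increasing sampling volume.
MASS_EFFECT_SCENARIOS: dict[str, tuple[float, float, float]] = {
    "scenario 1": (0.58, 1.5, 0.5),
    "scenario 2": (3.0, 3.31, 0.5),
    "scenario 3": (3.0, 3.31, 1.0),
    "scenario 4": (3.0, 3.31, 2.0),
}


@dataclass
class ScenarioResult:
    """One sweep: values of the swept variable and per-value outcomes."""

    scenario_name: str
    sweep_variable: str
    sweep_values: list
    mdt_hours: list[float]
    profiles: list[TransferProfile]
    verdicts: list[F1F2Result] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sweep_values) != len(self.mdt_hours):
            raise ValueError("sweep_values and mdt_hours must have equal length")
        if any(m <= 0 for m in self.mdt_hours):
            raise ValueError("all fitted MDTs must be positive")

    def to_frame(self) -> pd.DataFrame:
        data = {self.sweep_variable: self.sweep_values, "mdt_h": self.mdt_hours}
        if self.verdicts is not None:
            data["f1"] = [v.f1 for v in self.verdicts]
            data["f2"] = [v.f2 for v in self.verdicts]
            data["verdict"] = [v.verdict for v in self.verdicts]
        for key, values in self.extras.items():
            if isinstance(values, (list, np.ndarray)) and len(values) == len(self.sweep_values):
                data[key] = values
        return pd.DataFrame(data)


def _mdt(result: TransferResult) -> float:
    return fit_weibull(result.observed_profile()).mdt_hours


def solubility_sweep(
    base_config: ExperimentConfig, solubilities: Sequence[float]
) -> ScenarioResult:
    """Particle runs across media of different solubility vs the solution run.

    For each solubility the particle profile is simulated and fitted, and
    compared (f1/f2) against the matched solution run in the same medium —
    the dissolution-unlimited reference.  Locates the solubility below
    which particle dissolution becomes rate-limiting.
    """
    if base_config.psd is None:
        raise ValueError("solubility sweep needs a particle configuration")
    mdts, profiles, verdicts = [], [], []
    for cs in solubilities:
        cfg = replace(base_config, medium=replace(base_config.medium, solubility=cs, label=""))
        result = simulate(cfg)
        reference = simulate(replace(cfg, psd=None))
        profile = result.observed_profile()
        mdts.append(_mdt(result))
        profiles.append(profile)
        verdicts.append(f1_f2(reference.observed_profile(), profile))
    return ScenarioResult(
        "solubility sweep", "solubility_ug_per_ml", list(solubilities), mdts, profiles, verdicts
    )


def volume_sweep(
    base_config: ExperimentConfig, donor_volumes: Sequence[float]
) -> ScenarioResult:
    """Sweep donor volume with the receptor auto-matched for equal levels."""
    mdts, profiles, peaks, receptors = [], [], [], []
    for vd in donor_volumes:
        vr = match_receptor_volume(vd, base_config.geometry)
        cfg = replace(base_config, donor_volume=vd, receptor_volume=vr)
        result = simulate(cfg)
        mdts.append(_mdt(result))
        profiles.append(result.observed_profile())
        peaks.append(float(result.donor_concentration.max()))
        receptors.append(vr)
    return ScenarioResult(
        "donor/receptor volume sweep",
        "donor_volume_ml",
        list(donor_volumes),
        mdts,
        profiles,
        extras={"receptor_volume_ml": receptors, "peak_donor_conc_ug_per_ml": peaks},
    )


def sampling_volume_sweep(
    base_config: ExperimentConfig, sampling_volumes: Sequence[float]
) -> ScenarioResult:
    """Sweep the per-sample volume at a fixed sampling schedule."""
    mdts, profiles, peaks = [], [], []
    for vs in sampling_volumes:
        cfg = replace(
            base_config, schedule=replace(base_config.schedule, sample_volume=vs)
        )
        result = simulate(cfg)
        mdts.append(_mdt(result))
        profiles.append(result.observed_profile())
        peaks.append(float(result.donor_concentration.max()))
    return ScenarioResult(
        "sampling volume sweep",
        "sampling_volume_ml",
        list(sampling_volumes),
        mdts,
        profiles,
        extras={"peak_donor_conc_ug_per_ml": peaks},
    )


def psd_resolution_study(
    base_config: ExperimentConfig,
    scale_factors: Sequence[float] = (0.5, 1.0, 2.0),
    solubilities: Sequence[float] = (5.3, 19.12),
) -> ScenarioResult:
    """How well the assay separates formulations of different particle size.

    Simulates hypothetical formulations whose PSD is the base one scaled
    by each factor, across media solubilities.  The resolution metric per
    solubility is the spread of the fitted MDTs across the size factors,
    expressed relative to the MDT of the matched solution run (the
    assay's diffusion baseline) — a larger spread means the medium
    distinguishes particle-size differences better.
    """
    if base_config.psd is None:
        raise ValueError("psd resolution study needs a particle configuration")
    solution_mdt = _mdt(simulate(replace(base_config, psd=None)))
    rows = []
    profiles = []
    for cs in solubilities:
        for factor in scale_factors:
            cfg = replace(
                base_config,
                psd=scale_psd(base_config.psd, factor),
                medium=replace(base_config.medium, solubility=cs, label=""),
            )
            result = simulate(cfg)
            profiles.append(result.observed_profile())
            rows.append({"solubility_ug_per_ml": cs, "psd_factor": factor, "mdt_h": _mdt(result)})
    matrix = pd.DataFrame(rows)
    resolution = {
        float(cs): float((g["mdt_h"].max() - g["mdt_h"].min()) / solution_mdt)
        for cs, g in matrix.groupby("solubility_ug_per_ml")
    }
    return ScenarioResult(
        "psd resolution study",
        "psd_factor",
        matrix["psd_factor"].tolist(),
        matrix["mdt_h"].tolist(),
        profiles,
        extras={
            "mdt_matrix": matrix,
            "relative_mdt_spread": resolution,
            "solution_mdt_h": solution_mdt,
        },
    )


def mass_effect_study(
    base_config: ExperimentConfig,
    doses: Sequence[float] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    scenarios: dict[str, tuple[float, float, float]] | None = None,
    ratio_doses: tuple[float, float] = (10.0, 30.0),
) -> dict[str, ScenarioResult]:
    """Dose dependence of the MDT under different volume scenarios.

    For each named scenario ``(V_d, V_r, V_s)`` the same formulation is
    simulated at each initial dose and the fitted MDT recorded; the
    scenario's mass-effect ratio MDT(high)/MDT(low) for ``ratio_doses``
    is stored in ``extras["mdt_ratio"]``.  Larger ratios mean a stronger
    mass effect (loss of sink conditions at higher doses).
    """
    if base_config.psd is None:
        raise ValueError("mass effect study needs a particle configuration")
    scenarios = dict(scenarios or MASS_EFFECT_SCENARIOS)
    out: dict[str, ScenarioResult] = {}
    lo, hi = ratio_doses
    for name, (vd, vr, vs) in scenarios.items():
        mdts, profiles = [], []
        for dose in doses:
            cfg = replace(
                base_config,
                donor_volume=vd,
                receptor_volume=vr,
                initial_amount=dose,
                schedule=replace(base_config.schedule, sample_volume=vs),
            )
            result = simulate(cfg)
            mdts.append(_mdt(result))
            profiles.append(result.observed_profile())
        by_dose = dict(zip(doses, mdts))
        ratio = by_dose[hi] / by_dose[lo] if lo in by_dose and hi in by_dose else None
        out[name] = ScenarioResult(
            name,
            "dose_ug",
            list(doses),
            mdts,
            profiles,
            extras={"volumes_ml": (vd, vr, vs), "mdt_ratio": ratio},
        )
    return out
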