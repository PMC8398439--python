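"""Coupled dissolution–diffusion simulation of the Transwell transfer test.

Model
-----
Drug particles sit in a small donor volume above a porous membrane; the
receptor well below is stirred and sampled at scheduled times.  Three
processes are coupled:

* **Dissolution** (Nernst–Brunner, per particle-size bin ``i``)::

      dX_i/dt = -F * D * SA_i(t) * (C_s - X_d/V_d) / r_i(t)

  where the diffusion-layer thickness equals the particle radius, so
  ``SA_i / r_i = 4π N_i r_i`` and the rate vanishes smoothly as a bin
  exhausts.  ``F`` is a correction factor absorbing the stagnant layer,
  agglomeration and surface-accessibility effects of the filter-sandwich
  geometry.

* **Membrane transfer** (Fick's first law)::

      dY/dt = P * SM * (X_d/V_d - Y/V_r)
      dX_d/dt = -Σ dX_i/dt - dY/dt

* **Sampling**: at each scheduled time a fixed volume ``V_s`` is removed
  from the receptor and replaced with fresh medium, an instantaneous jump
  ``Y ← Y·(1 - V_s/V_r)`` that restores the concentration gradient.  The
  bench assay reports, at each sampling time, the cumulative transferred
  fraction ``100·(Y(t⁻) + S(t⁻))/X_initial`` where ``S`` is the amount
  already removed in earlier samples.

Units are internally consistent in µg, mL, cm and hours; schedule times
are minutes at the interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import ApparatusGeometry, CapacityError
from .particles import ParticleSizeDistribution, UG_TO_G
from .metrics import TransferProfile

logger = logging.getLogger(__name__)

#: Membrane diffusion coefficient of the model drug (fluticasone
#: propionate) in water at 37 °C, cm²/h (0.0003714 cm²/min).
DEFAULT_DIFFUSION_CM2_PER_H = 0.0003714 * 60.0
#: Fitted Transwell membrane permeability of fluticasone propionate, cm/h.
DEFAULT_PERMEABILITY_CM_PER_H = 0.289
#: Fitted Nernst–Brunner correction factor for the filter-sandwich geometry.
DEFAULT_CORRECTION_FACTOR = 0.0244

#: Bench sampling schedules (minutes): full dissolution run and the
#: shorter solution-diffusion run.
DISSOLUTION_TIMEPOINTS_MIN = (10, 20, 30, 45, 60, 90, 120, 180, 240, 360, 480, 720, 1440)
DIFFUSION_TIMEPOINTS_MIN = (10, 20, 30, 45, 60, 90, 120, 180, 240)
#: More frequent variant: hourly sampling from 2 h onwards.
FREQUENT_TIMEPOINTS_MIN = (10, 20, 30, 45, 60, 90, 120) + tuple(range(180, 1441, 60))


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge."""


class InternalConsistencyError(RuntimeError):
    """A state variable left its physical range beyond solver tolerance."""


def hayduk_laudie_D(
    eta: float, molecular_volume: float, exponent: float = 1.14
) -> float:
    """Aqueous diffusion coefficient from the Hayduk–Laudie correlation.

    ``D = 13.26e-5 / (η^1.14 · V_M^0.589)`` in cm²/s, returned in cm²/h.

    Parameters
    ----------
    eta : float
        Water viscosity in cP (≈0.69 at 37 °C).
    molecular_volume : float
        Molar volume of the solute at its normal boiling point, cm³/mol.
    exponent : float
        Viscosity exponent; 1.14 is the literature value.
    """
    if eta <= 0 or molecular_volume <= 0:
        raise ValueError("eta and molecular_volume must be > 0")
    d_cm2_s = 13.26e-5 / (eta**exponent * molecular_volume**0.589)
    return d_cm2_s * 3600.0


@dataclass(frozen=True)
class DrugProperties:
    """Transport and material properties of the drug substance.

    Either ``diffusion_coefficient`` (cm²/h) is given directly or it is
    derived from ``water_viscosity`` (cP) and ``molecular_volume``
    (cm³/mol) via Hayduk–Laudie.
    """

    permeability: float = DEFAULT_PERMEABILITY_CM_PER_H
    diffusion_coefficient: float | None = DEFAULT_DIFFUSION_CM2_PER_H
    water_viscosity: float | None = None
    molecular_volume: float | None = None
    density: float = 1.37
    shape_factor: float = 1.0
    hayduk_laudie_exponent: float = 1.14

    def __post_init__(self) -> None:
        # P = 0 (impermeable membrane) is a valid limiting case
        if self.permeability < 0 or self.density <= 0 or self.shape_factor <= 0:
            raise ValueError("permeability must be >= 0; density and shape_factor > 0")
        if self.diffusion_coefficient is None and (
            self.water_viscosity is None or self.molecular_volume is None
        ):
            raise ValueError(
                "give diffusion_coefficient or both water_viscosity and molecular_volume"
            )

    @property
    def resolved_diffusion_coefficient(self) -> float:
        """Diffusion coefficient in cm²/h, computed if not supplied."""
        if self.diffusion_coefficient is not None:
            return self.diffusion_coefficient
        return hayduk_laudie_D(
            self.water_viscosity, self.molecular_volume, self.hayduk_laudie_exponent
        )


@dataclass(frozen=True)
class MediumProperties:
    """Dissolution medium: what matters to the model is the solubility."""

    solubility: float  # µg/mL
    label: str = ""

    def __post_init__(self) -> None:
        if self.solubility <= 0:
            raise ValueError("solubility must be > 0")


@dataclass(frozen=True)
class SamplingSchedule:
    """Receptor sampling times (minutes) and per-sample volume (mL)."""

    times_min: tuple[float, ...] = DISSOLUTION_TIMEPOINTS_MIN
    sample_volume: float = 0.5
    replacement_volume: float | None = None  # None → equal to sample_volume

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing and positive")
        if self.sample_volume < 0:
            raise ValueError("sample_volume must be >= 0")
        object.__setattr__(self, "times_min", tuple(float(x) for x in t))


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration for the adaptive and Euler-oracle paths."""

    method: str = "LSODA"
    rtol: float = 1e-9
    atol: float = 1e-12
    dense_points_per_interval: int = 40
    euler_dt_min: float = 0.01
    exhaustion_rel_threshold: float = 1e-6


@dataclass
class ExperimentConfig:
    """Complete description of one Transwell run.

    ``psd=None`` describes a solution experiment: the whole
    ``initial_amount`` starts dissolved in the donor.
    """

    donor_volume: float = 0.58
    receptor_volume: float = 1.5
    initial_amount: float = 23.0
    psd: ParticleSizeDistribution | None = None
    correction_factor: float = DEFAULT_CORRECTION_FACTOR
    drug: DrugProperties = field(default_factory=DrugProperties)
    medium: MediumProperties = field(default_factory=lambda: MediumProperties(5.3, "0.5% Tween 80"))
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    geometry: ApparatusGeometry = field(default_factory=ApparatusGeometry)
    solver: SolverSettings = field(default_factory=SolverSettings)

    def validate(self) -> None:
        if self.donor_volume <= 0 or self.receptor_volume <= 0:
            raise ValueError("donor and receptor volumes must be > 0")
        if self.initial_amount <= 0:
            raise ValueError("initial_amount must be > 0")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be > 0")
        g = self.geometry
        if self.donor_volume + g.filter_volume > g.donor_max_volume + 1e-9:
            raise CapacityError("donor volume exceeds apparatus capacity")
        if self.receptor_volume > g.receptor_max_volume + g.membrane_wetting_volume + 1e-9:
            raise CapacityError("receptor volume exceeds apparatus capacity")
        if self.schedule.sample_volume > self.receptor_volume:
            raise ValueError("sample volume exceeds receptor volume")

    def log_resolved(self) -> None:
        """Log every resolved parameter and unit interpretation."""
        d = self.drug
        logger.info(
            "resolved parameters: V_d=%.4g mL, V_r=%.4g mL, X_initial=%.4g ug, "
            "F=%.4g, P=%.4g cm/h, D=%.4g cm2/h, Cs=%.4g ug/mL (%s), SM=%.4g cm2, "
            "V_s=%.4g mL, %d sampling times (min), psd=%s",
            self.donor_volume, self.receptor_volume, self.initial_amount,
            self.correction_factor, d.permeability, d.resolved_diffusion_coefficient,
            self.medium.solubility, self.medium.label or "unlabelled",
            self.geometry.membrane_area, self.schedule.sample_volume,
            len(self.schedule.times_min),
            "none (solution)" if self.psd is None else f"{len(self.psd.bins)} bins",
        )


@dataclass
class TransferResult:
    """Dense state trajectories plus the bench-style observed profile.

    Event (sampling) times appear twice in ``time_min``: once with the
    pre-sample state and once with the post-sample state.
    """

    time_min: np.ndarray
    per_bin_mass: np.ndarray  # shape (T, n_bins)
    donor_dissolved: np.ndarray
    receptor_amount: np.ndarray
    removed_cumulative: np.ndarray
    observed_times_min: np.ndarray
    observed_percent: np.ndarray
    config: ExperimentConfig

    @property
    def donor_concentration(self) -> np.ndarray:
        """Dissolved donor concentration, µg/mL."""
        return self.donor_dissolved / self.config.donor_volume

    @property
    def cumulative_transferred_percent(self) -> np.ndarray:
        """Dense cumulative transfer, % of the initial amount."""
        x0 = self.config.initial_amount
        return 100.0 * (self.receptor_amount + self.removed_cumulative) / x0

    def mass_balance_error(self) -> float:
        """Max relative deviation of X_d + Y + S + ΣX_i from X_initial."""
        total = (
            self.donor_dissolved
            + self.receptor_amount
            + self.removed_cumulative
            + self.per_bin_mass.sum(axis=1)
        )
        return float(np.max(np.abs(total - self.config.initial_amount)) / self.config.initial_amount)

    def observed_profile(self) -> TransferProfile:
        return TransferProfile(self.observed_times_min.copy(), self.observed_percent.copy())

    def to_frame(self):
        """Tidy per-time-point DataFrame of the dense trajectories."""
        import pandas as pd

        data = {
            "time_min": self.time_min,
            "donor_dissolved_ug": self.donor_dissolved,
            "receptor_ug": self.receptor_amount,
            "removed_ug": self.removed_cumulative,
            "donor_concentration_ug_per_ml": self.donor_concentration,
            "cumulative_transferred_percent": self.cumulative_transferred_percent,
        }
        for j in range(self.per_bin_mass.shape[1]):
            data[f"bin{j + 1}_ug"] = self.per_bin_mass[:, j]
        return pd.DataFrame(data)


class _Model:
    """Vectorised right-hand side and event bookkeeping for one config."""

    def __init__(self, config: ExperimentConfig):
        config.validate()
        self.cfg = config
        self.vd = config.donor_volume
        self.vr = config.receptor_volume
        self.p = config.drug.permeability
        self.sm = config.geometry.membrane_area
        self.cs = config.medium.solubility
        self.f = config.correction_factor
        self.d = config.drug.resolved_diffusion_coefficient
        psd = config.psd
        if psd is None:
            self.n_bins = 0
            self.counts = np.empty(0)
            self.x0_bins = np.empty(0)
            self.rho = config.drug.density
        else:
            # rescale the PSD proportionally to the delivered amount: more
            # drug means proportionally more particles of unchanged size
            self.n_bins = len(psd.bins)
            dose_scale = config.initial_amount / psd.total_mass
            self.counts = psd.counts * dose_scale
            self.x0_bins = psd.masses * dose_scale
            self.rho = psd.density
        self.exhaust = config.solver.exhaustion_rel_threshold * self.x0_bins
        # geometric prefactor: SA_i/r_i = 4π N_i r_i with r from remaining mass
        self._rcoef = (3.0 * UG_TO_G / (4.0 * math.pi * self.rho * np.maximum(self.counts, 1e-300))) ** (1.0 / 3.0)
        # bins frozen (exhausted) so far; persistent across sampling intervals
        self.frozen = np.zeros(self.n_bins, dtype=bool)

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_bins + 2)
        if self.n_bins:
            y[: self.n_bins] = self.x0_bins
            y[self.n_bins] = 0.0  # nothing dissolved yet
        else:
            y[self.n_bins] = self.cfg.initial_amount
        return y

    def radii(self, bin_masses: np.ndarray) -> np.ndarray:
        return self._rcoef * np.cbrt(np.maximum(bin_masses, 0.0))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n_bins
        xd, yv = y[n], y[n + 1]
        cd = xd / self.vd
        flux = self.p * self.sm * (cd - yv / self.vr)
        dy = np.empty_like(y)
        if n:
            r = self.radii(y[:n])
            rates = -4.0 * math.pi * self.f * self.d * self.counts * r * (self.cs - cd)
            rates[self.frozen & (rates < 0)] = 0.0
            dy[:n] = rates
            dy[n] = -rates.sum() - flux
        else:
            dy[n] = -flux
        dy[n + 1] = flux
        return dy


def _postprocess(model, times, states, s_values, obs_t, obs_pct, config):
    times = np.asarray(times)
    states = np.vstack(states)
    n = model.n_bins
    result = TransferResult(
        time_min=times * 60.0,
        per_bin_mass=states[:, :n],
        donor_dissolved=states[:, n],
        receptor_amount=states[:, n + 1],
        removed_cumulative=np.asarray(s_values),
        observed_times_min=np.asarray(obs_t) * 60.0,
        observed_percent=np.asarray(obs_pct),
        config=config,
    )
    worst = min(result.donor_dissolved.min(), result.receptor_amount.min())
    if worst < -1e-6 * config.initial_amount:
        raise InternalConsistencyError(
            f"negative state beyond tolerance: min amount {worst:.3e} µg"
        )
    return result


def simulate(config: ExperimentConfig, method: str | None = None) -> TransferResult:
    """Run one Transwell experiment in silico.

    Integrates the coupled dissolution–diffusion ODEs between consecutive
    sampling times with an adaptive stiff-capable solver (hard stops at
    every sampling event), applies the sample-and-replace jump at each
    event, and records the bench-style observed cumulative-% profile.

    Parameters
    ----------
    config : ExperimentConfig
    method : str, optional
        ``"euler"`` selects the fixed-step explicit-Euler reference
        integrator (step ``config.solver.euler_dt_min`` minutes), used as
        a brute-force cross-check; anything else (default) uses the
        adaptive solver named in ``config.solver.method``.

    Returns
    -------
    TransferResult
    """
    if method == "euler":
        return _simulate_euler(config)
    model = _Model(config)
    config.log_resolved()
    sched = config.schedule
    vs = sched.sample_volume
    times_h = np.concatenate([[0.0], np.asarray(sched.times_min) / 60.0])
    y = model.initial_state()
    s = 0.0
    all_t: list[float] = []
    all_states: list[np.ndarray] = []
    all_s: list[float] = []
    obs_t: list[float] = []
    obs_pct: list[float] = []
    npts = config.solver.dense_points_per_interval

    def _exhaustion_events():
        events = []
        for i in np.nonzero(~model.frozen)[0]:
            def crossing(t, y, i=int(i)):
                return y[i] - model.exhaust[i]
            crossing.terminal = True
            crossing.direction = -1.0
            events.append(crossing)
        return events

    for t_a, t_b in zip(times_h[:-1], times_h[1:]):
        grid = np.linspace(t_a, t_b, npts)
        if t_a > 0.0:
            grid = grid[1:]  # the post-sample row already covers t_a
        t_cur = t_a
        restarted = False
        while True:
            # after an event restart, don't re-emit an already-stored grid point
            pts = grid[grid > t_cur] if restarted else grid
            events = _exhaustion_events() if model.n_bins else None
            sol = solve_ivp(
                model.rhs,
                (t_cur, t_b),
                y,
                method=config.solver.method,
                t_eval=pts,
                events=events,
                rtol=config.solver.rtol,
                atol=config.solver.atol,
            )
            if sol.status == -1:
                raise IntegrationError(
                    f"integration failed on [{t_cur * 60:.1f}, {t_b * 60:.1f}] min: {sol.message}"
                )
            if len(sol.t):
                all_t.extend(sol.t)
                all_states.extend(np.asarray(sol.y).T)
                all_s.extend([s] * len(sol.t))
            if sol.status == 1:
                # a bin reached its exhaustion threshold: freeze it exactly
                # at the crossing and restart the solver from that point
                active = np.nonzero(~model.frozen)[0]
                for j, te in enumerate(sol.t_events):
                    if te.size:
                        model.frozen[active[j]] = True
                        t_cur = float(te[0])
                        y = sol.y_events[j][0].copy()
                restarted = True
                if t_b - t_cur <= 1e-12:
                    break
                continue
            y = sol.y[:, -1].copy()
            break
        # bench observation just before the sample is drawn
        yv = y[model.n_bins + 1]
        obs_t.append(t_b)
        obs_pct.append(100.0 * (yv + s) / config.initial_amount)
        removed = yv * vs / config.receptor_volume
        y[model.n_bins + 1] = yv - removed
        s += removed
        all_t.append(t_b)
        all_states.append(y.copy())
        all_s.append(s)
    return _postprocess(model, all_t, all_states, all_s, obs_t, obs_pct, config)


def _simulate_euler(config: ExperimentConfig) -> TransferResult:
    """Fixed-step explicit Euler reference path (brute-force oracle)."""
    model = _Model(config)
    sched = config.schedule
    vs = sched.sample_volume
    dt_h = config.solver.euler_dt_min / 60.0
    times_h = np.concatenate([[0.0], np.asarray(sched.times_min) / 60.0])
    y = model.initial_state()
    s = 0.0
    all_t, all_states, all_s = [0.0], [y.copy()], [0.0]
    obs_t, obs_pct = [], []
    n = model.n_bins
    for t_a, t_b in zip(times_h[:-1], times_h[1:]):
        nsteps = max(1, int(round((t_b - t_a) / dt_h)))
        h = (t_b - t_a) / nsteps
        t = t_a
        stride = max(1, nsteps // config.solver.dense_points_per_interval)
        for k in range(nsteps):
            y = y + h * model.rhs(t, y)
            if n:
                # a step can overshoot a bin past zero; the overshoot was
                # credited to X_d, so move it back when flooring the bin
                overshoot = np.minimum(y[:n], 0.0).sum()
                if overshoot < 0.0:
                    np.clip(y[:n], 0.0, None, out=y[:n])
                    y[n] += overshoot
                model.frozen |= y[:n] <= model.exhaust
            t = t_a + (k + 1) * h
            if (k + 1) % stride == 0 or k == nsteps - 1:
                all_t.append(t)
                all_states.append(y.copy())
                all_s.append(s)
        yv = y[n + 1]
        obs_t.append(t_b)
        obs_pct.append(100.0 * (yv + s) / config.initial_amount)
        removed = yv * vs / config.receptor_volume
        y[n + 1] = yv - removed
        s += removed
        all_t.append(t_b)
        all_states.append(y.copy())
        all_s.append(s)
    return _postprocess(model, all_t, all_states, all_s, obs_t, obs_pct, config)


def solution_closed_form(config: ExperimentConfig) -> TransferResult:
    """Exact piecewise-analytic solution for a solution (no-particle) run.

    Between sampling events the two-compartment system is linear: the
    total dissolved amount ``M = X_d + Y`` is conserved and the receptor
    amount relaxes to its equilibrium share ``M·V_r/(V_d+V_r)`` with rate
    constant ``k = P·SM·(1/V_d + 1/V_r)``.  Sampling jumps are applied
    exactly.  Serves as an independent oracle for :func:`simulate`.
    """
    if config.psd is not None:
        raise ValueError("closed form applies to solution runs only (psd=None)")
    config.validate()
    vd, vr = config.donor_volume, config.receptor_volume
    p, sm = config.drug.permeability, config.geometry.membrane_area
    k = p * sm * (1.0 / vd + 1.0 / vr)
    frac_r = vr / (vd + vr)
    vs = config.schedule.sample_volume
    times_h = np.concatenate([[0.0], np.asarray(config.schedule.times_min) / 60.0])
    xd, yv, s = config.initial_amount, 0.0, 0.0
    all_t, all_states, all_s = [], [], []
    obs_t, obs_pct = [], []
    npts = config.solver.dense_points_per_interval
    for t_a, t_b in zip(times_h[:-1], times_h[1:]):
        grid = np.linspace(t_a, t_b, npts)
        if t_a > 0.0:
            grid = grid[1:]  # the post-sample row already covers t_a
        m = xd + yv
        y_eq = m * frac_r
        yy = y_eq + (yv - y_eq) * np.exp(-k * (grid - t_a))
        xx = m - yy
        all_t.extend(grid)
        all_states.extend(np.column_stack([xx, yy]))
        all_s.extend([s] * grid.size)
        xd, yv = float(xx[-1]), float(yy[-1])
        obs_t.append(t_b)
        obs_pct.append(100.0 * (yv + s) / config.initial_amount)
        removed = yv * vs / vr
        yv -= removed
        s += removed
        all_t.append(t_b)
        all_states.append(np.array([xd, yv]))
        all_s.append(s)
    model = _Model(config)
    return _postprocess(model, all_t, all_states, all_s, obs_t, obs_pct, config)
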