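"""Calibration of the two fitted model parameters, P and F.

The Transwell model has exactly two parameters that cannot be measured
directly and are instead estimated from bench profiles:

* the membrane **permeability P** (cm/h), fitted to the transfer profile
  of a drug *solution* (no particles, so dissolution drops out), and
* the Nernst–Brunner **correction factor F** (dimensionless), fitted to a
  particle-dissolution profile with P held fixed.

Both fits are unweighted least squares on the cumulative-% scale, with a
log-parameterisation enforcing positivity, and report a relative standard
error from the linearised covariance at the optimum.  A seeded generator
of noisy replicate profiles stands in for bench sextuplicates in
simulation studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import lmfit

from .metrics import TransferProfile, FitError
from .particles import ParticleSizeDistribution
from .simulate import ExperimentConfig, TransferResult, simulate


@dataclass
class FitReport:
    """Point estimate and diagnostics for one fitted parameter."""

    parameter_name: str
    estimate: float
    relative_standard_error: float  # percent
    residual_sse: float
    iterations: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _observed_at(config: ExperimentConfig, times_min: np.ndarray) -> np.ndarray:
    result = simulate(config)
    pred = dict(zip(result.observed_times_min, result.observed_percent))
    return np.array([pred[t] for t in times_min])


def _check_times(observed: TransferProfile, config: ExperimentConfig) -> np.ndarray:
    sched = np.asarray(config.schedule.times_min, dtype=float)
    if not np.all(np.isin(observed.times_min, sched)):
        raise ValueError("observed timepoints must be a subset of the sampling schedule")
    return observed.times_min


def _fit_log_param(
    residual_fn, x0: float, name: str, bounds: tuple[float, float] = (1e-6, 1e4)
) -> tuple[float, float, float, int]:
    # log-parameterisation enforces positivity; bounds keep trial values in
    # the physically meaningful range where the ODE system stays tractable
    params = lmfit.Parameters()
    params.add(
        "log_value",
        value=math.log(x0),
        min=math.log(bounds[0]),
        max=math.log(bounds[1]),
    )
    out = lmfit.minimize(residual_fn, params, method="least_squares", diff_step=1e-4)
    if not out.success:
        raise FitError(f"{name} fit did not converge: {out.message}")
    est = math.exp(out.params["log_value"].value)
    stderr = out.params["log_value"].stderr
    if stderr is None:
        raise FitError(f"{name} fit is non-identifiable (no curvature at optimum)")
    # stderr of log(x) is the relative standard error of x
    rse = 100.0 * stderr
    sse = float(np.sum(out.residual**2))
    return est, rse, sse, int(out.nfev)


def fit_permeability(
    observed: TransferProfile, config: ExperimentConfig, p0: float = 0.3
) -> FitReport:
    """Estimate membrane permeability P (cm/h) from a solution profile.

    ``config`` describes the solution run (``psd`` must be ``None``); its
    drug permeability entry is ignored and replaced by the candidate
    value during optimisation.
    """
    if config.psd is not None:
        raise ValueError("permeability is fitted on a solution run (config.psd must be None)")
    times = _check_times(observed, config)
    if observed.cumulative_percent.max() - observed.cumulative_percent.min() <= 1e-6:
        raise FitError("flat observed profile: permeability is not identifiable")

    def residual(params):
        p = math.exp(params["log_value"].value)
        cfg = replace(config, drug=replace(config.drug, permeability=p))
        return _observed_at(cfg, times) - observed.cumulative_percent

    est, rse, sse, nfev = _fit_log_param(residual, p0, "permeability", bounds=(1e-3, 1e2))
    return FitReport("permeability", est, rse, sse, nfev)


def fit_correction_factor(
    observed: TransferProfile,
    config: ExperimentConfig,
    psd: ParticleSizeDistribution | None = None,
    f0: float = 0.02,
) -> FitReport:
    """Estimate the dissolution correction factor F from a particle profile.

    P must already be fixed in ``config.drug``.  Before fitting, the
    observed profile is compared against the dissolution-unlimited limit
    (the matched solution run, which is the F→∞ envelope): data faster
    than that envelope cannot be produced by any F and raise
    :class:`~twdiss.metrics.FitError` rather than silently returning a
    boundary estimate.
    """
    if psd is not None:
        config = replace(config, psd=psd)
    if config.psd is None:
        raise ValueError("fit_correction_factor needs a particle-size distribution")
    times = _check_times(observed, config)
    solution_cfg = replace(config, psd=None)
    sol = _observed_at(solution_cfg, times)
    if np.mean(observed.cumulative_percent - sol) > 1e-6:
        raise FitError(
            "observed transfer is faster than the dissolution-unlimited "
            "(solution) envelope; no correction factor can fit these data"
        )

    def residual(params):
        f = math.exp(params["log_value"].value)
        cfg = replace(config, correction_factor=f)
        return _observed_at(cfg, times) - observed.cumulative_percent

    est, rse, sse, nfev = _fit_log_param(residual, f0, "correction factor", bounds=(1e-6, 1e2))
    return FitReport("correction_factor", est, rse, sse, nfev)


def generate_noisy_profiles(
    result: TransferResult | TransferProfile,
    cv: float,
    n_replicates: int,
    seed: int | None = None,
) -> list[TransferProfile]:
    """Synthetic replicate profiles with multiplicative lognormal noise.

    Emulates bench sextuplicates: each observation is multiplied by a
    lognormal factor with coefficient of variation ``cv`` (percent) and
    unit mean, so the mean replicate profile converges to the input as
    the number of replicates grows.  Deterministic under a fixed seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    profile = result.observed_profile() if hasattr(result, "observed_profile") else result
    t = profile.times_min
    y = profile.cumulative_percent
    if cv == 0:
        return [TransferProfile(t.copy(), y.copy()) for _ in range(n_replicates)]
    rng = np.random.default_rng(seed)
    c = cv / 100.0
    sigma = math.sqrt(math.log1p(c * c))
    out = []
    for _ in range(n_replicates):
        factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=y.size)
        noisy = np.clip(y * factors, 0.0, 105.0)
        out.append(TransferProfile(t.copy(), noisy))
    return out


def mean_profile(profiles: list[TransferProfile]) -> TransferProfile:
    """Pointwise mean of replicate profiles sharing a common schedule."""
    t = profiles[0].times_min
    for p in profiles[1:]:
        if not np.array_equal(p.times_min, t):
            raise ValueError("replicates must share identical timepoints")
    y = np.mean([p.cumulative_percent for p in profiles], axis=0)
    return TransferProfile(t.copy(), y)
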