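"""Transfer-profile metrics: Weibull MDT, f1/f2 similarity, summaries.

The cumulative transfer profile of a run is characterised by fitting the
Weibull function

    Y_t = 100 * (1 - exp(-(t / MDT)**b))

whose scale parameter is the mean dissolution (transfer) time MDT and
whose shape parameter ``b`` captures curvature.  Pairs of profiles are
compared with the regulatory difference/similarity factors f1 and f2;
two profiles count as different only if both f1 > 15 and f2 < 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import lmfit


class FitError(RuntimeError):
    """Nonlinear fit failed; carries optimiser diagnostics in the message."""


class DegenerateProfileError(ValueError):
    """Profile carries too little information to analyse."""


class NotAttainedError(ValueError):
    """The requested transfer fraction is never reached by the profile."""


@dataclass
class TransferProfile:
    """Observed cumulative transfer: % of the initial amount vs time (min)."""

    times_min: np.ndarray
    cumulative_percent: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.cumulative_percent, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and percentages must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        # noisy bench replicates can slightly overshoot 100%
        if np.any(y < -1e-9) or np.any(y > 105.0):
            raise ValueError("cumulative percent must lie in [0, 100(+5 noise allowance)]")
        self.times_min = t
        self.cumulative_percent = y

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransferProfile":
        df = pd.read_csv(path)
        if list(df.columns) != ["time_min", "cumulative_percent"]:
            raise ValueError(
                "profile CSV must have columns time_min, cumulative_percent, "
                f"got {list(df.columns)}"
            )
        return cls(df["time_min"].to_numpy(), df["cumulative_percent"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_min": self.times_min, "cumulative_percent": self.cumulative_percent}
        ).to_csv(path, index=False)


@dataclass
class WeibullFit:
    """Result of fitting the Weibull transfer function to a profile."""

    mdt_hours: float
    shape: float
    residual_sse: float
    converged: bool
    nfev: int = 0

    @property
    def mdt_min(self) -> float:
        return self.mdt_hours * 60.0


def _weibull(t, mdt, b):
    return 100.0 * (1.0 - np.exp(-((t / mdt) ** b)))


def fit_weibull(profile: TransferProfile) -> WeibullFit:
    """Least-squares Weibull fit of a cumulative transfer profile.

    Unweighted least squares on the percent scale.  MDT is initialised at
    the (interpolated) first time the profile reaches 63.2% — the exact
    MDT if the data were Weibull — and the shape at 1; both are
    constrained positive.

    Raises
    ------
    DegenerateProfileError
        Fewer than 3 points or a flat profile (spread ≤ 5%).
    FitError
        Optimiser failure.
    """
    t = profile.times_min
    y = profile.cumulative_percent
    if t.size < 3:
        raise DegenerateProfileError("need at least 3 points to fit")
    if y.max() - y.min() <= 5.0:
        raise DegenerateProfileError("profile is flat (spread <= 5%)")
    if y.max() >= 63.2:
        mdt0 = float(np.interp(63.2, y, t)) if y[0] < 63.2 else float(t[0])
    else:
        mdt0 = float(t[-1])
    model = lmfit.Model(_weibull)
    params = model.make_params(
        mdt=dict(value=max(mdt0, 1e-3), min=1e-6),
        b=dict(value=1.0, min=1e-6),
    )
    out = model.fit(y, params, t=t)
    if not out.success:
        raise FitError(f"Weibull fit did not converge: {out.message}")
    return WeibullFit(
        mdt_hours=float(out.params["mdt"].value) / 60.0,
        shape=float(out.params["b"].value),
        residual_sse=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        nfev=int(out.nfev),
    )


@dataclass
class F1F2Result:
    f1: float
    f2: float
    different: bool

    @property
    def verdict(self) -> str:
        return "different" if self.different else "similar"


def f1_f2(
    reference: TransferProfile,
    test: TransferProfile,
    truncate_after_85: bool = False,
) -> F1F2Result:
    """Regulatory difference (f1) and similarity (f2) factors.

    ``f1 = 100·Σ|R_t−T_t| / ΣR_t`` and
    ``f2 = 50·log10(100·(1 + (1/n)Σ(R_t−T_t)²)^(−1/2))``, evaluated on the
    common timepoints of the two profiles.  The profiles are declared
    "different" only when both f1 > 15 and f2 < 50.

    Parameters
    ----------
    truncate_after_85 : bool
        If set, keep timepoints only up to one past the reference first
        exceeding 85% (the common pharmacopoeial convention); off by
        default, i.e. all shared scheduled timepoints are used.
    """
    common, ri, ti = np.intersect1d(
        reference.times_min, test.times_min, return_indices=True
    )
    if common.size < 3:
        raise ValueError("profiles share fewer than 3 common timepoints")
    r = reference.cumulative_percent[ri]
    tt = test.cumulative_percent[ti]
    if truncate_after_85:
        above = np.nonzero(r > 85.0)[0]
        if above.size:
            stop = min(above[0] + 1, r.size - 1)
            r, tt = r[: stop + 1], tt[: stop + 1]
    if r.sum() == 0:
        raise ZeroDivisionError("f1 undefined: reference profile sums to zero")
    f1 = 100.0 * np.abs(r - tt).sum() / r.sum()
    f2 = 50.0 * math.log10(100.0 * (1.0 + np.mean((r - tt) ** 2)) ** -0.5)
    return F1F2Result(f1=float(f1), f2=float(f2), different=(f1 > 15.0 and f2 < 50.0))


def time_to_fraction(result_or_profile, fraction: float) -> float:
    """First time (minutes) the cumulative transfer crosses ``fraction``.

    Works on the dense trajectory of a simulation result when given one
    (preferred — sub-sampling-interval resolution), or on an observed
    profile.  Linear interpolation between bracketing points; t=0 with
    zero transferred is the implicit starting point.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0, 1]")
    if fraction == 0.0:
        return 0.0
    if hasattr(result_or_profile, "cumulative_transferred_percent"):
        t = result_or_profile.time_min
        y = result_or_profile.cumulative_transferred_percent
    else:
        t = result_or_profile.times_min
        y = result_or_profile.cumulative_percent
    target = 100.0 * fraction
    t = np.concatenate([[0.0], t])
    y = np.concatenate([[0.0], y])
    above = np.nonzero(y >= target)[0]
    if above.size == 0:
        raise NotAttainedError(f"profile never reaches {target:.1f}%")
    j = above[0]
    if y[j] == target or j == 0:
        return float(t[j])
    return float(t[j - 1] + (target - y[j - 1]) * (t[j] - t[j - 1]) / (y[j] - y[j - 1]))


def mdt_ratio(low_dose, high_dose) -> float:
    """Ratio of fitted MDTs, larger-dose over smaller-dose.

    Quantifies the "mass effect": under non-sink conditions a larger
    deposited amount saturates the donor and slows apparent dissolution,
    pushing the ratio above 1.  Arguments are simulation results (their
    observed profiles are used) or observed profiles directly.
    """
    profiles = [
        x.observed_profile() if hasattr(x, "observed_profile") else x
        for x in (low_dose, high_dose)
    ]
    mdt_low = fit_weibull(profiles[0]).mdt_hours
    mdt_high = fit_weibull(profiles[1]).mdt_hours
    return mdt_high / mdt_low
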