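"""Polydisperse particle representation built from cascade-impactor data.

A cascade impactor (NGI) fractionates the aerosol into stages by
aerodynamic cut-off diameter.  Each stage is treated as a mono-disperse
bin of spherical particles whose geometric diameter follows from the
aerodynamic one via the particle density and shape factor:

    d_geo = d_aero * sqrt(k / rho)          (rho in g/cm³, unit reference)

Within a bin the particle number N is fixed at initialisation from the
deposited mass and the initial radius; as the bin dissolves, the shared
radius shrinks with the cube root of the remaining mass and the surface
area follows as N * 4πr².  Internally lengths are cm and masses µg
(1 µm = 1e-4 cm, 1 µg = 1e-6 g); density stays in g/cm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

UM_TO_CM = 1e-4
UG_TO_G = 1e-6

#: NGI calibrated stage cut-off diameters (µm) at 30 L/min, stages 1-7.
NGI_CUTOFFS_30LPM_UM = (11.7, 6.4, 3.99, 2.30, 1.36, 0.83, 0.54)

#: Density of micronised fluticasone propionate particles, g/cm³.
DEFAULT_PARTICLE_DENSITY = 1.37
#: Spherical particles.
DEFAULT_SHAPE_FACTOR = 1.0


class DegenerateInputError(ValueError):
    """Input carries no usable information (e.g. all stage masses zero)."""


def aero_to_geometric_diameter(
    d_aero: float, shape_factor: float = DEFAULT_SHAPE_FACTOR,
    density: float = DEFAULT_PARTICLE_DENSITY,
) -> float:
    """Convert an aerodynamic diameter to the geometric diameter.

    ``d_geo = d_aero * sqrt(k / rho)`` with density in g/cm³ (relative to
    the unit reference density).  Units of the returned diameter match the
    input's.
    """
    if d_aero <= 0 or shape_factor <= 0 or density <= 0:
        raise ValueError("d_aero, shape_factor and density must all be > 0")
    return d_aero * math.sqrt(shape_factor / density)


@dataclass
class ParticleBin:
    """One impactor stage modelled as N identical spherical particles.

    Masses in µg, radii in cm.  ``particle_count`` is frozen after
    initialisation; dissolution only reduces ``mass_remaining``.
    """

    stage_index: int
    aero_cutoff_um: float
    geo_radius_initial: float
    particle_count: float
    mass_initial: float
    mass_remaining: float

    def geometry_at_mass(
        self, mass_remaining: float | None = None,
        density: float = DEFAULT_PARTICLE_DENSITY,
    ) -> tuple[float, float]:
        """Radius (cm) and total surface area (cm²) at a given remaining mass.

        ``r = (3X / (4πρN))^(1/3)`` and ``SA = N·4πr²``; both are 0 for an
        exhausted bin.
        """
        x = self.mass_remaining if mass_remaining is None else mass_remaining
        if x < 0:
            raise ValueError(f"mass_remaining must be >= 0, got {x}")
        if x == 0 or self.particle_count == 0:
            return 0.0, 0.0
        r = (3.0 * x * UG_TO_G / (4.0 * math.pi * density * self.particle_count)) ** (1.0 / 3.0)
        sa = self.particle_count * 4.0 * math.pi * r * r
        return r, sa


def bin_geometry_at_mass(
    bin_: ParticleBin, density: float = DEFAULT_PARTICLE_DENSITY
) -> tuple[float, float]:
    """Radius and surface area of a bin at its current remaining mass."""
    return bin_.geometry_at_mass(density=density)


@dataclass
class ParticleSizeDistribution:
    """Ordered collection of particle bins plus shared material constants."""

    bins: list[ParticleBin]
    total_mass: float
    density: float = DEFAULT_PARTICLE_DENSITY
    shape_factor: float = DEFAULT_SHAPE_FACTOR

    def __post_init__(self) -> None:
        if not self.bins:
            raise DegenerateInputError("a PSD needs at least one bin")
        cutoffs = [b.aero_cutoff_um for b in self.bins]
        if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("bin cut-off diameters must be strictly decreasing")
        mass = sum(b.mass_initial for b in self.bins)
        if not math.isclose(mass, self.total_mass, rel_tol=1e-9):
            raise ValueError(
                f"bin masses sum to {mass} µg but total_mass is {self.total_mass} µg"
            )

    # -- convenience views ------------------------------------------------
    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass_initial for b in self.bins])

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.geo_radius_initial for b in self.bins])

    @property
    def counts(self) -> np.ndarray:
        return np.array([b.particle_count for b in self.bins])

    def mmad(self) -> float:
        """Mass-median aerodynamic diameter (µm) of the binned distribution.

        Log-linear interpolation of the cumulative mass-undersize curve at
        the stage cut-offs; stages are the mass between consecutive
        cut-offs, so the undersize at cut-off i is the mass on all finer
        stages.
        """
        cutoffs = np.array([b.aero_cutoff_um for b in self.bins])
        masses = self.masses
        undersize = np.concatenate([np.cumsum(masses[::-1])[::-1][1:], [0.0]])
        frac = undersize / masses.sum()
        # ascending order for interpolation
        x = np.log(cutoffs[::-1])
        y = frac[::-1]
        if y[-1] < 0.5:  # more than half the mass above the coarsest cut-off
            return float(cutoffs[0])
        if y[0] > 0.5:
            return float(cutoffs[-1])
        return float(np.exp(np.interp(0.5, y, x)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [b.stage_index for b in self.bins],
                "cutoff_um": [b.aero_cutoff_um for b in self.bins],
                "mass_ug": [b.mass_initial for b in self.bins],
            }
        )


def build_psd(
    stage_masses: Iterable[tuple[int, float, float]],
    delivered_mass: float,
    density: float = DEFAULT_PARTICLE_DENSITY,
    shape_factor: float = DEFAULT_SHAPE_FACTOR,
) -> ParticleSizeDistribution:
    """Build a PSD from stage depositions, rescaled to the delivered dose.

    The impactor measures relative stage depositions; the dissolution
    experiment uses a (generally different) total amount.  Stage masses
    are rescaled proportionally so their sum equals ``delivered_mass``,
    preserving the measured distribution shape.  Per bin the particle
    number is fixed as ``N = X₀ / ((4/3)πr³ρ)`` with ``r`` from the
    aerodynamic→geometric conversion of the stage cut-off.

    Parameters
    ----------
    stage_masses : iterable of (stage_index, cutoff_um, mass_ug)
        One entry per impactor stage; zero-mass stages are dropped.
    delivered_mass : float
        Total drug amount in the experiment, µg.
    """
    rows = [(int(s), float(c), float(m)) for s, c, m in stage_masses]
    if delivered_mass <= 0:
        raise ValueError("delivered_mass must be > 0")
    total = sum(m for _, _, m in rows)
    if total <= 0:
        raise DegenerateInputError("all stage masses are zero")
    scale = delivered_mass / total
    bins: list[ParticleBin] = []
    for stage, cutoff, mass in rows:
        if mass == 0:
            continue
        d_geo_cm = aero_to_geometric_diameter(cutoff, shape_factor, density) * UM_TO_CM
        r = d_geo_cm / 2.0
        x0 = mass * scale
        n = x0 * UG_TO_G / ((4.0 / 3.0) * math.pi * r**3 * density)
        bins.append(
            ParticleBin(
                stage_index=stage,
                aero_cutoff_um=cutoff,
                geo_radius_initial=r,
                particle_count=n,
                mass_initial=x0,
                mass_remaining=x0,
            )
        )
    return ParticleSizeDistribution(
        bins=bins, total_mass=delivered_mass, density=density, shape_factor=shape_factor
    )


def scale_psd(psd: ParticleSizeDistribution, factor: float) -> ParticleSizeDistribution:
    """Rescale every particle diameter by ``factor`` at constant mass.

    Models hypothetical formulations whose size distribution is a uniform
    multiple of a measured one: cut-offs and radii scale by ``factor``,
    bin masses are unchanged, so particle counts scale by ``factor**-3``.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    bins = [
        replace(
            b,
            aero_cutoff_um=b.aero_cutoff_um * factor,
            geo_radius_initial=b.geo_radius_initial * factor,
            particle_count=b.particle_count / factor**3,
        )
        for b in psd.bins
    ]
    return ParticleSizeDistribution(
        bins=bins,
        total_mass=psd.total_mass,
        density=psd.density,
        shape_factor=psd.shape_factor,
    )


def synthetic_psd(
    mmad: float = 3.7,
    gsd: float = 1.8,
    cutoffs: Sequence[float] = NGI_CUTOFFS_30LPM_UM,
    total_mass: float = 23.0,
    density: float = DEFAULT_PARTICLE_DENSITY,
    shape_factor: float = DEFAULT_SHAPE_FACTOR,
    seed: int | None = None,
    jitter_cv: float = 0.0,
) -> ParticleSizeDistribution:
    """Generate an impactor-style PSD from a lognormal aerodynamic distribution.

    Emulates the stage-deposition table of a dry-powder formulation: the
    aerodynamic mass distribution is lognormal with mass-median diameter
    ``mmad`` and geometric standard deviation ``gsd``, integrated
    analytically between consecutive stage cut-offs.  The coarsest stage
    collects everything above its cut-off; mass finer than the last
    cut-off is discarded (it escapes to the micro-orifice collector) and
    the stage masses are renormalised to ``total_mass``.

    Deterministic for fixed arguments; with ``jitter_cv`` > 0 a seeded
    multiplicative lognormal jitter perturbs the stage masses (then
    renormalises) to emulate run-to-run impactor variability.
    """
    if gsd <= 1:
        raise ValueError("gsd must be > 1")
    if mmad <= 0 or total_mass <= 0:
        raise ValueError("mmad and total_mass must be > 0")
    cut = np.asarray(cutoffs, dtype=float)
    if cut.ndim != 1 or cut.size < 1 or np.any(np.diff(cut) >= 0) or np.any(cut <= 0):
        raise DegenerateInputError("cutoffs must be a strictly decreasing positive list")
    sigma = math.log(gsd)
    dist = stats.lognorm(s=sigma, scale=mmad)
    cdf = dist.cdf(cut)  # mass-undersize fraction at each cut-off
    fractions = np.empty_like(cut)
    fractions[0] = 1.0 - cdf[0]
    fractions[1:] = cdf[:-1] - cdf[1:]
    if jitter_cv > 0:
        rng = np.random.default_rng(seed)
        cv = jitter_cv / 100.0
        s = math.sqrt(math.log1p(cv * cv))
        fractions = fractions * rng.lognormal(-0.5 * s * s, s, size=fractions.size)
    if fractions.sum() <= 0:
        raise DegenerateInputError("no mass falls on the supplied stages")
    masses = total_mass * fractions / fractions.sum()
    rows = [(i + 1, float(c), float(m)) for i, (c, m) in enumerate(zip(cut, masses))]
    return build_psd(rows, delivered_mass=total_mass, density=density, shape_factor=shape_factor)


# -- stage-deposition CSV I/O ---------------------------------------------

_STAGE_COLUMNS = ["stage", "cutoff_um", "mass_ug"]


def read_stage_table(path: str | Path) -> list[tuple[int, float, float]]:
    """Read a stage-deposition CSV with columns stage, cutoff_um, mass_ug."""
    df = pd.read_csv(path)
    if list(df.columns) != _STAGE_COLUMNS:
        raise ValueError(
            f"stage table must have columns {_STAGE_COLUMNS}, got {list(df.columns)}"
        )
    return [tuple(row) for row in df.itertuples(index=False)]


def write_stage_table(psd: ParticleSizeDistribution, path: str | Path) -> None:
    """Write a PSD back to the stage-deposition CSV format."""
    psd.to_frame().to_csv(path, index=False)
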