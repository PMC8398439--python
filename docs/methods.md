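# Methods

## Model structure

The assay is modelled as a two-compartment system separated by a porous
membrane of area `S_M`. State variables, all in µg: the undissolved
mass per particle-size bin `X_i`, the dissolved donor amount `X_d`, the
receptor amount `Y`, and the cumulatively removed (sampled) amount `S`.
Their sum is the delivered dose at all times.

**Dissolution.** Each cascade-impactor stage contributes one bin of
`N_i` identical spheres. The Nernst–Brunner rate uses the particle
radius as the diffusion-layer thickness, so the bin rate reduces to

    dX_i/dt = −F · D · 4π N_i r_i(t) · (C_s − X_d/V_d),

with `r_i = (3 X_i / (4πρN_i))^{1/3}`. The rate therefore vanishes
smoothly as a bin empties. `N_i` is fixed at initialisation from the
stage mass and the geometric radius converted from the stage's
aerodynamic cut-off (`d_geo = d_aero·√(k/ρ)`); dissolving mass shrinks
the shared radius with the cube root of remaining mass. The correction
factor `F` multiplies the rate and absorbs stagnant-layer thickness,
particle/lactose agglomeration and the reduced water-accessible surface
of particles pressed between filter and membrane — effects the
free-suspension Nernst–Brunner picture does not capture. The sign is
kept literal: a transiently supersaturated donor (`X_d/V_d > C_s`)
re-deposits mass onto the particles.

**Membrane transfer.** Fick's first law with a lumped permeability:
`dY/dt = P·S_M·(X_d/V_d − Y/V_r)`, and the donor balance
`dX_d/dt = −Σ dX_i/dt − dY/dt`.

**Sampling.** At each scheduled time a volume `V_s` is withdrawn from
the receptor and replaced with fresh medium, leaving `V_r` constant:
`Y ← Y·(1 − V_s/V_r)`, `S ← S + Y·V_s/V_r`. The observation reported at
sampling time `t_k` is the bench convention: the receptor content just
before the sample plus everything previously removed, as a percentage
of the dose, `100·(Y(t_k⁻)+S(t_k⁻))/X_initial`. Samples perturb the
system — they restore the transmembrane gradient — which is why the
sampling volume is itself a design variable.

**Volume matching.** Both compartments have near-constant
cross-sections over the working height, so equal fluid levels follow
from an affine relation: donor height `(V_d+V_f)/0.47` mm (the filter
paper volume `V_f = 0.118 mL` counts toward the column), receptor fill
`V_r = height·0.35 + 0.86 + W_v` with 0.86 mL of dead volume below the
membrane and `W_v ≈ 0.1 mL` wetting the membrane. The measured pairings
0.58→1.5 mL and 3.0→3.31 mL are reproduced to ≈1%; the implementation
returns the unrounded value.

## Units and parameters

Internal units are µg, mL (=cm³), cm and hours; schedule times are
minutes at every interface, MDT is stored in hours with a minutes
accessor. Defaults describe micronised fluticasone propionate:

| parameter | default | units | origin |
|---|---|---|---|
| particle density ρ | 1.37 | g/cm³ | database value for the compound |
| shape factor k | 1 | – | spherical particles |
| diffusion coefficient D | 0.0223 | cm²/h | 0.0003714 cm²/min; consistent with Hayduk–Laudie at η≈0.69 cP, V_M≈380 cm³/mol |
| permeability P | 0.289 | cm/h | fitted to bench solution-diffusion profiles |
| correction factor F | 0.0244 | – | fitted to a bench particle-dissolution profile |
| solubility C_s | 5.3 | µg/mL | 0.5% Tween 80 at 37 °C |
| membrane area S_M | 4.52 | cm² | 24 mm Transwell insert metrology |

The source literature prints D with inconsistent units (a length/time);
dimensional analysis and the Hayduk–Laudie estimate identify it as
cm²/min, and the value is carried here in cm²/h. The Hayduk–Laudie
helper uses the literature viscosity exponent 1.14 (a variant exponent
is selectable). Both interpretations are logged when a run resolves its
parameters.

## Numerical scheme

Between consecutive sampling times the ODE system is integrated with
LSODA (rtol 1e-9, atol 1e-12 µg), with hard stops at every sampling
event; the jump is applied exactly. The donor balance is written so the
per-step rates cancel identically, making `X_d+Y+S+ΣX_i` a discrete
invariant — conservation holds to ~1e-15 relative, asserted at 1e-9.

Bin exhaustion is the one numerical hazard: `dX/dt ∝ −X^{1/3}` reaches
zero in finite time with unbounded curvature, which stalls adaptive
steppers. Each active bin therefore carries a terminal solver event at
1e-6 of its initial mass; when hit, integration stops exactly at the
crossing, the bin is frozen (its rate pinned to zero), and the solver
restarts. The ≤1e-6-relative residual stays in the bin rather than
being zeroed, preserving exact mass balance; its effect on the profile
is far below observable resolution.

Two independent cross-checks guard the integrator: a piecewise
closed-form solution for solution-only runs (the linear two-compartment
system relaxes to the `V_r/(V_d+V_r)` equilibrium share with rate
`P·S_M·(1/V_d+1/V_r)`), matched to 1e-6 relative; and a fixed-step
explicit-Euler path (default 0.01 min) for particle runs, matched to
<0.5 percentage points on the observed profile. The Euler stepper
floors overshot bins at zero and returns the overshoot to the donor
pool so it, too, conserves mass exactly.

Dense output records 40 points per sampling interval; event times
appear twice (pre- and post-sample state).

## Profile metrics

Weibull fits are unweighted least squares on the percent scale (lmfit),
initialised at the interpolated 63.2% crossing with shape 1, both
parameters constrained positive. f1/f2 are computed over all shared
scheduled timepoints by default; the pharmacopoeial
one-point-past-85% truncation is available but off, since the assay
comparisons here use the full schedule. Two profiles are "different"
only if both f1 > 15 and f2 < 50.

## Parameter fitting

`P` is fitted on a solution run (dissolution drops out), then `F` on a
particle run with `P` fixed — a deliberately sequential, identifiable
design. Both are 1-D unweighted least squares on cumulative-%, with the
parameter log-transformed for positivity and bounded to the physically
sensible range; the relative standard error is the standard error of
the log-parameter from the linearised covariance at the optimum. Before
fitting `F`, the observed profile is checked against the matched
solution run, which is the `F→∞` envelope: data faster than that
envelope are rejected as infeasible rather than silently producing a
boundary estimate.

## Synthetic data generators

Two generators stand in for bench inputs; both are deterministic under
fixed arguments/seeds.

**Impactor PSD.** A lognormal aerodynamic mass distribution (default
MMAD 3.7 µm, GSD 1.8 — a fine-particle DPI formulation) is integrated
analytically between NGI stage cut-offs (11.7/6.4/3.99/2.30/1.36/
0.83/0.54 µm, the 30 L/min calibration), the sub-cut-off tail dropped,
and stage masses renormalised to the delivered dose (default 23 µg).
Optional seeded lognormal jitter emulates run-to-run impactor
variability. What it does not emulate: intra-stage size spread (each
stage is mono-disperse at its cut-off), lactose-carrier agglomerates,
and any deviation of the true formulation's stage pattern from a
lognormal — so simulation studies built on it reproduce *directional*
bench findings (orderings, verdict flips, ratio rankings), not specific
fitted values of a particular commercial formulation.

**Noisy replicates.** Bench sextuplicates are emulated by multiplying
each observation with unit-mean lognormal noise of a chosen CV (values
capped at 105%, matching assay-style overshoot); the replicate mean
converges to the input profile.

## Design choices

- Stage masses are rescaled *proportionally* to the delivered amount
  (preserving the measured distribution shape); an additive adjustment
  would distort bin ratios.
- Dose changes scale particle *number*, not particle size: counts and
  masses scale together, radii stay put.
- A PSD scale factor multiplies all diameters at constant mass
  (counts scale by factor⁻³), modelling formulations that differ only
  in size.
- The particle-size resolution metric of the scenario study is the MDT
  spread across size factors relative to the solution-run MDT (the
  assay's diffusion baseline). Both tested media are
  dissolution-limited, so spread relative to the mid formulation is
  nearly solubility-independent; what improves at low solubility is the
  separation relative to what the assay could resolve at all.
- The mass-effect scenarios are (V_d, V_r, V_s) = (0.58, 1.5, 0.5),
  (3.0, 3.31, 0.5), (3.0, 3.31, 1.0) and (3.0, 3.31, 2.0) mL, the
  ratio reported is MDT(30 µg)/MDT(10 µg).
- Scenario runners never mutate the base configuration and contain no
  randomness; re-runs are bit-identical.

## Problem sizes

The test suite and the acceptance script run desk-scale problems: 7-bin
PSDs, 9- or 13-point sampling schedules, sweeps of ≤6 values, noisy
parameter-recovery over 20 seeds of 6 replicates. A single particle
simulation integrates ~9 states over 24 h of assay time in ~0.1 s.

## Known limitations

- `F` lumps geometry, agglomeration and surface-accessibility effects;
  it is formulation- and apparatus-specific and must be refitted when
  either changes.
- No spatial model of the stagnant layer, filter microstructure or
  membrane pore field; concentrations are compartment-homogeneous
  (the receptor is assumed well-stirred).
- Mono-disperse bins at stage cut-offs; no intra-bin evolution of the
  size distribution.
- The observation model assumes instantaneous sampling and replacement
  and no analytical error; noise is only introduced explicitly via the
  replicate generator.
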