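# Methods

`taxisort` models a fluidic device that separates swimming nematodes
(*Caenorhabditis elegans*-like animals) by gravitaxis competence.  The
device is a row of ten vertical columns filled with a working fluid
slightly denser than the animals, bridged by a feed conduit below and a
collection conduit above, both pumped left to right.  Taxis-competent
animals thrust steadily downward, overcome buoyancy, and discharge through
the feed line; taxis-deficient animals reorient their thrust at random,
gain nothing from it on average, rise with buoyancy, and discharge through
the collection line.  The package implements the four layers of that
story: the single-animal force balance, the device flow field, the
population simulation, and the sorting statistics.

## 1. Force balance (`taxisort.physics`)

Each animal is modelled as an equivalent rigid sphere of Stokes radius
`r_s` moving at velocity `U` relative to the local fluid.  With particle
Reynolds numbers well below one, three forces are in quasi-static balance:

    (rho_w - rho_f) V_w g  +  6 pi mu r_s U  +  F_p  =  0

* `W = (rho_f - rho_w) V_w g` — the **reduced weight**, stored signed with
  +z up, so `W > 0` means the animal floats.
* `C_f = 6 pi mu r_s` — the Stokes drag coefficient.
* `F_p` — propulsive thrust along the body heading.

Every estimator is a rearrangement of this identity:

* `estimate_stokes_radius`: a randomly reorienting strain has `F_p ~ 0`
  over times much longer than its persistence time, so its settling speed
  gives `r_s = (rho_w - rho_f) V_w g / (6 pi mu U)`.
* `estimate_thrust`: subtracting the balance for the passive settler from
  that for the directed swimmer cancels the (poorly pinned) reduced
  weight, leaving `F_p = 6 pi mu r_s (U_directed - U_passive)`.  The
  single-strain form (`thrust_single_strain`) is provided but flagged as
  sensitive to the density contrast.  With the canonical inputs (`mu` =
  1.0 mPa s, `r_s` = 0.37 mm, speed difference 0.12 mm/s) the estimate is
  0.84 nN.
* `apparent_diffusion`: `D_app = U^2 tau_r / 3`, the long-time diffusivity
  of a self-propelled particle whose heading decorrelates exponentially
  with persistence time `tau_r`.

Canonical parameter values used throughout (all configurable):
body volume 5.96e-12 m^3, body density 1.08 g/mL, Stokes radius 0.37 mm,
thrust 0.81 nN, reorientation time 4.65 s; plain buffer density
1.00 g/mL and viscosity 1.0 mPa s; working colloid blend density
1.09 g/mL and viscosity 4.78 mPa s; g defaults to 9.81 m/s^2.  The
package works in strict SI internally; configuration values carry unit
suffixes parsed at the boundary (`taxisort.units`), because the inputs
naturally mix g/mL, mm/s, nN and minutes.

Known tensions in the canonical inputs, deliberately left exposed rather
than resolved: the settling numbers above imply `r_s` = 0.48 mm rather
than the quoted 0.37 mm (the exact density contrast and viscosity behind
the quoted value are not pinned); the Reynolds number computed with
`r_s` = 0.37 mm and 0.64 mm/s in plain buffer is ~0.24, above the nominal
"Re < 0.1" regime (the appropriate length scale may be the body radius,
which is much smaller); and the ideal volume-additive density of the
1 : 0.315 buffer/colloid blend is 1.072 g/mL against a measured
1.09 g/mL, so `mixture_density` is documented as an estimate only and the
measured density is what the scenarios use.

## 2. Unit-cell Stokes flow (`taxisort.flow`)

The device-scale Reynolds number is `rho U L / mu ≈ 1090 × 5e-4 × 3e-3 /
4.78e-3 ≈ 0.34`, so the flow is solved in the Stokes (creeping) limit.
The domain is a 2-D x–z unit cell — one column plus half a wall pitch of
conduit on each side — with the 3 mm depth treated as invariant.  This
replaces a full 3-D CFD computation; its diagnostics are therefore
order-of-magnitude statements about the device, not calibrated
predictions.

Discretisation: stream-function/vorticity form (`lap psi = -omega`,
`lap omega = 0`) on a regular grid (default spacing 0.1 mm), red-black SOR
(factor 1.7) with Jensen's second-order wall-vorticity closure
(`omega_w = (7 psi_w - 8 psi_1 + psi_2) / 2h^2`, exact for the cubic
Poiseuille stream function; Thom's first-order formula is the fallback at
nodes without two fluid neighbours along the normal, and wall updates are
under-relaxed by 0.5).  Convergence: normalised residuals of both
equations below 1e-8, iteration cap 2e5; non-convergence raises an error
carrying the residual history.  An SOR factor of 1.9 destabilises the
wall-vorticity coupling on small domains, which is why 1.7 is the
default.

Boundary conditions: fully developed plane-Poiseuille profiles (mean
0.5 mm/s) at all four conduit ports; no-slip walls; zero net flux through
the column imposed by giving both column walls the same stream-function
constant.  The zero-flux condition encodes the observed absence of
conduit-to-conduit crossflow under equal-rate dual-syringe pumping, not an
assumption of convenience.  On the 0.1 mm grid the 0.55 mm wall half-pitch
is not an integer number of cells; wall indices snap to the nearest node,
shifting the column ~0.05 mm off-centre in the periodic cell, which is
immaterial to every reported diagnostic.

Diagnostics at the defaults: peak circulation speed in the column
~3.5e-4 m/s; the slice-maximum speed decays roughly exponentially with
depth and falls below 1% of its mouth value ~2.9 mm into the column
(about one column width), consistent with the expected confinement of
junction-driven vortices.  The 1% threshold is a package choice (the
physical statement is only "same order as the conduit width") and is
configurable and recorded in output.  Port-to-port flux balance holds to
machine precision, far inside the 3% experimental bound.  A zero column
height degenerates the domain to a straight channel and reproduces plane
Poiseuille exactly; `build_geometry` still rejects zero heights because
they are not a device.

`analytic_fallback_field` offers a vortex-free piecewise field (Poiseuille
conduits, still columns) for fast simulations and degenerate references.

## 3. Agent simulation (`taxisort.sim`)

Overdamped (massless) dynamics: each particle's velocity is the algebraic
force balance `v = u_fluid + (F_p n_hat + W z_hat) / C_f`, integrated by
explicit Euler with `dt` capped at `0.1 min(tau_r, cell / v_max)` (refused
otherwise).  Positions are 3-D; the planar field is sampled at (x, z) with
x wrapped by the column pitch, and y-motion (thrust only) reflects at the
depth walls.  Keeping the heading 3-D preserves the 3-D diffusivity
`U^2 tau_r / 3` exactly while using the 2-D field.

Taxis-deficient particles resample their heading uniformly on the unit
sphere every 4.65 s (fixed interval by default, matching the modelled
behaviour; an exponential scheme with the same mean is available as the
alternative physical reading of `tau_r`).  Competent particles keep a
fixed downward heading.  Optional quiescence is a two-state Markov switch
(onset hazard, mean bout length) that zeroes thrust without touching
weight or drag.

Walls are specular with the heading preserved, applied to the fluid
domain eroded by a **geometric body radius** (default 0.05 mm, an adult's
body half-width).  Two facts make this the load-bearing design choice of
the module:

* A point particle pushed against a no-slip wall samples zero fluid
  velocity and freezes; a finite body rides the conduit flow at one
  radius off the wall and is discharged normally.
* The radius must be the geometric half-thickness, *not* the 0.37 mm
  Stokes radius.  The buoyant rise speed (W/C_f ≈ 0.017 mm/s) is an order
  of magnitude below the junction-vortex downwelling (~0.3 mm/s), so a
  body held 0.37 mm off every wall can never ascend a column: in that
  configuration zero deficient particles reach the top.  Real animals
  escape along the near-wall layer where the downwelling vanishes, and
  the geometric radius restores exactly that route.  With it, ~98% of
  deficient particles reach the collection line within 30 minutes while
  every competent particle exits through the feed line.

Injection defaults to a pulse distributed uniformly over the feed-inlet
cross-section at t = 0 (the physical release protocol is not specified
beyond "introduced through the bottom feed conduit"); a distributed
feed-line mode exists.  `max_time` defaults to 1800 s, the device's
operating window; timed-out particles are reported separately, never
dropped.  All randomness flows through one seeded NumPy generator, and a
zero-hazard quiescence model consumes no draws, so it is bit-identical to
no model at all.

Bordertaxis (hydrodynamic wall attraction) is *not* modelled beyond the
geometric wall interaction; the near-wall escape route described above is
a consequence of the flow field, not a behavioural bias.

## 4. Sorting statistics (`taxisort.metrics`)

With `N^C_0` competent animals in and `N^C_b` of them discharged at the
bottom, and `N^D_0` deficient in with `N^D_T` at the top:

    eps_C = N^C_b / N^C_0        eps_D = N^D_T / N^D_0
    S_p   = N^D_T / (N^D_T + N^C_T)

Specificity with an empty top outlet is signalled as undefined, not zero.
These ratio forms are forced by the definitional wording of the source
experiments (the display equations themselves survive only as figure
placeholders); the same applies to the cumulative multi-round formula.
Re-sorting is applied to the top-collected fraction after a feeding
recovery, so the cumulative competent recovery after K rounds is
`1 - prod_k (1 - eps_k)` — verified in the tests against an exhaustive
enumeration of the per-round outcome tree.

The efficiency decline over residence time is captured by a
four-parameter logistic `eps(t) = a / (1 + exp(-b (t - d))) + c` (with
`b < 0`: early plateau `a + c`, late plateau `c`, midpoint `d` minutes).
The curve is invariant under `(a, b, c) -> (-a, -b, a + c)`, so fits are
canonicalised to `a >= 0`.  Fitting is multi-start nonlinear least
squares; recovery tests at noise sigma = 0.01 bound each parameter's bias
below 5%.  The published coefficient set (a = 0.49, b = -3.29 /min,
c = 0.41, d = 3.3 min) is used as a recovery target, not as a correctness
oracle: its midpoint sits oddly against the reported stable first 20
minutes, suggesting an ambiguous time origin in the original fit.

`two_sample_t_from_summary` computes the gait-frequency comparison from
summary statistics; Welch two-tailed is the default with pooled and
one-tailed variants, because the published p = 0.005 sits between the
one-tailed (~0.006) and two-tailed (~0.011) values of the printed
summaries and the convention is unstated.

## 5. Synthetic tracks (`taxisort.synth`)

Generators emulate the two camera assays at 16 frames/s: settling tracks
(straight downward drift, per-animal speed Normal(U, sd), isotropic
Gaussian position noise, default sd 0.05 mm standing in for an unstated
pixel scale) and run-and-tumble tracks (constant speed, uniform-sphere
headings, exponential waiting times by default).  The published
±0.02 mm/s on the settling speeds is read as the standard error of the
mean of N = 30, so the per-animal spread defaults to 0.02·sqrt(30) mm/s.
`estimate_tau_r` fits `A exp(-lag/tau)` to the ensemble heading
autocorrelation over lags ≤ 3 tau (window iterated once) — the
autocorrelation reading of "persistence time"; a bout-duration reading
would be an alternative estimator.  Non-decaying autocorrelation returns
an infinite sentinel.

What the generators do **not** contain — body undulation, tracking
dropouts, wall effects, camera calibration — bounds what passing
round-trip tests show: the estimators are consistent under the stated
statistical model of the assays, not validated against real video.

## 6. Problem sizes and tolerances used in the tests

The shipped suite solves the unit cell at the reported 0.1 mm grid,
simulates the full 600 + 600 standard mixture over five seeds, and runs
the quiescence sweep at 500 particles per hazard level on a two-column
device (columns shortened to 6 mm so that the rise dynamics, not the
column length, set the cost).  Monte-Carlo assertions use 3-sigma bands
computed from the ensembles themselves; grid-convergence checks use one
halving step on a reduced single-column geometry.  Free-space ensembles
of 400–600 particles make the diffusion/drift comparisons sharp to a few
percent.

## 7. Known limitations

* The flow model is planar; depth-dependent (y) shear and the weakening
  of the junction vortices near the front/back walls are absent.  The
  simulation consequently over-weights the mid-plane flow for particles
  at all depths.
* Particles do not couple back to the fluid and do not interact.
* The wall interaction is purely geometric; lubrication forces and the
  hydrodynamic torque behind bordertaxis are not modelled.
* Quiescence is a homogeneous two-state process; real pause/coil bouts
  have heavier-tailed durations and age with time off food.
* The logistic decline is a descriptive fit, not a mechanistic link
  between the quiescence model of §3 and measured efficiency.
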