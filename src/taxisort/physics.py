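"""Quasi-static force balance for a swimming or settling nematode.

A worm in a viscous bath is modelled as an equivalent rigid sphere of
Stokes radius ``r_s`` moving at velocity ``U`` relative to the local fluid.
At the relevant Reynolds numbers (Re << 1) inertia is negligible and three
forces are in quasi-static balance along each axis:

* reduced weight ``W = (rho_f - rho_w) V_w g`` (signed, +z up: positive
  means the body floats),
* Stokes drag ``-C_f U`` with drag coefficient ``C_f = 6 pi mu r_s``,
* propulsive thrust ``F_p n_hat`` along the body heading.

Every estimator in this module is an algebraic rearrangement of that
balance.  Sign convention throughout the package: +z is up, gravity acts
along -z.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

G_STANDARD = 9.81  # m s^-2; configurable everywhere it is used


@dataclass(frozen=True)
class FluidMedium:
    """Bathing liquid: density (kg m^-3) and dynamic viscosity (Pa s)."""

    density: float
    dynamic_viscosity: float
    label: str = ""

    def __post_init__(self):
        if not self.density > 0:
            raise InvalidInputError(f"fluid density must be > 0, got {self.density}")
        if not self.dynamic_viscosity > 0:
            raise InvalidInputError(
                f"dynamic viscosity must be > 0, got {self.dynamic_viscosity}"
            )


@dataclass(frozen=True)
class WormBody:
    """Passive body properties: volume (m^3), density (kg m^-3), Stokes
    radius (m).  ``stokes_radius`` may be None while it is being estimated."""

    volume: float
    density: float
    stokes_radius: float | None = None

    def __post_init__(self):
        if not self.volume > 0:
            raise InvalidInputError(f"worm volume must be > 0, got {self.volume}")
        if not self.density > 0:
            raise InvalidInputError(f"worm density must be > 0, got {self.density}")
        if self.stokes_radius is not None:
            if not self.stokes_radius > 0:
                raise InvalidInputError(
                    f"Stokes radius must be > 0, got {self.stokes_radius}"
                )
            if self.stokes_radius >= 1e-2:
                raise InvalidInputError(
                    f"Stokes radius {self.stokes_radius} m exceeds the 1 cm sanity bound"
                )


@dataclass(frozen=True)
class BehaviorParams:
    """Active-locomotion parameters.

    mode:
        ``directed_down`` -- constant thrust along -z (taxis-competent),
        ``random_reorient`` -- thrust direction resampled with persistence
        time ``reorientation_time`` (taxis-deficient), or ``passive``.
    reorientation_scheme:
        ``fixed_interval`` resamples exactly every tau_r seconds;
        ``exponential`` draws exponential waiting times with mean tau_r.
    gait_frequency:
        optional undulation frequency (Hz) used for thrust rescaling.
    """

    thrust_magnitude: float = 0.0
    mode: str = "passive"
    reorientation_time: float | None = None
    reorientation_scheme: str = "fixed_interval"
    gait_frequency: float | None = None

    def __post_init__(self):
        if self.thrust_magnitude < 0:
            raise InvalidInputError("thrust magnitude must be >= 0")
        if self.mode not in ("directed_down", "random_reorient", "passive"):
            raise InvalidInputError(f"unknown behavior mode {self.mode!r}")
        if self.mode == "random_reorient":
            if self.reorientation_time is None or not self.reorientation_time > 0:
                raise InvalidInputError(
                    "random_reorient mode requires reorientation_time > 0"
                )
        if self.reorientation_scheme not in ("fixed_interval", "exponential"):
            raise InvalidInputError(
                f"unknown reorientation scheme {self.reorientation_scheme!r}"
            )


@dataclass(frozen=True)
class ForceBudget:
    """Signed force budget of one particle.

    reduced_weight: net of gravity and buoyancy, +z up (positive = floats).
    drag_coefficient: C_f = 6 pi mu r_s (N s / m).
    thrust: 3-vector (N).
    """

    reduced_weight: float
    drag_coefficient: float
    thrust: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if not self.drag_coefficient > 0:
            raise InvalidInputError("drag coefficient must be > 0")
        object.__setattr__(self, "thrust", np.asarray(self.thrust, dtype=float))
        if self.thrust.shape != (3,):
            raise InvalidInputError("thrust must be a 3-vector")


def buoyant_net_force(worm: WormBody, fluid: FluidMedium, g: float = G_STANDARD) -> float:
    """Reduced weight ``(rho_f - rho_w) V_w g`` (N, +z up).

    Positive when the fluid is denser than the worm (the worm rises).
    """
    if not worm.volume > 0:
        raise InvalidInputError("worm volume must be > 0")
    return (fluid.density - worm.density) * worm.volume * g


def drag_coefficient(fluid: FluidMedium, r_s: float) -> float:
    """Stokes drag coefficient ``C_f = 6 pi mu r_s`` (N s m^-1)."""
    if r_s < 0:
        raise InvalidInputError(f"Stokes radius must be >= 0, got {r_s}")
    return 6.0 * math.pi * fluid.dynamic_viscosity * r_s


def estimate_stokes_radius(
    settling_speed: float,
    worm: WormBody,
    fluid: FluidMedium,
    g: float = G_STANDARD,
) -> float:
    """Stokes radius from the passive settling speed of a randomly
    reorienting strain.

    Over times much longer than the reorientation time the randomly
    oriented thrust averages out (F_p ~ 0), so the force balance reduces to
    ``(rho_w - rho_f) V_w g = 6 pi mu r_s U`` and

        r_s = (rho_w - rho_f) V_w g / (6 pi mu U).

    Requires the worm to be denser than the fluid and U > 0 (downward
    settling speed, given as a positive magnitude).
    """
    if not settling_speed > 0:
        raise InvalidInputError("settling speed must be > 0")
    if not worm.density > fluid.density:
        raise InvalidInputError(
            "worm must be denser than the fluid to settle "
            f"(rho_w={worm.density}, rho_f={fluid.density})"
        )
    w = (worm.density - fluid.density) * worm.volume * g
    return w / (6.0 * math.pi * fluid.dynamic_viscosity * settling_speed)


def estimate_thrust(
    u_directed: float,
    u_passive: float,
    r_s: float,
    fluid: FluidMedium,
) -> float:
    """Propulsive thrust from the settling-speed difference of two strains.

    Writing the force balance for a strain that swims deliberately downward
    (speed ``u_directed``) and for an otherwise identical passive settler
    (speed ``u_passive``) and subtracting cancels the unknown reduced
    weight, leaving ``F_p = 6 pi mu r_s (u_directed - u_passive)``.

    This velocity-difference form does not require the density contrast,
    which is why it is preferred over the single-strain form
    (:func:`thrust_single_strain`).  A negative return (directed strain
    slower than the passive one) is physically a thrust opposing gravity
    and is flagged with a warning.
    """
    if not (u_directed > 0 and u_passive > 0 and r_s > 0):
        raise InvalidInputError("speeds and Stokes radius must be > 0")
    f_p = 6.0 * math.pi * fluid.dynamic_viscosity * r_s * (u_directed - u_passive)
    if f_p < 0:
        warnings.warn(
            "directed speed below passive settling speed: estimated thrust "
            "is negative (opposes gravity)",
            stacklevel=2,
        )
    return f_p


def thrust_single_strain(
    u_directed: float,
    worm: WormBody,
    fluid: FluidMedium,
    g: float = G_STANDARD,
) -> float:
    """Single-strain thrust estimate ``C_f u_directed - |W|``.

    Sensitive to the poorly pinned density contrast and Stokes radius;
    prefer :func:`estimate_thrust` whenever a passive reference strain is
    available.
    """
    if worm.stokes_radius is None:
        raise InvalidInputError("worm needs a Stokes radius for this estimate")
    c_f = drag_coefficient(fluid, worm.stokes_radius)
    w = buoyant_net_force(worm, fluid, g)  # negative when the worm sinks
    return c_f * u_directed + w


def terminal_velocity(budget: ForceBudget) -> np.ndarray:
    """Quasi-static velocity relative to the fluid, ``(F_p + W z_hat)/C_f``."""
    if not budget.drag_coefficient > 0:
        raise InvalidInputError("drag coefficient must be > 0")
    force = budget.thrust + np.array([0.0, 0.0, budget.reduced_weight])
    return force / budget.drag_coefficient


def apparent_diffusion(speed: float, tau_r: float) -> float:
    """Long-time diffusivity ``U^2 tau_r / 3`` of a randomly reorienting
    self-propelled particle (3-D, exponential directional persistence)."""
    if speed < 0 or tau_r < 0:
        raise InvalidInputError("speed and reorientation time must be >= 0")
    return speed * speed * tau_r / 3.0


def reynolds_number(fluid: FluidMedium, speed: float, r_s: float) -> float:
    """Particle Reynolds number ``rho_f U r_s / mu``."""
    if speed < 0 or r_s < 0:
        raise InvalidInputError("speed and length scale must be >= 0")
    return fluid.density * speed * r_s / fluid.dynamic_viscosity


def mixture_density(fractions: list[tuple[float, float]]) -> float:
    """Ideal volume-additive density of a blend, ``sum(v_i rho_i)/sum(v_i)``.

    An estimate only: real colloid/buffer blends mix non-ideally, so the
    measured density of a working blend should always take precedence.
    """
    if not fractions:
        raise InvalidInputError("mixture needs at least one component")
    volumes = np.array([v for v, _ in fractions], dtype=float)
    densities = np.array([rho for _, rho in fractions], dtype=float)
    if np.any(volumes < 0) or not volumes.sum() > 0:
        raise InvalidInputError("component volumes must be >= 0 with a positive total")
    if np.any(densities <= 0):
        raise InvalidInputError("component densities must be > 0")
    return float(np.sum(volumes * densities) / np.sum(volumes))


def thrust_from_frequency(base_thrust: float, base_freq: float, new_freq: float) -> float:
    """Rescale thrust linearly with undulation frequency.

    Slender-body and resistive-force arguments make propulsive thrust
    proportional to the gait frequency, so
    ``F_new = F_base * f_new / f_base``.
    """
    if not base_freq > 0:
        raise InvalidInputError("base frequency must be > 0")
    if new_freq < 0:
        raise InvalidInputError("frequency must be >= 0")
    return base_thrust * new_freq / base_freq
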