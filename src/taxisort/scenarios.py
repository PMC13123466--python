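"""Canned, versioned parameter bundles for the documented experiments.

Each scenario pins every physical input of one study condition so that
simulations and estimates are reproducible from a single name:

* ``cuvette_m9`` -- settling/thrust estimation in plain M9 buffer
  (density ~1.0 g/mL, viscosity 1.0 mPa s): passive settlers at
  0.52 mm/s, directed swimmers at 0.64 mm/s, tau_r = 4.65 s.
* ``sorter_ludox`` -- the sorter run in the 1.09 g/mL colloidal-silica
  blend (viscosity 4.78 mPa s): 600 taxis-competent + 600 taxis-deficient
  particles, buoyancy +0.58 nN, thrust 0.81 nN, fixed-interval
  reorientation every 4.65 s, conduits at 0.5 mm/s.
* ``mixed_population_30min`` -- the mixed-strain run (674 competent +
  736 deficient) over a 30-minute window.
"""

from __future__ import annotations

from .errors import InvalidInputError
from .flow import SorterGeometry
from .physics import BehaviorParams, FluidMedium, WormBody
from .sim import SimConfig, WormPhenotype

SCENARIO_VERSION = "1"

M9 = FluidMedium(density=1000.0, dynamic_viscosity=1.0e-3, label="M9")
LUDOX_BLEND = FluidMedium(density=1090.0, dynamic_viscosity=4.78e-3, label="M9/LUDOX 1:0.315")

#: shared body parameters of the modelled adult worm
WORM_BODY = WormBody(volume=5.96e-12, density=1080.0, stokes_radius=0.37e-3)

THRUST = 0.81e-9  # N
TAU_R = 4.65  # s
SETTLING_SPEED_DEFICIENT = 0.52e-3  # m/s, passive settling in M9
SETTLING_SPEED_COMPETENT = 0.64e-3  # m/s, directed downward swimming in M9

COMPETENT = WormPhenotype(
    body=WORM_BODY,
    behavior=BehaviorParams(thrust_magnitude=THRUST, mode="directed_down"),
    label="taxis-competent",
    role="competent",
)
DEFICIENT = WormPhenotype(
    body=WORM_BODY,
    behavior=BehaviorParams(
        thrust_magnitude=THRUST,
        mode="random_reorient",
        reorientation_time=TAU_R,
        reorientation_scheme="fixed_interval",
    ),
    label="taxis-deficient",
    role="deficient",
)

_NAMES = ("cuvette_m9", "sorter_ludox", "mixed_population_30min")


def scenario(name: str, seed: int | None = 0) -> dict:
    """Return the fully populated parameter bundle for a named scenario."""
    if name == "cuvette_m9":
        return {
            "version": SCENARIO_VERSION,
            "fluid": M9,
            "worm": WORM_BODY,
            "tau_r": TAU_R,
            "settling_speed_deficient": SETTLING_SPEED_DEFICIENT,
            "settling_speed_competent": SETTLING_SPEED_COMPETENT,
            "n_tracks": 30,
        }
    if name in ("sorter_ludox", "mixed_population_30min"):
        n_comp, n_def = (600, 600) if name == "sorter_ludox" else (674, 736)
        config = SimConfig(
            geometry=SorterGeometry(),
            fluid=LUDOX_BLEND,
            populations=[(COMPETENT, n_comp), (DEFICIENT, n_def)],
            flow="solved",
            dt=0.01,
            max_time=1800.0,
            injection="pulse_at_inlet",
            seed=seed,
        )
        return {"version": SCENARIO_VERSION, "sim_config": config, "fluid": LUDOX_BLEND}
    raise InvalidInputError(
        f"unknown scenario {name!r}; available scenarios: {', '.join(_NAMES)}"
    )
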