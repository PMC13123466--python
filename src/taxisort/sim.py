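"""Agent-based simulation of worm-like particles in the sorter.

Particles are overdamped: at Re << 1 the velocity is the algebraic force
balance, ``v = u_fluid + (F_p n_hat + W z_hat) / C_f``, integrated by
explicit Euler -- no inertia.  Taxis-competent particles thrust steadily
downward; taxis-deficient particles carry the same thrust magnitude but
resample their heading uniformly on the sphere at fixed (default) or
exponential intervals.  Optional two-state quiescence switches thrust off
without touching weight or drag.

Positions are 3-D but the flow field is x-z planar (depth-invariant);
y-motion arises from the thrust heading only and is reflected at the
channel depth walls, which keeps the 3-D diffusivity U^2 tau_r / 3 exact
while using the 2-D field.

Walls are specular with the heading preserved, applied to a fluid domain
eroded by a finite body radius (default 0.05 mm, an adult worm's body
half-width).  The erosion matters twice over.  A point particle pressed
against a no-slip wall samples zero fluid velocity and never discharges,
whereas a finite body rides the conduit flow at one radius off the wall.
And the radius must be the geometric half-thickness, not the much larger
Stokes radius (a drag equivalent): buoyant animals escape the junction
vortices by creeping up the near-wall layer where the downwelling is
weak, a route that exists only within ~0.1 mm of the column walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .flow import FlowField2D, SorterGeometry, analytic_fallback_field, solve_unit_cell_flow
from .metrics import ConfusionCounts
from .physics import (
    G_STANDARD,
    BehaviorParams,
    FluidMedium,
    WormBody,
    buoyant_net_force,
    drag_coefficient,
)
from .synth import TrajectorySet, _uniform_sphere

#: default wall-exclusion radius: the body half-width of an adult worm (m)
BODY_HALF_WIDTH = 0.05e-3

IN_TRANSIT, EXITED_TOP, EXITED_BOTTOM, TIMED_OUT = 0, 1, 2, 3
STATUS_NAMES = {0: "in_transit", 1: "exited_top", 2: "exited_bottom", 3: "timed_out"}


@dataclass(frozen=True)
class QuiescenceModel:
    """Two-state activity switching.

    onset_hazard: rate of active -> quiescent transitions (s^-1), either a
    constant or a callable of time.  mean_bout: mean quiescent-bout
    duration (s).  ineffective_fraction_curve optionally stores a
    normalised (time, fraction) table for reference/reporting; it is not
    consumed by the simulation itself.
    """

    onset_hazard: float | object = 0.0
    mean_bout: float = 60.0
    ineffective_fraction_curve: tuple | None = None

    def hazard_at(self, t: float) -> float:
        h = self.onset_hazard(t) if callable(self.onset_hazard) else self.onset_hazard
        if h < 0:
            raise InvalidInputError("quiescence hazard must be >= 0")
        return float(h)

    def __post_init__(self):
        if not self.mean_bout > 0:
            raise InvalidInputError("mean quiescent bout must be > 0")
        if not callable(self.onset_hazard) and self.onset_hazard < 0:
            raise InvalidInputError("quiescence hazard must be >= 0")


@dataclass(frozen=True)
class WormPhenotype:
    """Body + behavior (+ optional quiescence) of one strain."""

    body: WormBody
    behavior: BehaviorParams
    quiescence: QuiescenceModel | None = None
    label: str = ""
    role: str = "other"  # competent | deficient | other

    def __post_init__(self):
        if self.role not in ("competent", "deficient", "other"):
            raise InvalidInputError(f"unknown phenotype role {self.role!r}")
        if self.body.stokes_radius is None:
            raise InvalidInputError("phenotype body needs a Stokes radius")


@dataclass
class ParticleState:
    """State of a single particle (used by the scalar :func:`step` API)."""

    position: np.ndarray
    heading: np.ndarray
    phenotype: WormPhenotype
    activity: str = "active"
    next_reorientation: float = np.inf
    status: int = IN_TRANSIT
    time: float = 0.0


@dataclass
class SimConfig:
    """Configuration of one sorter run.

    flow: a FlowField2D, or "solved" / "analytic" to build one from the
    geometry.  populations: list of (phenotype, count).  injection:
    "pulse_at_inlet" (uniform over the feed-inlet cross-section at t=0) or
    "distributed_feedline".  exclusion_radius: geometric wall standoff of
    the body centre (default the worm half-width; 0 -> point particles).
    """

    geometry: SorterGeometry
    fluid: FluidMedium
    populations: list
    flow: object = "analytic"
    dt: float = 0.01
    max_time: float = 1800.0
    injection: str = "pulse_at_inlet"
    seed: int | None = 0
    boundary: str = "reflect"
    g: float = G_STANDARD
    exclusion_radius: float = BODY_HALF_WIDTH
    record_interval: float | None = None

    def __post_init__(self):
        if self.max_time <= 0 or self.dt <= 0:
            raise InvalidInputError("dt and max_time must be > 0")
        if self.injection not in ("pulse_at_inlet", "distributed_feedline"):
            raise InvalidInputError(f"unknown injection mode {self.injection!r}")
        if self.boundary != "reflect":
            raise InvalidInputError("only reflective boundaries are supported")


@dataclass
class GroupOutcome:
    label: str
    role: str
    n_in: int
    n_top: int
    n_bottom: int
    n_timed_out: int
    mean_exit_time_top: float
    mean_exit_time_bottom: float

    def to_dict(self):
        out = dict(self.__dict__)
        for key in ("mean_exit_time_top", "mean_exit_time_bottom"):
            if isinstance(out[key], float) and np.isnan(out[key]):
                out[key] = None
        return out


@dataclass
class SortOutcome:
    groups: list
    seed: int | None
    dt: float
    max_time: float
    field_meta: dict = dc_field(default_factory=dict)

    def confusion(self) -> ConfusionCounts:
        c = dict.fromkeys(
            (
                "n_competent_in",
                "n_competent_bottom",
                "n_competent_top",
                "n_deficient_in",
                "n_deficient_top",
                "n_deficient_bottom",
            ),
            0,
        )
        for g in self.groups:
            if g.role == "competent":
                c["n_competent_in"] += g.n_in
                c["n_competent_bottom"] += g.n_bottom
                c["n_competent_top"] += g.n_top
            elif g.role == "deficient":
                c["n_deficient_in"] += g.n_in
                c["n_deficient_top"] += g.n_top
                c["n_deficient_bottom"] += g.n_bottom
        return ConfusionCounts(**c)

    def to_dict(self):
        return {
            "groups": [g.to_dict() for g in self.groups],
            "seed": self.seed,
            "dt": self.dt,
            "max_time": self.max_time,
            "field_meta": self.field_meta,
        }


def reorient(state: ParticleState, rng: np.random.Generator, scheme: str | None = None) -> ParticleState:
    """Resample the heading uniformly on the unit sphere and reschedule.

    Directed-down phenotypes are returned unchanged (their heading never
    changes).  fixed_interval schedules the next event exactly tau_r
    later; exponential draws an Exp(tau_r) waiting time.
    """
    beh = state.phenotype.behavior
    if beh.mode != "random_reorient":
        return state
    scheme = scheme or beh.reorientation_scheme
    state.heading = _uniform_sphere(rng, 1)[0]
    tau = beh.reorientation_time
    wait = tau if scheme == "fixed_interval" else rng.exponential(tau)
    state.next_reorientation = state.next_reorientation + wait if np.isfinite(state.next_reorientation) else state.time + wait
    return state


class _Domain:
    """Eroded fluid domain of the full device for finite-radius centres."""

    def __init__(self, geom: SorterGeometry):
        self.geom = geom
        self.p = geom.column_pitch
        self.x0 = (self.p - geom.column_width) / 2.0
        self.x1 = self.x0 + geom.column_width
        self.hf = geom.feed_height
        self.zc = geom.feed_height + geom.column_height  # column top
        self.ht = geom.total_height
        self.depth = min(geom.conduit_depth, geom.column_depth)
        self.L = geom.device_length

    def allowed(self, x, z, r):
        xc = np.mod(x, self.p)
        in_col = (xc >= self.x0 + r) & (xc <= self.x1 - r)
        a = (z >= r) & (z <= self.hf - r)
        b = (z >= self.zc + r) & (z <= self.ht - r)
        c = in_col & (z > self.hf - r) & (z < self.zc + r)
        return (a | b | c) & (x >= 0)

    def reflect_x(self, x_old, x_new, z, r):
        """Specular reflection of an x-move off column side walls / inlet."""
        x_new = np.where(x_new < 0, -x_new, x_new)
        bad = ~self.allowed(x_new, z, r)
        if not np.any(bad):
            return x_new
        xc = np.mod(x_new, self.p)
        lo, hi = self.x0 + r, self.x1 - r
        fold = np.where(xc < lo, 2 * lo - xc, np.where(xc > hi, 2 * hi - xc, xc))
        cand = np.where(bad, x_new + (fold - xc), x_new)
        still = ~self.allowed(cand, z, r)
        return np.where(still, x_old, cand)

    def reflect_z(self, x, z_old, z_new, r):
        """Specular reflection of a z-move off floors, ceilings and shelves."""
        z_new = np.where(z_new < r, 2 * r - z_new, z_new)
        z_new = np.where(z_new > self.ht - r, 2 * (self.ht - r) - z_new, z_new)
        bad = ~self.allowed(x, z_new, r)
        if not np.any(bad):
            return z_new
        # rising out of the feed conduit under a wall shelf
        up = bad & (z_old <= self.hf - r) & (z_new > self.hf - r)
        cand = np.where(up, 2 * (self.hf - r) - z_new, z_new)
        # sinking out of the collection conduit onto a wall shelf
        down = bad & (z_old >= self.zc + r) & (z_new < self.zc + r)
        cand = np.where(down, 2 * (self.zc + r) - cand, cand)
        still = ~self.allowed(x, cand, r)
        return np.where(still, z_old, cand)


def _resolve_field(config: SimConfig) -> FlowField2D:
    if isinstance(config.flow, FlowField2D):
        return config.flow
    if config.flow == "analytic":
        return analytic_fallback_field(config.geometry)
    if config.flow == "solved":
        return solve_unit_cell_flow(config.geometry)
    raise InvalidInputError(f"unknown flow source {config.flow!r}")


def _dt_bound(config: SimConfig, field: FlowField2D, groups) -> float:
    drift = max(
        (g["F"] + abs(g["W"])) / g["Cf"] for g in groups
    )
    vmax = field.max_speed + drift
    taus = [g["tau"] for g in groups if g["tau"] is not None]
    tau_min = min(taus) if taus else np.inf
    cell = field.grid_spacing
    return 0.1 * min(tau_min, cell / vmax if vmax > 0 else np.inf)


def simulate_population(config: SimConfig) -> tuple[TrajectorySet, SortOutcome]:
    """Run every particle to an exit (or time-out) and classify it.

    Deterministic given the seed.  Returns the (optionally thinned)
    trajectories and the per-phenotype exit counts; timed-out particles
    are reported separately, never dropped.
    """
    field = _resolve_field(config)
    geom = config.geometry
    dom = _Domain(geom)
    rng = np.random.default_rng(config.seed)

    groups = []
    for pheno, n in config.populations:
        if n < 0:
            raise InvalidInputError("population counts must be >= 0")
        w = buoyant_net_force(pheno.body, config.fluid, config.g)
        cf = drag_coefficient(config.fluid, pheno.body.stokes_radius)
        r = config.exclusion_radius
        if not r < dom.hf / 2:
            raise InvalidInputError(
                "exclusion radius must be smaller than half the feed-conduit height"
            )
        beh = pheno.behavior
        groups.append(
            dict(
                pheno=pheno,
                n=int(n),
                W=w,
                Cf=cf,
                F=beh.thrust_magnitude if beh.mode != "passive" else 0.0,
                mode=beh.mode,
                tau=beh.reorientation_time if beh.mode == "random_reorient" else None,
                scheme=beh.reorientation_scheme,
                r=r,
                quies=pheno.quiescence,
            )
        )

    bound = _dt_bound(config, field, groups) if groups else np.inf
    if config.dt > bound * (1 + 1e-9):
        raise InvalidInputError(
            f"dt = {config.dt:g} s violates the stability bound "
            f"0.1*min(tau_r, cell/max_speed) = {bound:g} s; reduce dt or coarsen "
            "the requested accuracy"
        )

    n_total = sum(g["n"] for g in groups)
    pos = np.zeros((n_total, 3))
    heading = np.zeros((n_total, 3))
    group_id = np.zeros(n_total, dtype=int)
    status = np.full(n_total, IN_TRANSIT, dtype=int)
    exit_time = np.full(n_total, np.nan)
    next_reo = np.full(n_total, np.inf)
    active_state = np.ones(n_total, dtype=bool)

    f_over_cf = np.zeros(n_total)
    w_over_cf = np.zeros(n_total)
    radius = np.zeros(n_total)
    is_random = np.zeros(n_total, dtype=bool)
    is_fixed = np.zeros(n_total, dtype=bool)
    tau_arr = np.full(n_total, np.nan)
    hazard_g = [g["quies"] for g in groups]
    hazard_const = np.zeros(n_total)
    hazard_time_dep = any(
        g["quies"] is not None and callable(g["quies"].onset_hazard) for g in groups
    )
    bout_rate = np.zeros(n_total)
    has_quies = np.zeros(n_total, dtype=bool)

    start = 0
    for gi, g in enumerate(groups):
        sl = slice(start, start + g["n"])
        group_id[sl] = gi
        f_over_cf[sl] = g["F"] / g["Cf"]
        w_over_cf[sl] = g["W"] / g["Cf"]
        radius[sl] = g["r"]
        if g["mode"] == "directed_down":
            heading[sl] = np.array([0.0, 0.0, -1.0])
        elif g["mode"] == "random_reorient":
            heading[sl] = _uniform_sphere(rng, g["n"])
            is_random[sl] = True
            is_fixed[sl] = g["scheme"] == "fixed_interval"
            tau_arr[sl] = g["tau"]
            if g["scheme"] == "fixed_interval":
                next_reo[sl] = g["tau"]
            else:
                next_reo[sl] = rng.exponential(g["tau"], size=g["n"])
        if g["quies"] is not None:
            has_quies[sl] = True
            bout_rate[sl] = 1.0 / g["quies"].mean_bout
            if not callable(g["quies"].onset_hazard):
                hazard_const[sl] = g["quies"].onset_hazard
        # injection
        r = g["r"]
        if config.injection == "pulse_at_inlet":
            pos[sl, 0] = 0.0
        else:
            pos[sl, 0] = rng.uniform(0.0, geom.device_length * 0.98, size=g["n"])
        pos[sl, 1] = rng.uniform(r, dom.depth - r, size=g["n"])
        pos[sl, 2] = rng.uniform(r, geom.feed_height - r, size=g["n"])
        start += g["n"]

    record = config.record_interval is not None
    rec_stride = max(1, int(round((config.record_interval or 0) / config.dt))) if record else 0
    rec_rows = []

    dt = config.dt
    t = 0.0
    step_i = 0
    n_steps = int(np.ceil(config.max_time / dt))
    while step_i < n_steps:
        idx = np.nonzero(status == IN_TRANSIT)[0]
        if idx.size == 0:
            break
        # --- reorientation events ------------------------------------
        due = idx[is_random[idx] & (next_reo[idx] <= t)]
        if due.size:
            heading[due] = _uniform_sphere(rng, due.size)
            fixed = is_fixed[due]
            next_reo[due[fixed]] += tau_arr[due[fixed]]
            nf = due[~fixed]
            if nf.size:
                next_reo[nf] = t + rng.exponential(tau_arr[nf])
        # --- quiescence switching ------------------------------------
        qi = idx[has_quies[idx]]
        if qi.size:
            if hazard_time_dep:
                haz = np.array([hazard_g[group_id[j]].hazard_at(t) for j in qi])
            else:
                haz = hazard_const[qi]
            # draw only where a transition is possible, so a zero-hazard
            # model consumes no randomness (identical to no model at all)
            need = (~active_state[qi]) | (haz > 0)
            qi, haz = qi[need], haz[need]
        if qi.size:
            u = rng.random(qi.size)
            on = active_state[qi] & (u < haz * dt)
            off = ~active_state[qi] & (u < bout_rate[qi] * dt)
            active_state[qi[on]] = False
            active_state[qi[off]] = True
        # --- overdamped velocity -------------------------------------
        ux, uz = field.velocity_at(pos[idx, 0], pos[idx, 2])
        thrust = f_over_cf[idx] * active_state[idx]
        vx = ux + thrust * heading[idx, 0]
        vy = thrust * heading[idx, 1]
        vz = uz + thrust * heading[idx, 2] + w_over_cf[idx]
        # --- move with axis-wise specular reflection ------------------
        r = radius[idx]
        x_new = pos[idx, 0] + vx * dt
        out = x_new > geom.device_length
        if np.any(out):
            exited = idx[out]
            top = pos[exited, 2] > dom.hf + geom.column_height / 2.0
            status[exited] = np.where(top, EXITED_TOP, EXITED_BOTTOM)
            exit_time[exited] = t + dt
            keep = ~out
            idx, r, x_new = idx[keep], r[keep], x_new[keep]
            vy, vz = vy[keep], vz[keep]
        if idx.size:
            pos[idx, 0] = dom.reflect_x(pos[idx, 0], x_new, pos[idx, 2], r)
            z_new = dom.reflect_z(pos[idx, 0], pos[idx, 2], pos[idx, 2] + vz * dt, r)
            pos[idx, 2] = z_new
            y_new = pos[idx, 1] + vy * dt
            y_new = np.where(y_new < r, 2 * r - y_new, y_new)
            y_hi = dom.depth - r
            y_new = np.where(y_new > y_hi, 2 * y_hi - y_new, y_new)
            pos[idx, 1] = y_new
        t += dt
        step_i += 1
        if record and step_i % rec_stride == 0:
            live = np.nonzero(status == IN_TRANSIT)[0]
            for j in live:
                rec_rows.append(
                    (int(j), t, pos[j, 0], pos[j, 1], pos[j, 2], STATUS_NAMES[int(status[j])])
                )
    status[status == IN_TRANSIT] = TIMED_OUT

    out_groups = []
    start = 0
    for g in groups:
        sl = slice(start, start + g["n"])
        st = status[sl]
        et = exit_time[sl]
        top = st == EXITED_TOP
        bot = st == EXITED_BOTTOM
        out_groups.append(
            GroupOutcome(
                label=g["pheno"].label or g["pheno"].role,
                role=g["pheno"].role,
                n_in=g["n"],
                n_top=int(top.sum()),
                n_bottom=int(bot.sum()),
                n_timed_out=int((st == TIMED_OUT).sum()),
                mean_exit_time_top=float(np.nanmean(et[top])) if top.any() else float("nan"),
                mean_exit_time_bottom=float(np.nanmean(et[bot])) if bot.any() else float("nan"),
            )
        )
        start += g["n"]

    frame = pd.DataFrame(
        rec_rows, columns=["particle_id", "t", "x", "y", "z", "status"]
    )
    traj = TrajectorySet(
        frame,
        sampling_rate=1.0 / config.record_interval if record else np.nan,
        metadata={"seed": config.seed, "dt": dt, "recorded": record},
    )
    outcome = SortOutcome(
        groups=out_groups,
        seed=config.seed,
        dt=dt,
        max_time=config.max_time,
        field_meta=dict(field.meta, grid_spacing=field.grid_spacing),
    )
    return traj, outcome


def make_step_fn(fluid: FluidMedium, g: float = G_STANDARD, exclusion_radius: float = BODY_HALF_WIDTH):
    """Build a scalar single-particle stepper bound to a fluid medium.

    The returned function applies the same overdamped Euler update as the
    vectorised engine in :func:`simulate_population`; it exists for
    inspection and unit-level oracles.
    """

    def _step(state: ParticleState, field: FlowField2D, dt: float) -> ParticleState:
        if state.status != IN_TRANSIT:
            raise InvalidInputError("cannot step a particle that has exited")
        pheno = state.phenotype
        geom = field.geometry
        dom = _Domain(geom)
        w = buoyant_net_force(pheno.body, fluid, g)
        cf = drag_coefficient(fluid, pheno.body.stokes_radius)
        fmag = pheno.behavior.thrust_magnitude if pheno.behavior.mode != "passive" else 0.0
        if state.activity != "active":
            fmag = 0.0
        x, y, z = state.position
        if not dom.allowed(np.array([x]), np.array([z]), exclusion_radius)[0]:
            raise InvalidInputError("particle is outside the fluid domain")
        ux, uz = field.velocity_at(np.array([x]), np.array([z]))
        v = np.array(
            [
                ux[0] + fmag * state.heading[0] / cf,
                fmag * state.heading[1] / cf,
                uz[0] + fmag * state.heading[2] / cf + w / cf,
            ]
        )
        r = np.array([exclusion_radius])
        x_new = np.array([x + v[0] * dt])
        if x_new[0] > geom.device_length:
            state.status = EXITED_TOP if z > dom.hf + geom.column_height / 2 else EXITED_BOTTOM
            state.time += dt
            return state
        xr = dom.reflect_x(np.array([x]), x_new, np.array([z]), r)
        zr = dom.reflect_z(xr, np.array([z]), np.array([z + v[2] * dt]), r)
        y_new = y + v[1] * dt
        rr = exclusion_radius
        if y_new < rr:
            y_new = 2 * rr - y_new
        y_hi = dom.depth - rr
        if y_new > y_hi:
            y_new = 2 * y_hi - y_new
        state.position = np.array([xr[0], y_new, zr[0]])
        state.time += dt
        return state

    return _step


def free_ensemble(
    phenotype: WormPhenotype,
    fluid: FluidMedium,
    n: int,
    duration: float,
    dt: float,
    seed: int | None = 0,
    sample_every: int = 10,
    g: float = G_STANDARD,
    include_weight: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unbounded still-fluid ensemble (no walls, no flow).

    Returns (times, positions[time, particle, 3]).  Used as the free-space
    oracle: the ensemble MSD of a randomly reorienting phenotype should
    approach ``6 D_app t + (W/C_f)^2 t^2``.
    """
    rng = np.random.default_rng(seed)
    beh = phenotype.behavior
    w = buoyant_net_force(phenotype.body, fluid, g) if include_weight else 0.0
    cf = drag_coefficient(fluid, phenotype.body.stokes_radius)
    fmag = beh.thrust_magnitude if beh.mode != "passive" else 0.0
    pos = np.zeros((n, 3))
    if beh.mode == "directed_down":
        head = np.tile([0.0, 0.0, -1.0], (n, 1))
        next_reo = np.full(n, np.inf)
    elif beh.mode == "random_reorient":
        head = _uniform_sphere(rng, n)
        if beh.reorientation_scheme == "fixed_interval":
            next_reo = np.full(n, beh.reorientation_time)
        else:
            next_reo = rng.exponential(beh.reorientation_time, size=n)
    else:
        head = np.zeros((n, 3))
        next_reo = np.full(n, np.inf)
    n_steps = int(round(duration / dt))
    times = [0.0]
    samples = [pos.copy()]
    t = 0.0
    for i in range(1, n_steps + 1):
        due = np.nonzero(next_reo <= t)[0]
        if due.size:
            head[due] = _uniform_sphere(rng, due.size)
            if beh.reorientation_scheme == "fixed_interval":
                next_reo[due] += beh.reorientation_time
            else:
                next_reo[due] = t + rng.exponential(beh.reorientation_time, size=due.size)
        v = fmag * head / cf
        pos = pos + v * dt
        pos[:, 2] += (w / cf) * dt
        t += dt
        if i % sample_every == 0:
            times.append(t)
            samples.append(pos.copy())
    return np.asarray(times), np.asarray(samples)
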