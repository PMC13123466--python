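"""Agent-engine oracles: overdamped kinematics, reorientation statistics,
bookkeeping invariants, and the free-space run-and-tumble closed form."""

import numpy as np
import pytest

from taxisort import sim as S
from taxisort.errors import InvalidInputError
from taxisort.flow import SorterGeometry, analytic_fallback_field
from taxisort.physics import (
    BehaviorParams,
    FluidMedium,
    WormBody,
    apparent_diffusion,
    buoyant_net_force,
    drag_coefficient,
)

from conftest import LUDOX, WORM

THRUST = 0.81e-9
TAU = 4.65

COMPETENT = S.WormPhenotype(
    body=WORM,
    behavior=BehaviorParams(thrust_magnitude=THRUST, mode="directed_down"),
    label="competent",
    role="competent",
)
DEFICIENT = S.WormPhenotype(
    body=WORM,
    behavior=BehaviorParams(
        thrust_magnitude=THRUST,
        mode="random_reorient",
        reorientation_time=TAU,
        reorientation_scheme="fixed_interval",
    ),
    label="deficient",
    role="deficient",
)
DEFICIENT_EXP = S.WormPhenotype(
    body=WORM,
    behavior=BehaviorParams(
        thrust_magnitude=THRUST,
        mode="random_reorient",
        reorientation_time=TAU,
        reorientation_scheme="exponential",
    ),
    role="deficient",
)
PASSIVE = S.WormPhenotype(
    body=WORM, behavior=BehaviorParams(mode="passive"), role="other", label="passive"
)

SMALL_GEOM = SorterGeometry(n_columns=2, device_length=8.2e-3, column_height=6e-3)


def small_config(populations, seed=0, max_time=900.0, **kw):
    return S.SimConfig(
        geometry=SMALL_GEOM,
        fluid=LUDOX,
        populations=populations,
        flow=analytic_fallback_field(SMALL_GEOM),
        dt=0.01,
        max_time=max_time,
        seed=seed,
        **kw,
    )


class TestSingleParticleStep:
    def setup_method(self):
        self.field = analytic_fallback_field(SorterGeometry())
        self.step = S.make_step_fn(LUDOX)

    def test_passive_particle_rises_at_exact_terminal_speed(self):
        """In still fluid the rise per step is exactly (W / C_f) dt."""
        w = buoyant_net_force(WORM, LUDOX)
        c_f = drag_coefficient(LUDOX, WORM.stokes_radius)
        state = S.ParticleState(
            position=np.array([2.05e-3, 1.5e-3, 10e-3]),
            heading=np.zeros(3),
            phenotype=PASSIVE,
        )
        z0 = state.position[2]
        self.step(state, self.field, 0.01)
        assert state.position[2] - z0 == pytest.approx((w / c_f) * 0.01, rel=1e-12)
        assert state.position[0] == 2.05e-3  # no flow inside the column

    def test_tracer_limit_follows_local_fluid(self):
        neutral_body = WormBody(volume=WORM.volume, density=LUDOX.density, stokes_radius=WORM.stokes_radius)
        tracer = S.WormPhenotype(body=neutral_body, behavior=BehaviorParams(mode="passive"))
        state = S.ParticleState(
            position=np.array([2.05e-3, 1.5e-3, 0.5e-3]),  # feed-conduit centreline
            heading=np.zeros(3),
            phenotype=tracer,
        )
        x0 = state.position[0]
        self.step(state, self.field, 0.01)
        assert state.position[0] - x0 == pytest.approx(1.5 * 0.5e-3 * 0.01, rel=1e-9)
        assert state.position[2] == pytest.approx(0.5e-3)

    def test_thrust_cancelling_weight_freezes_particle(self):
        w = buoyant_net_force(WORM, LUDOX)  # positive, up
        balanced = S.WormPhenotype(
            body=WORM,
            behavior=BehaviorParams(thrust_magnitude=w, mode="directed_down"),
        )
        state = S.ParticleState(
            position=np.array([2.05e-3, 1.5e-3, 10e-3]),
            heading=np.array([0.0, 0.0, -1.0]),
            phenotype=balanced,
        )
        p0 = state.position.copy()
        self.step(state, self.field, 0.01)
        assert np.allclose(state.position, p0, atol=1e-18)

    def test_quiescent_particle_is_a_passive_tracer(self):
        """Permanent quiescence removes thrust but keeps weight and drag."""
        w = buoyant_net_force(WORM, LUDOX)
        c_f = drag_coefficient(LUDOX, WORM.stokes_radius)
        state = S.ParticleState(
            position=np.array([2.05e-3, 1.5e-3, 10e-3]),
            heading=np.array([0.0, 0.0, -1.0]),
            phenotype=COMPETENT,
            activity="quiescent",
        )
        z0 = state.position[2]
        self.step(state, self.field, 0.01)
        assert state.position[2] - z0 == pytest.approx((w / c_f) * 0.01, rel=1e-12)


class TestReorientation:
    def test_directed_phenotype_never_reorients(self):
        rng = np.random.default_rng(0)
        state = S.ParticleState(
            position=np.zeros(3), heading=np.array([0.0, 0.0, -1.0]), phenotype=COMPETENT
        )
        S.reorient(state, rng)
        assert np.array_equal(state.heading, [0.0, 0.0, -1.0])

    def test_fixed_interval_schedule_is_exact_multiples(self):
        rng = np.random.default_rng(0)
        state = S.ParticleState(
            position=np.zeros(3),
            heading=np.array([1.0, 0.0, 0.0]),
            phenotype=DEFICIENT,
            next_reorientation=TAU,
        )
        for k in range(2, 6):
            S.reorient(state, rng)
            assert state.next_reorientation == pytest.approx(k * TAU, rel=1e-12)

    def test_resampled_headings_are_unit_and_isotropic(self):
        rng = np.random.default_rng(42)
        h = S._uniform_sphere(rng, 10_000)
        assert np.allclose(np.linalg.norm(h, axis=1), 1.0, atol=1e-9)
        # per-component mean of a uniform sphere: sd = sqrt(1/3)/sqrt(n)
        tol = 3.0 * np.sqrt(1.0 / 3.0) / np.sqrt(10_000)
        assert np.all(np.abs(h.mean(axis=0)) < tol)


class TestPopulationBookkeeping:
    def test_counts_are_conserved_per_phenotype(self):
        cfg = small_config([(COMPETENT, 25), (DEFICIENT, 25)], max_time=300.0)
        _, out = S.simulate_population(cfg)
        for g in out.groups:
            assert g.n_top + g.n_bottom + g.n_timed_out == g.n_in

    def test_identical_seed_gives_identical_outcome(self):
        outs = []
        for _ in range(2):
            cfg = small_config([(COMPETENT, 15), (DEFICIENT, 15)], seed=123, max_time=300.0)
            _, out = S.simulate_population(cfg)
            outs.append(out.to_dict())
        assert outs[0] == outs[1]

    def test_zero_population_yields_empty_outcome(self):
        cfg = small_config([(COMPETENT, 0)], max_time=10.0)
        _, out = S.simulate_population(cfg)
        assert out.groups[0].n_in == 0
        assert out.confusion().n_competent_in == 0

    def test_oversized_dt_is_refused_with_explanation(self):
        cfg = small_config([(DEFICIENT, 5)], max_time=10.0)
        cfg.dt = 1.0
        with pytest.raises(InvalidInputError, match="stability bound"):
            S.simulate_population(cfg)

    def test_dt_halving_leaves_exit_fractions_within_binomial_error(self):
        fracs = []
        for dt in (0.01, 0.005):
            cfg = small_config([(DEFICIENT, 150)], seed=7, max_time=900.0)
            cfg.dt = dt
            _, out = S.simulate_population(cfg)
            g = out.groups[0]
            fracs.append(g.n_top / g.n_in)
        p = np.mean(fracs)
        se = np.sqrt(p * (1 - p) / 150)
        assert abs(fracs[0] - fracs[1]) <= se

    def test_zero_hazard_quiescence_is_bitwise_neutral(self):
        """A quiescence model that can never fire leaves the trajectory
        stream identical to the bare phenotype."""
        quiet = S.WormPhenotype(
            body=WORM,
            behavior=DEFICIENT.behavior,
            quiescence=S.QuiescenceModel(onset_hazard=0.0, mean_bout=60.0),
            role="deficient",
        )
        outs = []
        for pheno in (DEFICIENT, quiet):
            cfg = small_config([(pheno, 20)], seed=5, max_time=300.0)
            cfg.record_interval = 1.0
            traj, out = S.simulate_population(cfg)
            outs.append((traj.frame[["t", "x", "y", "z"]], out.groups[0]))
        assert outs[0][0].equals(outs[1][0])
        assert outs[0][1].n_top == outs[1][1].n_top


class TestCompetentNeverExitTop:
    def test_downward_thrust_exceeding_buoyancy_forbids_top_exit(self, solved_field, device_geometry):
        """With F_p > |W| and bottom injection, no competent particle can
        accumulate the net upward displacement needed to reach the top."""
        cfg = S.SimConfig(
            geometry=device_geometry,
            fluid=LUDOX,
            populations=[(COMPETENT, 40)],
            flow=solved_field,
            dt=0.01,
            max_time=900.0,
            seed=11,
        )
        _, out = S.simulate_population(cfg)
        g = out.groups[0]
        assert g.n_top == 0
        assert g.n_bottom == g.n_in  # all discharged through the feed line


class TestFreeSpaceEnsemble:
    def test_msd_matches_drift_plus_run_tumble_diffusion(self):
        """Unbounded still-fluid ensemble MSD equals the exact run-and-tumble
        expression plus the squared buoyant drift, within 3 sigma."""
        n, duration, dt = 500, 50.0, 0.05
        times, pos = S.free_ensemble(DEFICIENT_EXP, LUDOX, n, duration, dt, seed=2)
        w = buoyant_net_force(WORM, LUDOX)
        c_f = drag_coefficient(LUDOX, WORM.stokes_radius)
        u = THRUST / c_f
        t = times[-1]
        disp = pos[-1] - pos[0]
        r2 = np.einsum("ij,ij->i", disp, disp)
        msd = r2.mean()
        expected = (
            2.0 * u**2 * TAU**2 * (t / TAU - 1.0 + np.exp(-t / TAU)) + (w / c_f * t) ** 2
        )
        sigma = r2.std(ddof=1) / np.sqrt(n)
        assert abs(msd - expected) < 3.0 * sigma

    def test_long_time_diffusivity_approaches_u2_tau_over_three(self):
        n, duration, dt = 400, 60.0, 0.05
        times, pos = S.free_ensemble(
            DEFICIENT_EXP, LUDOX, n, duration, dt, seed=9, include_weight=False
        )
        c_f = drag_coefficient(LUDOX, WORM.stokes_radius)
        u = THRUST / c_f
        i1 = np.argmin(np.abs(times - 30.0))
        d1 = pos[i1] - pos[0]
        d2 = pos[-1] - pos[0]
        slopes = (np.einsum("ij,ij->i", d2, d2) - np.einsum("ij,ij->i", d1, d1)) / (
            6.0 * (times[-1] - times[i1])
        )
        d_hat = slopes.mean()
        se = slopes.std(ddof=1) / np.sqrt(n)
        assert abs(d_hat - apparent_diffusion(u, TAU)) < 3.0 * se
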