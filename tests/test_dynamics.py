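import numpy as np
import pytest

from iefsim.charge_model import ChargeState, ProteinSpecies
from iefsim.constants import DRAG_B, E_CHARGE, K_BOLTZMANN, Q_NUCLEUS, UM
from iefsim.dynamics import (
    DynamicsParams,
    Particle,
    SimState,
    brownian_step,
    drag_constant,
    drift_transit_time,
    einstein_stokes_D,
    integrate_step,
    pair_coulomb_force,
    random_positions_on_cap,
    random_unit_vectors,
    simulate_free_walkers,
    terminal_velocity,
    total_force,
    velocity_update,
)
from iefsim.geometry import NuclearField


def make_particle(i, pos_m, q, species=None, vel=None):
    sp = species or ProteinSpecies("m", iep=9.2)
    return Particle(
        id=i,
        species=sp,
        position=np.asarray(pos_m, dtype=float),
        velocity=np.zeros(3) if vel is None else np.asarray(vel, dtype=float),
        charge_state=ChargeState(iep_charge=q),
    )


class TestEinsteinStokes:
    def test_reference_diffusion_coefficient(self, params):
        # eta = 0.3 Pa s, T = 310 K, r = 5 nm
        assert einstein_stokes_D(params, 5e-9) == pytest.approx(1.514e-13, rel=1e-3)

    def test_hundredfold_lower_viscosity(self):
        p = DynamicsParams(eta=0.003)
        assert einstein_stokes_D(p, 5e-9) == pytest.approx(1.514e-11, rel=1e-3)

    def test_doubling_radius_halves_D(self, params):
        assert einstein_stokes_D(params, 1e-8) == pytest.approx(
            einstein_stokes_D(params, 5e-9) / 2
        )

    def test_consistency_with_drag(self, params):
        # D * b = k_B T exactly for derived coefficients
        for r in (2e-9, 5e-9, 1.1e-8):
            assert einstein_stokes_D(params, r) * drag_constant(params.eta, r) == (
                pytest.approx(K_BOLTZMANN * params.temperature)
            )

    def test_invalid_inputs(self, params):
        with pytest.raises(ValueError):
            einstein_stokes_D(params, -1e-9)
        with pytest.raises(ValueError):
            drag_constant(0.0, 5e-9)


class TestDrag:
    def test_reference_drag_constant(self):
        assert drag_constant(0.3, 5e-9) == pytest.approx(2.827e-8, rel=1e-3)

    def test_linearity_in_radius(self):
        assert drag_constant(0.3, 1e-8) == pytest.approx(2 * drag_constant(0.3, 5e-9))

    def test_terminal_velocity_reference(self):
        assert terminal_velocity(5.654e-12, 2.827e-8) == pytest.approx(2.0e-4, rel=1e-3)

    def test_terminal_velocity_edge_cases(self):
        assert terminal_velocity(0.0, DRAG_B) == 0.0
        assert terminal_velocity(2.0, DRAG_B) == pytest.approx(
            2 * terminal_velocity(1.0, DRAG_B)
        )
        with pytest.raises(ValueError):
            terminal_velocity(1.0, 0.0)


class TestBrownianStep:
    def test_zero_diffusion_is_identity(self, rng):
        p = np.array([1e-6, 0.0, 0.0])
        assert np.allclose(brownian_step(p, 0.0, 1e-4, rng), p)

    def test_fixed_step_length(self, rng):
        D, dt = 1.514e-13, 1e-4
        p0 = np.zeros(3)
        for _ in range(20):
            p1 = brownian_step(p0, D, dt, rng)
            assert np.linalg.norm(p1 - p0) == pytest.approx(
                np.sqrt(6 * D * dt), rel=1e-12
            )
        assert np.sqrt(6 * D * dt) == pytest.approx(9.53e-9, rel=1e-3)

    def test_rms_displacement_law(self, rng):
        # sqrt(6 D t) within 3 standard errors of the sample RMS
        D, dt, t = 1.514e-13, 1e-4, 0.2
        disp = simulate_free_walkers(2000, D, dt, [t], rng)[0]
        rms = np.sqrt(np.mean(disp**2))
        expected = np.sqrt(6 * D * t)
        se = rms / np.sqrt(2 * len(disp))
        assert abs(rms - expected) < 3 * se

    def test_directions_are_isotropic(self, rng):
        v = random_unit_vectors(20000, rng)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0)
        assert np.allclose(v.mean(axis=0), 0.0, atol=0.02)


class TestCoulombForces:
    def test_pair_force_magnitude(self, params):
        f = pair_coulomb_force(1, 1, (1e-6, 0, 0), (0, 0, 0), params)
        assert np.linalg.norm(f) == pytest.approx(2.88e-18, rel=1e-2)
        assert f[0] > 0  # repulsive, pushing particle 1 away from 2

    def test_neutral_particle_feels_nothing(self, params):
        f = pair_coulomb_force(0, 5, (1e-6, 0, 0), (0, 0, 0), params)
        assert np.allclose(f, 0.0)

    def test_newtons_third_law(self, params):
        a, b = np.array([1e-6, 2e-6, 0.0]), np.array([-1e-6, 0.0, 1e-6])
        f_ab = pair_coulomb_force(2, -1, a, b, params)
        f_ba = pair_coulomb_force(-1, 2, b, a, params)
        assert np.allclose(f_ab, -f_ba)

    def test_softening_clamps_close_pairs(self, params):
        near = pair_coulomb_force(1, 1, (1e-12, 0, 0), (0, 0, 0), params, min_separation=1e-8)
        at_clamp = pair_coulomb_force(1, 1, (1e-8, 0, 0), (0, 0, 0), params)
        assert np.linalg.norm(near) <= np.linalg.norm(at_clamp) * (1 + 1e-9)

    def test_nuclear_attraction_reference(self, geometry, nucleus, params):
        # -2 e at r = 4 um: |F| = k Q_N 2e / (80 r^2) = 5.65e-12 N, inward
        p = make_particle(0, (0, 0, 4e-6), -2)
        f = total_force(p, [p], nucleus, geometry, params)
        assert np.linalg.norm(f) == pytest.approx(5.65e-12, rel=1e-2)
        assert f[2] < 0

    def test_neutral_alone_feels_nothing(self, geometry, nucleus, params):
        p = make_particle(0, (0, 0, 4e-6), 0)
        f = total_force(p, [p], nucleus, geometry, params)
        assert np.allclose(f, 0.0)

    def test_symmetric_pair_symmetric_radial_force(self, geometry, nucleus, params):
        p1 = make_particle(0, (0, 0, 4e-6), -1)
        p2 = make_particle(1, (0, 0, -4e-6), -1)
        f1 = total_force(p1, [p1, p2], nucleus, geometry, params)
        f2 = total_force(p2, [p1, p2], nucleus, geometry, params)
        assert np.allclose(f1, -f2)

    def test_absorbed_neighbours_excluded(self, geometry, nucleus, params):
        p1 = make_particle(0, (0, 0, 4e-6), -1)
        p2 = make_particle(1, (0, 0, 4.5e-6), -1)
        p2.absorbed = True
        f_with = total_force(p1, [p1, p2], nucleus, geometry, params)
        p3 = make_particle(1, (0, 0, 4.5e-6), 0)
        f_alone = total_force(p1, [p1, p3], nucleus, geometry, params)
        assert np.allclose(f_with, f_alone)


class TestVelocityUpdate:
    def test_cap_engages_at_reference_force(self, params):
        # Newtonian v from F = 5.65e-12 N over dt is ~10 orders above v_t
        p = make_particle(0, (0, 0, 4e-6), -2)
        f = np.array([0.0, 0.0, -5.654e-12])
        v = velocity_update(p, f, params)
        assert np.linalg.norm(v) == pytest.approx(2.0e-4, rel=1e-3)
        assert v[2] < 0

    def test_zero_force_zero_velocity(self, params):
        p = make_particle(0, (0, 0, 4e-6), 0)
        assert np.allclose(velocity_update(p, np.zeros(3), params), 0.0)

    def test_uncapped_newtonian_branch(self, params):
        # with a tiny enough force*dt the cap is inactive
        p = make_particle(0, (0, 0, 4e-6), 0)
        f = np.array([1e-30, 0.0, 0.0])
        v = velocity_update(p, f, params)
        v_newton = f / p.species.mass_kg * params.dt
        vt = np.linalg.norm(f) / DRAG_B
        if np.linalg.norm(v_newton) < vt:
            assert np.allclose(v, v_newton)

    def test_moving_neutral_particle_stops(self, params):
        # zero force means zero terminal velocity: no ballistic coasting
        p = make_particle(0, (0, 0, 4e-6), 0, vel=(1e-4, 0, 0))
        assert np.allclose(velocity_update(p, np.zeros(3), params), 0.0)


class TestDriftTransitTime:
    def test_reference_transit(self, nucleus):
        t = drift_transit_time(5e-6, 3e-6, -2, nucleus, DRAG_B)
        assert t == pytest.approx(0.0102, rel=1e-2)

    def test_degenerate_zero_distance(self, nucleus):
        assert drift_transit_time(4e-6, 4e-6, -2, nucleus, DRAG_B) == 0.0

    def test_doubling_charge_halves_time(self, nucleus):
        t1 = drift_transit_time(5e-6, 3e-6, -1, nucleus, DRAG_B)
        t2 = drift_transit_time(5e-6, 3e-6, -2, nucleus, DRAG_B)
        assert t1 == pytest.approx(2 * t2)

    def test_repulsive_inward_rejected(self, nucleus):
        with pytest.raises(ValueError):
            drift_transit_time(5e-6, 3e-6, +2, nucleus, DRAG_B)

    def test_outward_repulsive_transit(self, nucleus):
        t = drift_transit_time(3e-6, 5e-6, +1, nucleus, DRAG_B)
        assert t == pytest.approx(0.0204, rel=1e-2)


class TestIntegrateStep:
    def _pulse_state(self, geometry, rng, n=50, q=-2.0):
        pos = random_positions_on_cap(geometry, (0, 0, 1), 15, n, rng) * UM
        st = SimState(
            [ProteinSpecies("m", iep=9.2)], np.zeros(n, dtype=np.int64), pos
        )
        st.fixed_charge[:] = q
        return st

    def test_neutral_reduces_to_diffusion(self, geometry, ph_linear, params, rng):
        # all charges zero: RMS of short confined runs matches sqrt(6 D t)
        nuc = NuclearField(q_nucleus=0.0)
        n = 400
        st = SimState(
            [ProteinSpecies("m", iep=9.2)],
            np.zeros(n, dtype=np.int64),
            np.array([[0.0, 0.0, 4e-6]] * n),
            nm_policy="reflect_all",
        )
        st.fixed_charge[:] = 0.0
        x0 = st.pos.copy()
        n_steps = 200  # short: stays far from both walls
        for _ in range(n_steps):
            integrate_step(st, geometry, ph_linear, nuc, params, rng)
        disp = np.linalg.norm(st.pos - x0, axis=1)
        rms = np.sqrt(np.mean(disp**2))
        expected = np.sqrt(6 * st.diffusion_D(params)[0] * n_steps * params.dt)
        se = rms / np.sqrt(2 * n)
        assert abs(rms - expected) < 3 * se

    def test_charged_pulse_arrives_near_release_ray(self, geometry, ph_linear, nucleus, params, rng):
        st = self._pulse_state(geometry, rng, n=30)
        for _ in range(300):
            integrate_step(st, geometry, ph_linear, nucleus, params, rng)
            if st.pinned.all():
                break
        assert st.pinned.all()
        # drift-dominated: angular deviation from the release axis << 90 deg
        pts = st.arrival_point / UM
        cosang = pts[:, 2] / np.linalg.norm(pts, axis=1)
        assert np.rad2deg(np.arccos(np.clip(cosang, -1, 1))).max() < 45

    def test_speed_cap_invariant(self, geometry, ph_linear, nucleus, params, rng):
        st = self._pulse_state(geometry, rng, n=40)
        for _ in range(50):
            integrate_step(st, geometry, ph_linear, nucleus, params, rng)
            act = st.free
            if not act.any():
                break
            b = st.drag_b(params)[act]
            # recompute the terminal velocity from the actual speeds: the
            # capped speed can never exceed F_max/b; bound via the nuclear
            # force at the smallest admissible radius
            r = np.linalg.norm(st.pos[act], axis=1)
            f_max = (
                params.k_coulomb
                * nucleus.q_nucleus
                * (np.abs(st.charge[act]) * E_CHARGE)
                / (params.epsilon_r * r**2)
            )
            # generous slack for the pairwise contribution
            assert (
                np.linalg.norm(st.vel[act], axis=1) <= (f_max * 1.5 + 1e-30) / b + 1e-12
            ).all()

    def test_overdamped_mode_statistically_equivalent(self, geometry, ph_linear, nucleus, rng):
        means = {}
        for mode in ("capped_newtonian", "overdamped"):
            p = DynamicsParams(mode=mode)
            r = np.random.default_rng(7)
            st = self._pulse_state(geometry, r, n=60)
            for _ in range(400):
                integrate_step(st, geometry, ph_linear, nucleus, p, r)
                if st.pinned.all():
                    break
            means[mode] = np.nanmean(st.arrival_time)
        assert means["capped_newtonian"] == pytest.approx(means["overdamped"], rel=0.05)

    def test_same_seed_same_trajectories(self, geometry, ph_linear, nucleus, params):
        outs = []
        for _ in range(2):
            r = np.random.default_rng(99)
            st = self._pulse_state(geometry, r, n=20)
            for _ in range(150):
                integrate_step(st, geometry, ph_linear, nucleus, params, r)
            outs.append((st.pos.copy(), st.arrival_time.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1], equal_nan=True)

    def test_halved_dt_agrees_within_noise(self, geometry, ph_linear, nucleus):
        means = []
        for dt in (1e-4, 5e-5):
            p = DynamicsParams(dt=dt)
            r = np.random.default_rng(11)
            st = self._pulse_state(geometry, r, n=60)
            for _ in range(int(0.05 / dt)):
                integrate_step(st, geometry, ph_linear, nucleus, p, r)
                if st.pinned.all():
                    break
            means.append(np.nanmean(st.arrival_time))
        assert means[0] == pytest.approx(means[1], rel=0.1)
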