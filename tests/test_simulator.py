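"""Engine and slab-protocol tests: initialization, thermostat, barostat,
box operations and dense-phase extraction."""

import numpy as np
import pytest

import hpslab as h
from hpslab.constants import KB
from hpslab.forcefield import ForceFieldConfig, total_energy_forces
from hpslab.simulator import (SimProtocolConfig, init_slab_configuration,
                              kinetic_temperature, minimize_energy,
                              run_langevin)
from hpslab.synthetic import gen_slab_frame


@pytest.fixture(scope="module")
def toy_chain():
    top = h.build_system([h.ChainSpec("c", "GS" * 25, 1)], (50, 50, 50))
    pos = init_slab_configuration(top, (1, 1, 1), 2.5, seed=2)
    pos = minimize_energy(pos, top, ForceFieldConfig())
    return top, pos


class TestInitSlabConfiguration:
    def test_grid_occupancy(self):
        top = h.build_system([h.ChainSpec("t", "GSGSG", 80)], (30, 30, 40))
        pos = init_slab_configuration(top, (4, 4, 5), 1.2, seed=1)
        centroids = pos.reshape(80, 5, 3).mean(axis=1)
        # each chain centroid sits on its own grid point
        xs = np.round((centroids[:, 0] / (30 / 4)) - 0.5).astype(int)
        ys = np.round((centroids[:, 1] / (30 / 4)) - 0.5).astype(int)
        zs = np.round((centroids[:, 2] / (40 / 5)) - 0.5).astype(int)
        occupied = {(x, y, z) for x, y, z in zip(xs, ys, zs)}
        assert len(occupied) == 80

    def test_confinement_radius_respected(self):
        top = h.build_system([h.ChainSpec("t", "GS" * 15, 6)], (30, 30, 30))
        radius = 1.8
        pos = init_slab_configuration(top, (2, 2, 2), radius, seed=3)
        for c in range(6):
            sl = top.chain_slice(c)
            centroid = pos[sl].mean(axis=0)
            assert np.linalg.norm(pos[sl] - centroid, axis=1).max() <= radius + 1e-9

    def test_bond_lengths_exact(self):
        top = h.build_system([h.ChainSpec("t", "GSGSGSGS", 4)], (20, 20, 20))
        pos = init_slab_configuration(top, (2, 2, 1), 1.5, seed=4)
        d = np.linalg.norm(pos[top.bonds[:, 1]] - pos[top.bonds[:, 0]], axis=1)
        np.testing.assert_allclose(d, 0.38, atol=1e-9)

    def test_grid_too_small_rejected(self):
        top = h.build_system([h.ChainSpec("t", "GS", 9)], (10, 10, 10))
        with pytest.raises(ValueError):
            init_slab_configuration(top, (2, 2, 2), 1.0, seed=1)

    def test_infeasible_confinement_rejected(self):
        top = h.build_system([h.ChainSpec("t", "GS" * 40, 1)], (10, 10, 10))
        with pytest.raises(RuntimeError):
            init_slab_configuration(top, (1, 1, 1), 0.5, seed=1)

    def test_deterministic_given_seed(self):
        top = h.build_system([h.ChainSpec("t", "GS" * 10, 3)], (15, 15, 15))
        p1 = init_slab_configuration(top, (2, 2, 1), 1.5, seed=9)
        p2 = init_slab_configuration(top, (2, 2, 1), 1.5, seed=9)
        np.testing.assert_array_equal(p1, p2)


class TestLangevinDynamics:
    def test_same_seed_bitwise_identical(self, toy_chain):
        top, pos = toy_chain
        cfg = SimProtocolConfig(frame_interval=0.01)
        t1 = run_langevin(pos, top, ForceFieldConfig(), 300.0, 0.05, cfg, seed=5)
        t2 = run_langevin(pos, top, ForceFieldConfig(), 300.0, 0.05, cfg, seed=5)
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_different_seeds_diverge(self, toy_chain):
        top, pos = toy_chain
        cfg = SimProtocolConfig(frame_interval=0.01)
        t1 = run_langevin(pos, top, ForceFieldConfig(), 300.0, 0.02, cfg, seed=5)
        t2 = run_langevin(pos, top, ForceFieldConfig(), 300.0, 0.02, cfg, seed=6)
        assert not np.array_equal(t1.positions, t2.positions)

    def test_kinetic_temperature_tracks_set_point(self, toy_chain):
        top, pos = toy_chain
        cfg = SimProtocolConfig(diag_interval=0.002)
        traj = run_langevin(pos, top, ForceFieldConfig(), 250.0, 0.3, cfg, seed=8)
        mean_t = traj.kinetic_temperature[len(traj.kinetic_temperature) // 4:].mean()
        assert mean_t == pytest.approx(250.0, rel=0.05)

    def test_zero_temperature_energy_conservation(self):
        # velocity-Verlet limit: no thermostat noise at T = 0, energy
        # conserved to O(dt^2) on a two-bead bonded system
        top = h.build_system([h.ChainSpec("b", "GG", 1)], (10, 10, 10))
        ff = ForceFieldConfig()
        pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.45]])  # stretched bond
        v0 = np.zeros((2, 3))
        drifts = []
        for dt in (10.0, 5.0):
            cfg = SimProtocolConfig(timestep=dt, frame_interval=0.01)
            traj = run_langevin(pos, top, ff, 0.0, 0.1, cfg, seed=1,
                                velocities=v0)
            e0, _ = total_energy_forces(pos, top.box, top, ff)
            ef, _ = total_energy_forces(traj.final_positions, top.box, top, ff)
            kin = 0.5 * np.sum(top.mass[:, None] * traj.final_velocities**2)
            drifts.append(abs(ef + kin - e0))
        # bounded second-order energy error: ~(dt*omega)^2 of the bond energy
        assert drifts[0] < 0.01 * abs(e0)
        # halving dt reduces the drift by roughly 4x (second-order method)
        if drifts[1] > 1e-12:
            assert drifts[0] / drifts[1] > 2.0

    def test_free_bead_einstein_relation(self):
        # D = kB T tau / m for an isolated Langevin bead
        top = h.build_system([h.ChainSpec("g", "G", 150)], (400, 400, 400))
        rng = np.random.default_rng(0)
        pos = rng.random((150, 3)) * 400
        cfg = SimProtocolConfig(frame_interval=0.01)
        traj = run_langevin(pos, top, ForceFieldConfig(), 300.0, 1.0, cfg, seed=3)
        res = h.compute_msd(traj, origin_stride=10, max_lag=0.5)
        d_fit, _ = h.fit_msd_linear(res)
        d_true = KB * 300.0 * 5.0 / top.mass[0] * 1000.0  # nm^2/ns
        assert d_fit == pytest.approx(d_true, rel=0.05)

    def test_com_drift_unbiased_over_seeds(self, toy_chain):
        top, pos = toy_chain
        cfg = SimProtocolConfig(frame_interval=0.01)
        drifts = []
        for seed in range(6):
            traj = run_langevin(pos, top, ForceFieldConfig(), 300.0, 0.05,
                                cfg, seed=seed)
            com0 = np.average(pos, axis=0, weights=top.mass)
            com1 = np.average(traj.final_positions, axis=0, weights=top.mass)
            drifts.append(com1 - com0)
        drifts = np.array(drifts)
        per_seed = np.linalg.norm(drifts, axis=1).mean()
        assert np.linalg.norm(drifts.mean(axis=0)) < per_seed


class TestExpandZ:
    def test_box_scaling(self):
        rng = np.random.default_rng(1)
        pos = rng.random((50, 3)) * [6.0, 6.0, 20.0]
        new_pos, new_box = h.expand_z(pos, [6.0, 6.0, 20.0], factor=10.0)
        assert new_box[2] == pytest.approx(200.0)
        assert new_box[0] == 6.0 and new_box[1] == 6.0

    def test_rigid_operation_preserves_distances(self):
        rng = np.random.default_rng(2)
        box = np.array([6.0, 6.0, 20.0])
        # compact slab in the middle so wrapping is unambiguous
        pos = rng.random((40, 3)) * [6.0, 6.0, 4.0] + [0, 0, 8.0]
        new_pos, new_box = h.expand_z(pos, box, factor=10.0)
        d_old = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
        d_new = np.linalg.norm(new_pos[None, :, :] - new_pos[:, None, :], axis=-1)
        np.testing.assert_allclose(d_new, d_old, atol=1e-9)

    def test_slab_recentered_at_midplane(self):
        rng = np.random.default_rng(3)
        box = np.array([6.0, 6.0, 20.0])
        pos = rng.random((40, 3)) * [6.0, 6.0, 4.0] + [0, 0, 1.0]
        new_pos, new_box = h.expand_z(pos, box, factor=5.0)
        assert new_pos[:, 2].mean() == pytest.approx(new_box[2] / 2, abs=0.5)

    def test_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            h.expand_z(np.zeros((2, 3)), [5, 5, 5], factor=1.0)


class TestRelaxCompress:
    def test_attractive_system_compresses(self):
        top = h.build_system([h.ChainSpec("p", "FGFGFGFGFG", 8)], (12, 12, 12))
        pos = init_slab_configuration(top, (2, 2, 2), 1.5, seed=6)
        ff = ForceFieldConfig()
        pos = minimize_energy(pos, top, ff)
        cfg = SimProtocolConfig(frame_interval=0.01)
        new_pos, new_box, _ = h.relax_compress(
            pos, top, ff, temperature=150.0, pressure=1.0, duration=0.3,
            config=cfg, seed=7)
        assert np.prod(new_box) < np.prod(top.box)
        d = new_pos[top.bonds[:, 1]] - new_pos[top.bonds[:, 0]]
        d -= new_box * np.rint(d / new_box)
        assert np.linalg.norm(d, axis=1).max() < 0.76

    def test_barostat_approaches_target_pressure(self):
        # dilute repulsive gas initialized above the target pressure
        top = h.build_system([h.ChainSpec("g", "G", 64)], (7.6, 7.6, 7.6))
        rng = np.random.default_rng(4)
        pos = rng.random((64, 3)) * 7.6
        pos = minimize_energy(pos, top, ForceFieldConfig())
        cfg = SimProtocolConfig(frame_interval=0.1, diag_interval=0.005,
                                compressibility=0.02)
        _, new_box, traj = h.relax_compress(
            pos, top, ForceFieldConfig(), temperature=150.0, pressure=1.0,
            duration=1.0, config=cfg, seed=8)
        late = traj.pressure[len(traj.pressure) // 2:]
        p_init = traj.pressure[0]
        assert abs(late.mean() - 1.0) < abs(p_init - 1.0)
        assert late.mean() == pytest.approx(1.0, abs=1.0)


class TestTemperatureRamp:
    def test_duration_follows_rate(self):
        top = h.build_system([h.ChainSpec("c", "GS" * 10, 1)], (30, 30, 30))
        pos = init_slab_configuration(top, (1, 1, 1), 1.8, seed=2)
        pos = minimize_energy(pos, top, ForceFieldConfig())
        cfg = SimProtocolConfig(frame_interval=0.05)
        traj = h.temperature_ramp(pos, top, ForceFieldConfig(), 200.0, 300.0,
                                  rate=100.0, config=cfg, seed=3)
        assert traj.times[-1] == pytest.approx(1.0)
        # printed protocol arithmetic: 150 K at 0.2 K/ns takes 750 ns
        assert abs(300.0 - 150.0) / SimProtocolConfig().ramp_rate == 750.0

    def test_final_temperature_reaches_target(self):
        top = h.build_system([h.ChainSpec("c", "GS" * 25, 2)], (30, 30, 30))
        pos = init_slab_configuration(top, (2, 1, 1), 2.5, seed=4)
        pos = minimize_energy(pos, top, ForceFieldConfig())
        cfg = SimProtocolConfig(diag_interval=0.002)
        traj = h.temperature_ramp(pos, top, ForceFieldConfig(), 200.0, 320.0,
                                  rate=60.0, config=cfg, seed=5)
        late = traj.kinetic_temperature[-20:].mean()
        assert late == pytest.approx(320.0, rel=0.05)

    def test_equal_temperatures_rejected(self):
        top = h.build_system([h.ChainSpec("c", "GS", 1)], (10, 10, 10))
        with pytest.raises(ValueError):
            h.temperature_ramp(np.zeros((2, 3)), top, ForceFieldConfig(),
                               300.0, 300.0)


class TestExtractDensePhase:
    def test_chain_bookkeeping_and_cubic_box(self):
        top, pos = gen_slab_frame(
            n_chains=150, chain_length=25, dense_density=650.0,
            dilute_density=1.0, interface_width=1.2,
            box=(8.0, 8.0, 60.0), seed=12)
        new_top, new_pos = h.extract_dense_phase(pos, top.box, top)
        assert new_top.box[0] == new_top.box[1] == new_top.box[2]
        # nearly all chains sit in the dense slab for these densities
        assert new_top.n_chains >= 130
        # output density preserves the fitted dense-phase density
        from hpslab.constants import AMU_PER_NM3_TO_MG_PER_CM3
        rho_out = (new_top.total_mass() * AMU_PER_NM3_TO_MG_PER_CM3
                   / np.prod(new_top.box))
        assert rho_out == pytest.approx(650.0, rel=0.15)

    def test_no_dense_phase_is_an_error(self):
        top = h.build_system([h.ChainSpec("u", "G", 400)], (8, 8, 60))
        rng = np.random.default_rng(5)
        pos = rng.random((400, 3)) * top.box
        with pytest.raises(RuntimeError):
            h.extract_dense_phase(pos, top.box, top)
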