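import math

import numpy as np
import pytest
from scipy import stats

from chromodyn import geometry as geo
from chromodyn.engine import (
    EngineError,
    Trajectory,
    run_langevin,
    run_umbrella,
    soft_core_relax,
    _run,
)
from chromodyn.forcefield import BeadTypeTable, Topology, build_topology
from chromodyn.params import SIGMA, ForceFieldParams, SimulationConfig, kbt


def free_bead_topology(n: int, k_bond: float = 0.0,
                       bonds=None, r0=None) -> Topology:
    """Minimal topology: n beads, optional harmonic bonds, no nonbonded
    attraction (all LJ strengths zeroed)."""
    table = BeadTypeTable.default()
    bonds = np.asarray(bonds if bonds is not None else [],
                       dtype=np.int64).reshape(-1, 2)
    nb = len(bonds)
    return Topology(
        bonds=bonds, bond_r0=np.full(nb, r0 if r0 else SIGMA),
        bond_k=np.full(nb, k_bond),
        morse=np.zeros((0, 2), dtype=np.int64), morse_d_e=np.zeros(0),
        morse_a=np.zeros(0), morse_r0=np.zeros(0),
        angles=np.zeros((0, 3), dtype=np.int64), angle_theta0=np.zeros(0),
        angle_k=np.zeros(0),
        bead_type=np.zeros(n, dtype=np.int32), type_table=table,
        eps_matrix=np.zeros((table.n_types, table.n_types)),
        charges=np.zeros(n),
        exclusions=bonds.copy() if nb else np.zeros((0, 2), dtype=np.int64),
        params=ForceFieldParams())


class TestDeterminism:
    def test_same_seed_bit_identical(self, dinucleosome,
                                     dinucleosome_topology):
        cfg = SimulationConfig(n_steps=20_000, dump_interval=2_000, seed=3)
        a = run_langevin(dinucleosome, dinucleosome_topology, cfg)
        b = run_langevin(dinucleosome, dinucleosome_topology, cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seed_differs(self, dinucleosome,
                                    dinucleosome_topology):
        cfg = SimulationConfig(n_steps=20_000, dump_interval=2_000, seed=3)
        cfg2 = SimulationConfig(n_steps=20_000, dump_interval=2_000, seed=4)
        a = run_langevin(dinucleosome, dinucleosome_topology, cfg)
        b = run_langevin(dinucleosome, dinucleosome_topology, cfg2)
        assert not np.array_equal(a.frames, b.frames)


class TestFreeDiffusion:
    def test_msd_slope_is_6kT_over_gamma(self):
        """A free bead diffuses with MSD = 6 (kBT/gamma) t at long times."""
        n = 60
        pos = (np.arange(n * 3, dtype=float).reshape(n, 3)) * 500.0
        top = free_bead_topology(n)
        # bypass the dangling-bead builder check: topology built by hand
        cfg = SimulationConfig(n_steps=60_000, dump_interval=500, seed=8,
                               dt=0.05)
        traj = _run(pos, top, cfg)
        t = traj.frame_steps * cfg.dt
        disp = traj.frames.astype(float) - pos[None]
        msd = (disp ** 2).sum(axis=2).mean(axis=1)
        slope = np.polyfit(t, msd, 1)[0]
        d_expect = 6 * kbt(cfg.temperature) / cfg.gamma
        assert slope == pytest.approx(d_expect, rel=0.05)


class TestEquipartition:
    def test_kinetic_energy_per_dof(self):
        """<KE>/dof = kBT/2 within 2% for a stable bonded system."""
        n = 40
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * SIGMA
        bonds = [(i, i + 1) for i in range(n - 1)]
        top = free_bead_topology(n, k_bond=10.0, bonds=bonds)
        cfg = SimulationConfig(n_steps=150_000, dump_interval=150_000,
                               seed=2, dt=0.01)
        traj = _run(pos, top, cfg)
        assert traj.ke_per_dof == pytest.approx(kbt(300.0) / 2, rel=0.02)


class TestBoltzmannSampling:
    def test_harmonic_dimer_bond_distribution(self):
        """Bond length samples follow r^2 exp(-k (r-r0)^2 / kBT)."""
        pos = np.array([[0.0, 0.0, 0.0], [SIGMA, 0.0, 0.0]])
        k, r0 = 2.0, SIGMA
        top = free_bead_topology(2, k_bond=k, bonds=[(0, 1)], r0=r0)
        cfg = SimulationConfig(n_steps=550_000, dump_interval=50, seed=5,
                               dt=0.01)
        traj = _run(pos, top, cfg)
        r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0],
                           axis=1).astype(float)[1000:]
        kt = kbt(300.0)
        grid = np.linspace(r0 - 6, r0 + 6, 4001)
        pdf = grid ** 2 * np.exp(-k * (grid - r0) ** 2 / kt)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        # decorrelate, then KS against the analytic distribution
        sub = r[::10][:10_000]
        ks = stats.kstest(sub, lambda x: np.interp(x, grid, cdf))
        assert ks.pvalue > 0.01

    def test_damping_independence_of_equilibrium(self):
        """Static averages do not depend on the Langevin damping."""
        pos = np.array([[0.0, 0.0, 0.0], [SIGMA, 0.0, 0.0]])
        top = free_bead_topology(2, k_bond=2.0, bonds=[(0, 1)])
        means = []
        for damp in (40.0, 240.0):
            cfg = SimulationConfig(n_steps=400_000, dump_interval=50,
                                   seed=6, dt=0.01, damping_ns=damp)
            traj = _run(pos, top, cfg)
            r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
            means.append(float(r[2000:].mean()))
        assert means[0] == pytest.approx(means[1], rel=0.01)


class TestBoundaries:
    def test_spherical_wall_contains_beads(self):
        n = 30
        rng = np.random.default_rng(0)
        pos = rng.normal(0, 80.0, (n, 3))
        pos = pos[np.linalg.norm(pos, axis=1) < 230.0][:n]
        n = len(pos)
        top = free_bead_topology(n)
        radius = 300.0
        cfg = SimulationConfig(n_steps=40_000, dump_interval=1_000, seed=4,
                               boundary={"kind": "sphere", "radius": radius})
        traj = _run(pos, top, cfg, boundary=cfg.boundary)
        r = np.linalg.norm(traj.frames.astype(float), axis=2)
        assert r.max() <= radius + SIGMA

    def test_slab_periodic_runs(self):
        n = 20
        rng = np.random.default_rng(1)
        pos = rng.uniform(-100, 100, (n, 3))
        top = free_bead_topology(n)
        cfg = SimulationConfig(
            n_steps=20_000, dump_interval=20_000, seed=4,
            boundary={"kind": "slab", "box": (400.0, 400.0, 1200.0)})
        traj = _run(pos, top, cfg, boundary=cfg.boundary)
        assert traj.n_frames == 1


class TestSoftCoreRelax:
    def test_coincident_beads_get_separated(self):
        spec = geo.FiberSpec.naked_dna("dna", 210.0)
        system = geo.build_fiber(spec)
        system.positions[5] = system.positions[12] + 0.1   # near-coincident
        top = build_topology(system)
        relaxed = soft_core_relax(system, top, steps=4000)
        from chromodyn.engine import min_nonbonded_distance
        assert min_nonbonded_distance(relaxed.positions, top) >= 0.8 * SIGMA
        assert relaxed.n_beads == system.n_beads

    def test_relaxed_system_is_near_fixed_point(self, dinucleosome,
                                                dinucleosome_topology):
        once = soft_core_relax(dinucleosome, dinucleosome_topology,
                               steps=3000)
        twice = soft_core_relax(once, dinucleosome_topology, steps=3000)
        rms = np.sqrt(((twice.positions - once.positions) ** 2)
                      .sum(axis=1).mean())
        assert rms < 0.1 * SIGMA

    def test_unrelaxed_system_rejected_by_engine(self):
        spec = geo.FiberSpec.naked_dna("dna", 210.0)
        system = geo.build_fiber(spec)
        system.positions[5] = system.positions[12] + 0.1
        top = build_topology(system)
        with pytest.raises(EngineError, match="soft_core_relax"):
            run_langevin(system, top, SimulationConfig(n_steps=100,
                                                       dump_interval=100))


class TestUmbrella:
    def test_stiff_spring_pins_colvar(self):
        n = 8
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * 100.0
        top = free_bead_topology(n)
        ga, gb = np.array([0, 1]), np.array([6, 7])
        center = 300.0
        cfg = SimulationConfig(n_steps=40_000, dump_interval=40_000, seed=9)
        windows = run_umbrella(
            type("S", (), {"positions": pos, "boundary": None})(), top,
            ga, gb, [(center, 50.0)], cfg, colvar_interval=50)
        assert windows[0].samples[200:].mean() == pytest.approx(center,
                                                                abs=1.0)

    def test_windows_deterministic(self, dinucleosome,
                                   dinucleosome_topology):
        ga = dinucleosome.nucleosome_beads(0)
        gb = dinucleosome.nucleosome_beads(1)
        cfg = SimulationConfig(n_steps=10_000, dump_interval=10_000, seed=3)
        w1 = run_umbrella(dinucleosome, dinucleosome_topology, ga, gb,
                          [(100.0, 0.2)], cfg, colvar_interval=100)
        w2 = run_umbrella(dinucleosome, dinucleosome_topology, ga, gb,
                          [(100.0, 0.2)], cfg, colvar_interval=100)
        assert np.array_equal(w1[0].samples, w2[0].samples)


class TestTrajectoryContainer:
    def test_frame_times_follow_dump_interval(self, dinucleosome,
                                              dinucleosome_topology):
        cfg = SimulationConfig(n_steps=6_000, dump_interval=2_000, seed=1)
        traj = run_langevin(dinucleosome, dinucleosome_topology, cfg)
        assert traj.n_frames == 3
        assert np.array_equal(traj.frame_steps, [2_000, 4_000, 6_000])
        assert np.allclose(traj.times_ns,
                           traj.frame_steps * cfg.time_scale_ns)

    def test_hdf5_round_trip(self, tmp_path, dinucleosome,
                             dinucleosome_topology):
        cfg = SimulationConfig(n_steps=4_000, dump_interval=2_000, seed=1)
        traj = run_langevin(dinucleosome, dinucleosome_topology, cfg)
        p = tmp_path / "traj.h5"
        traj.to_hdf5(p)
        again = Trajectory.from_hdf5(p)
        assert np.array_equal(again.frames, traj.frames)
        assert again.config.seed == cfg.seed
        assert np.array_equal(again.bead_meta["nuc_id"],
                              traj.bead_meta["nuc_id"])


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(temperature=-1)
    with pytest.raises(ValueError):
        SimulationConfig(dump_interval=0)
    cfg = SimulationConfig()
    assert cfg.damping_steps == pytest.approx(100.0)   # 140 ns / 1.4 ns/step
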