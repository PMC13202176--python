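import math

import numpy as np
import pytest

from chromodyn import analysis as an
from chromodyn.engine import UmbrellaWindow
from chromodyn.params import SIGMA, kbt


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        frames = np.zeros((2, 5, 3))
        assert np.allclose(an.radius_of_gyration(frames).values, 0.0)

    def test_sphere_surface_gives_radius(self):
        # antipodal pairs keep the centroid at the origin exactly
        rng = np.random.default_rng(3)
        v = rng.normal(size=(200, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = 120.0 * np.vstack([v, -v])
        rg = an.radius_of_gyration(pts[None]).values[0]
        assert rg == pytest.approx(12.0)      # nm

    def test_rotation_translation_invariance(self, rng):
        x = rng.normal(size=(1, 40, 3)) * 50
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        moved = x @ rot.T + np.array([100.0, -50.0, 3.0])
        assert an.radius_of_gyration(x).values == pytest.approx(
            an.radius_of_gyration(moved).values)


class TestContactMap:
    def test_frozen_stacked_pair_counts_every_frame(self, dinucleosome):
        # collapse the two nucleosomes onto each other and freeze
        f = dinucleosome.positions.copy()
        b1 = dinucleosome.nucleosome_beads(1)
        f[b1] += (f[dinucleosome.nucleosome_beads(0)].mean(axis=0)
                  - f[b1].mean(axis=0)) + np.array([0.0, 0.0, 60.0])
        frames = np.repeat(f[None], 7, axis=0)
        cm = an.contact_map(frames, dinucleosome.nuc_id)
        assert cm.counts[0, 1] == 7 == cm.n_frames
        assert cm.counts[0, 0] == 7

    def test_symmetric_and_frame_permutation_invariant(self, rng):
        frames = rng.normal(size=(6, 44, 3)) * 40
        nuc_id = np.repeat([0, 1, 2, 3], 11)
        cm1 = an.contact_map(frames, nuc_id)
        cm2 = an.contact_map(frames[::-1].copy(), nuc_id)
        assert np.array_equal(cm1.counts, cm1.counts.T)
        assert np.array_equal(cm1.counts, cm2.counts)

    def test_normalization_pipeline_preserves_symmetry(self, rng):
        n = 30
        raw = rng.poisson(5, (n, n)).astype(float)
        raw = raw + raw.T
        np.fill_diagonal(raw, 50)
        cm = an.ContactMatrix(raw, n_frames=50)
        dist = an.normalize(cm, "distance")
        corr = an.normalize(cm, "correlation")
        for m in (dist, corr):
            assert np.allclose(m.counts, m.counts.T)
        assert dist.normalization == "distance"
        assert corr.normalization == "correlation"


class TestCompartments:
    def _two_block(self, n=20, strong=4.0, weak=1.0):
        m = np.full((n, n), weak)
        h = n // 2
        m[:h, :h] = strong
        m[h:, h:] = strong
        np.fill_diagonal(m, 10.0)
        return an.ContactMatrix(m, n_frames=10)

    def test_pc1_splits_two_blocks_exactly(self):
        """Oracle: the leading eigenvector of the two-block correlation
        matrix separates the blocks by sign."""
        cm = self._two_block()
        corr = an.normalize(cm, "correlation")
        pc1, r = an.compartment_pc1(corr)
        assert np.all(np.sign(pc1[:10]) == np.sign(pc1[0]))
        assert np.all(np.sign(pc1[10:]) == -np.sign(pc1[0]))

    def test_pc1_sign_follows_acetylation(self):
        cm = self._two_block()
        corr = an.normalize(cm, "correlation")
        ac = np.array([2.0] * 10 + [0.1] * 10)
        pc1, r = an.compartment_pc1(corr, acetylation=ac)
        assert r > 0
        assert pc1[:10].mean() > 0

    def test_pc1_permutation_equivariance(self, rng):
        # relabeling nucleosomes permutes PC1 identically (applied to the
        # correlation-normalized map, whose labels are exchangeable)
        cm = self._two_block()
        corr = an.normalize(cm, "correlation")
        pc1, _ = an.compartment_pc1(corr)
        perm = rng.permutation(20)
        corr_p = an.ContactMatrix(corr.counts[np.ix_(perm, perm)],
                                  corr.n_frames,
                                  normalization="correlation")
        pc1_p, _ = an.compartment_pc1(corr_p)
        sign = np.sign(pc1_p[np.argmax(perm == 0)] / pc1[0])
        assert np.allclose(pc1_p, sign * pc1[perm], atol=1e-8)

    def test_insulation_uniform_matrix_is_zero(self):
        m = np.full((40, 40), 3.0)
        cm = an.ContactMatrix(m, n_frames=5)
        ins = an.insulation_score(cm, window=5)
        assert np.allclose(ins[~np.isnan(ins)], 0.0)

    def test_insulation_detects_block_boundary(self):
        cm = self._two_block(n=40)
        ins = an.insulation_score(cm, window=5)
        mid = 20
        interior = np.nanmean([ins[10], ins[30]])
        assert ins[mid] < interior

    def test_comp_coefficient_perfect_blocks_is_one(self):
        n = 8
        m = np.zeros((n, n))
        m[:4, :4] = 2.0
        m[4:, 4:] = 2.0
        np.fill_diagonal(m, 5.0)
        cm = an.ContactMatrix(m, n_frames=3, normalization="distance")
        pc1 = np.array([1.0] * 4 + [-1.0] * 4)
        assert an.compartmentalization_coefficient(cm, pc1) == \
            pytest.approx(1.0)

    def test_comp_coefficient_checkerboard_oracle(self):
        """Hand-summed 3:1 checkerboard observed/expected toy."""
        n = 8
        m = np.ones((n, n))
        m[:4, :4] = 3.0
        m[4:, 4:] = 3.0
        np.fill_diagonal(m, 0.0)
        pc1 = np.array([1.0] * 4 + [-1.0] * 4)
        aa = bb = 12 * 3.0                     # 12 off-diagonal cells/block
        ab = 16 * 1.0                          # upper-triangle cross cells
        expect = (aa + bb - 2 * ab) / (aa + bb + 2 * ab)
        cm = an.ContactMatrix(m, n_frames=1, normalization="distance")
        assert an.compartmentalization_coefficient(cm, pc1) == \
            pytest.approx(expect)


class TestStructureClustering:
    def test_three_archetypes_recovered_exactly(self, rng):
        centers = np.array([[50, 200, 220, 210, 190, 60],
                            [210, 60, 200, 55, 220, 200],
                            [220, 210, 50, 215, 65, 55]], dtype=float)
        feats = np.vstack([c + rng.normal(0, 3, (30, 6)) for c in centers])
        labels, _ = an.cluster_structures(feats, k=3, seed=1)
        groups = [set(labels[i * 30:(i + 1) * 30]) for i in range(3)]
        assert all(len(g) == 1 for g in groups)
        assert len(set.union(*groups)) == 3

    def test_identical_frames_single_cluster(self):
        feats = np.tile([100.0, 90.0, 80.0, 70.0, 60.0, 50.0], (20, 1))
        labels, _ = an.cluster_structures(feats, k=3, seed=0)
        assert len(set(labels.tolist())) == 1

    def test_pair_distance_series(self):
        nuc_id = np.repeat([0, 1, 2], 4)
        f = np.zeros((2, 12, 3))
        f[:, 4:8, 0] = 100.0
        f[:, 8:, 0] = 300.0
        out = an.pair_distance_series(f, nuc_id,
                                      {"E1": [0], "P1": [1], "P2": [2]})
        assert out["E1-P1"].values == pytest.approx([10.0, 10.0])
        assert out["E1-P2"].values == pytest.approx([30.0, 30.0])


class TestMSD:
    def test_brownian_exponent_is_one(self, rng):
        steps = rng.normal(0, 2.0, (600, 80, 3))
        frames = np.cumsum(steps, axis=0)
        series = an.msd(frames, time_per_frame=1.0)
        alpha, k = an.msd_fit(series, fit_range=(1, 100))
        assert alpha == pytest.approx(1.0, abs=0.05)

    def test_immobile_beads_rejected(self):
        frames = np.zeros((50, 5, 3))
        series_ok = an.msd(frames)
        with pytest.raises(an.AnalysisError, match="immobile"):
            an.msd_fit(series_ok)

    def test_plateau_detection_truncates_fit(self, rng):
        t = np.arange(1, 400)
        msd_vals = np.minimum(0.5 * t, 40.0) + rng.normal(0, 0.1, len(t))
        series = an.ObservableSeries("MSD", np.abs(msd_vals), t)
        alpha, _ = an.msd_fit(series)
        assert alpha == pytest.approx(1.0, abs=0.12)


class TestPersistenceLength:
    def test_rigid_rod_is_infinite(self):
        frames = np.zeros((3, 50, 3))
        frames[:, :, 0] = np.arange(50) * SIGMA
        assert an.persistence_length(frames) == math.inf

    def test_discrete_wlc_recovery(self, rng):
        """Analytic oracle: chains generated with Boltzmann bend angles for
        E = K(theta-pi)^2 have l_p = 2 b K / kBT."""
        k_angle = 4.2
        kt = kbt(300.0)
        lp_expect = 2 * SIGMA * k_angle / kt / 10.0    # nm
        n_beads, n_chains = 120, 150
        frames = []
        for _ in range(n_chains):
            t = np.array([0.0, 0.0, 1.0])
            pts = [np.zeros(3)]
            for _ in range(n_beads - 1):
                # sample polar bend from ~theta exp(-K theta^2/kT)
                theta = rng.rayleigh(math.sqrt(kt / (2 * k_angle)))
                phi = rng.uniform(0, 2 * math.pi)
                a = np.cross(t, [1.0, 0.0, 0.0])
                if np.linalg.norm(a) < 1e-6:
                    a = np.cross(t, [0.0, 1.0, 0.0])
                a /= np.linalg.norm(a)
                b = np.cross(t, a)
                t = (math.cos(theta) * t
                     + math.sin(theta) * (math.cos(phi) * a
                                          + math.sin(phi) * b))
                pts.append(pts[-1] + SIGMA * t)
            frames.append(pts)
        lp = an.persistence_length(np.asarray(frames))
        assert lp == pytest.approx(lp_expect, rel=0.10)


class TestSedimentation:
    def test_single_bead_stokes_limit(self):
        frames = np.zeros((1, 1, 3))
        m = 1.0e5     # g/mol
        s = an.sedimentation_coefficient(frames, [m])
        a = (SIGMA / 2) * 1e-10
        f = 6 * math.pi * an.ETA_WATER_20C * a
        expect = (m / 1000.0 / an.AVOGADRO) * \
            (1 - an.VBAR_CHROMATIN * an.RHO_WATER_20C) / f / 1e-13
        assert s == pytest.approx(expect, rel=1e-9)

    def test_touching_dimer_kirkwood_ratio(self):
        """Closed form: a rigid touching dimer sediments 1.5x faster than a
        monomer of the same bead mass."""
        a = SIGMA / 2
        mono = an.sedimentation_coefficient(np.zeros((1, 1, 3)), [1e5])
        dim = an.sedimentation_coefficient(
            np.array([[[0, 0, 0], [2 * a, 0, 0]]], dtype=float), [1e5, 1e5])
        assert dim / mono == pytest.approx(1.5, rel=1e-9)

    def test_compaction_increases_s(self, rng):
        x = rng.normal(size=(1, 60, 3))
        open_ = 200.0 * x
        compact = 80.0 * x
        m = np.full(60, 7000.0)
        assert an.sedimentation_coefficient(compact, m) > \
            an.sedimentation_coefficient(open_, m)


class TestUnwrapping:
    def test_all_wrapped_gives_zero(self, dinucleosome,
                                    dinucleosome_topology):
        frames = np.repeat(dinucleosome.positions[None], 5, axis=0)
        k, err = an.unwrapping_keq(frames, dinucleosome_topology,
                                   dinucleosome, n_blocks=5)
        assert k == 0.0

    def test_two_state_toy_matches_boltzmann(self, dinucleosome,
                                             dinucleosome_topology, rng):
        """Frames constructed from an exact two-state occupancy with known
        free-energy gap recover K_eq = exp(-dG/kBT)."""
        dg = 1.5 * kbt()
        p_open = math.exp(-dg / kbt()) / (1 + math.exp(-dg / kbt()))
        base = dinucleosome.positions
        termini = an.terminus_morse_bonds(dinucleosome_topology,
                                          dinucleosome)
        frames = np.repeat(base[None], 4000, axis=0).astype(float)
        for t, partners in termini.items():
            opens = rng.random(4000) < p_open
            # park the terminus far from every Morse partner
            frames[opens, t] = base[t] + np.array([0.0, 0.0, 400.0])
        k, err = an.unwrapping_keq(frames, dinucleosome_topology,
                                   dinucleosome)
        assert k == pytest.approx(math.exp(-dg / kbt()), abs=3 * err + 0.02)

    def test_bootstrap_error_shrinks_with_length(self, dinucleosome,
                                                 dinucleosome_topology, rng):
        base = dinucleosome.positions
        termini = an.terminus_morse_bonds(dinucleosome_topology,
                                          dinucleosome)
        def make(n):
            fr = np.repeat(base[None], n, axis=0).astype(float)
            for t in termini:
                fr[rng.random(n) < 0.1, t] += 25.0
            return fr
        _, e_short = an.unwrapping_keq(make(400), dinucleosome_topology,
                                       dinucleosome)
        _, e_long = an.unwrapping_keq(make(6400), dinucleosome_topology,
                                      dinucleosome)
        assert e_long < e_short


class TestWham:
    def _mcmc(self, u_func, center, k, rng, n=25_000):
        kt = kbt()
        x = center
        out = []
        for i in range(n):
            xn = x + rng.normal(0, 1.2)
            du = (u_func(xn) + 0.5 * k * (xn - center) ** 2) \
                - (u_func(x) + 0.5 * k * (x - center) ** 2)
            if du <= 0 or rng.random() < math.exp(-du / kt):
                x = xn
            if i > 2000 and i % 4 == 0:
                out.append(x)
        return np.array(out)

    def test_flat_potential_gives_flat_pmf(self, rng):
        w = UmbrellaWindow(center=0.0, k=0.0,
                           samples=rng.uniform(-10, 10, 250_000))
        centers, free = an.wham([w], n_bins=20)
        ok = np.isfinite(free)
        assert free[ok].max() - free[ok].min() < 0.1

    def test_double_well_recovered_within_tolerance(self, rng):
        kt = kbt()

        def u(x):
            return kt * (0.02 * (x ** 2 - 25.0) ** 2 / 25.0)

        windows = [UmbrellaWindow(c, 0.3, self._mcmc(u, c, 0.3, rng))
                   for c in np.arange(-9.0, 9.1, 1.5)]
        centers, free = an.wham(windows)
        analytic = u(centers) / kt
        analytic -= analytic.min()
        ok = np.isfinite(free) & (np.abs(centers) < 8)
        assert np.max(np.abs(free[ok] - analytic[ok])) < 0.2

    def test_window_order_invariance(self, rng):
        kt = kbt()

        def u(x):
            return -3 * kt * np.exp(-0.5 * (x / 3.0) ** 2)

        windows = [UmbrellaWindow(c, 0.3, self._mcmc(u, c, 0.3, rng,
                                                     n=12_000))
                   for c in np.arange(-9.0, 9.1, 3.0)]
        c1, f1 = an.wham(windows, n_bins=60)
        c2, f2 = an.wham(windows[::-1], n_bins=60)
        ok = np.isfinite(f1) & np.isfinite(f2)
        assert np.allclose(f1[ok], f2[ok], atol=1e-6)

    def test_well_depth_helper(self):
        centers = np.linspace(50, 150, 100)
        free = np.where(np.abs(centers - 65) < 5, -4.0, 0.0)
        assert an.pmf_well_depth(centers, free) == pytest.approx(4.0)


class TestSlabDensities:
    def test_uniform_gas_not_phase_separated(self, rng):
        box = (500.0, 500.0, 2000.0)
        nuc_id = np.arange(200)
        frames = rng.uniform(-0.5, 0.5, (200, 200, 3)) * np.array(box)
        dilute, condensed, flag = an.slab_densities(frames, nuc_id, box)
        assert not flag
        assert dilute == pytest.approx(condensed, rel=0.05)

    def test_step_profile_fixture(self, rng):
        """Constructed two-phase profile: 90% of nucleosomes in the central
        20% of the box -> condensed/dilute ratio matches construction."""
        box = (500.0, 500.0, 2000.0)
        n = 1000
        n_in = 900
        z_in = rng.uniform(-200, 200, n_in)
        z_out = rng.uniform(-1000, 1000, n - n_in)
        z_out = z_out[np.abs(z_out) > 210][: n - n_in]
        z = np.concatenate([z_in, z_out, rng.uniform(
            -1000, 1000, n - n_in - len(z_out))])
        frames = np.zeros((1, n, 3))
        frames[0, :, 2] = z[:n]
        frames[0, :, :2] = rng.uniform(-250, 250, (n, 2))
        nuc_id = np.arange(n)
        dilute, condensed, flag = an.slab_densities(frames, nuc_id, box,
                                                    n_bins=40)
        assert flag
        rho_in = n_in / 400.0          # per Å of axis
        rho_out = (n - n_in) / 1600.0
        assert condensed / dilute == pytest.approx(rho_in / rho_out,
                                                   rel=0.5)


class TestScalingExponent:
    def test_ideal_chain_dimension_two(self, rng):
        n = 400
        steps = rng.normal(0, 120.0, (n, 3))
        centers = np.cumsum(steps, axis=0)
        dyads = np.arange(n) * 195.0
        nuc_id = np.arange(n)
        d, _ = an.scaling_exponent(centers[None], nuc_id, dyads,
                                   region_sizes_kb=(5, 10, 20, 40))
        assert d == pytest.approx(2.0, abs=0.3)

    def test_rod_dimension_one(self):
        n = 400
        centers = np.zeros((n, 3))
        centers[:, 0] = np.arange(n) * 100.0
        dyads = np.arange(n) * 195.0
        d, _ = an.scaling_exponent(centers[None], np.arange(n), dyads,
                                   region_sizes_kb=(5, 10, 20, 40))
        assert d == pytest.approx(1.0, abs=0.1)
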