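import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromodyn import geometry as geo
from chromodyn.forcefield import (
    BeadTypeTable,
    ForceFieldError,
    apply_mutation,
    brd4_rule,
    build_topology,
    dh_energy,
    export_lammps,
    lj_energy,
    pair_energy,
    read_lammps,
    reference_bond_pairs,
)
from chromodyn.params import (
    ACETYL_BRD4_NUC,
    ACETYL_NUC,
    AVOGADRO,
    CANONICAL_NUC,
    COULOMB_KCAL,
    KB_KCAL,
    LINKER_DNA,
    LINKER_HISTONE,
    SIGMA,
    ForceFieldParams,
    SimulationConfig,
    debye_length,
)


class TestBeadTypes:
    def test_twenty_types_five_classes(self):
        t = BeadTypeTable.default()
        assert t.n_types == 20
        assert set(t.classes) == {LINKER_DNA, CANONICAL_NUC, ACETYL_NUC,
                                  ACETYL_BRD4_NUC, LINKER_HISTONE}
        assert t.diameter == SIGMA

    def test_charges(self):
        t = BeadTypeTable.default()
        for name, cls, q in zip(t.names, t.classes, t.charges):
            if cls == LINKER_DNA:
                assert q == -7.35
            elif cls == LINKER_HISTONE:
                assert q == 5.0
            else:
                assert q == 0.0


class TestPairMatrix:
    def test_brd4_rule(self):
        p = ForceFieldParams()
        assert brd4_rule(ACETYL_BRD4_NUC, ACETYL_NUC, p) == p.eps_b
        assert brd4_rule(ACETYL_BRD4_NUC, ACETYL_BRD4_NUC, p) == p.eps_b
        # no enhancement toward canonical partners
        assert brd4_rule(ACETYL_BRD4_NUC, CANONICAL_NUC, p) == p.eps_h
        assert brd4_rule(CANONICAL_NUC, CANONICAL_NUC, p) == p.eps_0
        assert brd4_rule(ACETYL_NUC, ACETYL_NUC, p) == p.eps_ac
        with pytest.raises(ForceFieldError):
            brd4_rule("NOT_A_STATE", CANONICAL_NUC, p)

    def test_symmetry_and_ordering(self):
        p = ForceFieldParams()
        classes = (LINKER_DNA, CANONICAL_NUC, ACETYL_NUC, ACETYL_BRD4_NUC,
                   LINKER_HISTONE)
        for a in classes:
            for b in classes:
                assert p.pair_eps(a, b) == p.pair_eps(b, a) > 0
        assert p.eps_ac < p.eps_h < p.eps_0 < p.eps_b

    def test_geometric_mean_mixing(self):
        p = ForceFieldParams()
        assert p.eps_h == pytest.approx(math.sqrt(p.eps_0 * p.eps_ac))


class TestPairEnergy:
    def test_lj_minimum_matches_eps0(self):
        r_min = 2 ** (1 / 6) * SIGMA
        e = pair_energy(CANONICAL_NUC, CANONICAL_NUC, r_min)
        assert e == pytest.approx(-0.115, abs=1.5e-3)   # shifted at 3 sigma

    def test_hybrid_pair_minimum(self):
        r_min = 2 ** (1 / 6) * SIGMA
        e = pair_energy(CANONICAL_NUC, ACETYL_NUC, r_min)
        assert e == pytest.approx(-math.sqrt(0.115 * 0.06), abs=1.5e-3)

    def test_uncharged_pair_vanishes_at_long_range(self):
        assert pair_energy(CANONICAL_NUC, CANONICAL_NUC, 1e6) == 0.0

    def test_debye_length_at_150mM(self):
        # independent closed form: 1/kappa = sqrt(eps0 eps_r kB T / 2 NA e^2 I)
        kbt = KB_KCAL * 300.0
        l_b = COULOMB_KCAL / (78.0 * kbt)
        n = 0.150 * AVOGADRO * 1e-27
        expect = 1.0 / math.sqrt(8 * math.pi * l_b * n)
        assert debye_length(150.0) == pytest.approx(expect, rel=1e-12)
        assert debye_length(150.0) == pytest.approx(7.9, abs=0.15)

    def test_energy_continuity_at_cutoffs(self):
        p = ForceFieldParams()
        rc = p.lj_cutoff_factor * SIGMA
        assert abs(lj_energy(rc - 1e-9, 0.115)) < 1e-10
        lam = debye_length(150.0)
        rc_dh = p.dh_cutoff_debye * lam
        assert abs(dh_energy(rc_dh - 1e-9, 7.35 ** 2, 150.0)) < 1e-10

    def test_unknown_class_pair_rejected(self):
        with pytest.raises(ForceFieldError):
            pair_energy("MYSTERY", CANONICAL_NUC, 40.0)
        with pytest.raises(ForceFieldError):
            pair_energy(CANONICAL_NUC, CANONICAL_NUC, 0.0)

    def test_charged_pair_includes_screened_coulomb(self):
        r = 30.0       # inside the 5-Debye-length cutoff at 150 mM
        e_tot = pair_energy(LINKER_DNA, LINKER_DNA, r, salt_mM=150.0)
        e_lj = lj_energy(r, ForceFieldParams().eps_default)
        lam = debye_length(150.0)
        dh = COULOMB_KCAL * 7.35 ** 2 * math.exp(-r / lam) / (78.0 * r)
        dh -= COULOMB_KCAL * 7.35 ** 2 * math.exp(-5 * lam / lam) / (
            78.0 * 5 * lam)
        assert e_tot - e_lj == pytest.approx(dh, rel=1e-9)


class TestTopology:
    def test_bonded_set_equals_brute_force_scan(self, dinucleosome,
                                                dinucleosome_topology):
        """Within each nucleosome, harmonic + Morse bonds together must be
        exactly the sub-38 Å pairs of the reference geometry."""
        top = dinucleosome_topology
        bonded = {tuple(b) for b in top.bonds.tolist()} | \
                 {tuple(m) for m in top.morse.tolist()}
        for nuc in range(dinucleosome.n_nucleosomes):
            beads = dinucleosome.nucleosome_beads(nuc)
            ref = geo.build_nucleosome(
                dinucleosome.fibers[0].nucleosomes[nuc])
            scan = {(int(beads[a]), int(beads[b]))
                    for a, b, _ in reference_bond_pairs(ref.coords)}
            inside = {p for p in bonded
                      if p[0] in set(beads) and p[1] in set(beads)}
            assert inside == scan

    @given(st.sampled_from([126.0, 136.5, 147.0]), st.booleans())
    @settings(max_examples=6, deadline=None)
    def test_scan_equality_randomized_wraps(self, wrap, h1):
        rec = geo.NucleosomeRecord(wrap / 2, wrap_bp=wrap, h1=h1)
        spec = geo.FiberSpec("one", wrap, [rec], [0.0, 0.0])
        system = geo.build_fiber(spec)
        top = build_topology(system)
        bonded = {tuple(b) for b in top.bonds.tolist()} | \
                 {tuple(m) for m in top.morse.tolist()}
        scan = {(a, b) for a, b, _ in
                reference_bond_pairs(geo.build_nucleosome(rec).coords)}
        assert scan <= bonded            # H1 anchoring may add bonds
        extras = bonded - scan
        h1_roles = (geo.ROLE_H1_GLOBULAR, geo.ROLE_H1_TAIL)
        for (i, j) in extras:
            assert system.role[i] in h1_roles or system.role[j] in h1_roles

    def test_naked_dna_chain_topology(self):
        top = build_topology(geo.build_fiber(geo.FiberSpec.naked_dna(
            "dna", 1050.0)))
        assert len(top.bonds) == 99
        assert len(top.angles) == 98
        assert len(top.morse) == 0
        assert np.allclose(top.bond_r0, SIGMA)
        assert np.allclose(top.angle_theta0, math.pi)

    def test_dinucleosome_morse_bonds(self, dinucleosome_topology):
        """Each terminus binds its core via breakable Morse bonds; every
        Morse bond touches an entry/exit bead."""
        top = dinucleosome_topology
        assert len(top.morse) == 12       # 3 core partners x 2 termini x 2
        assert np.all(top.morse_d_e > 0)

    def test_morse_only_on_termini(self, dinucleosome, dinucleosome_topology):
        for (i, j) in dinucleosome_topology.morse:
            assert geo.ROLE_ENTRY_DNA in (dinucleosome.role[i],
                                          dinucleosome.role[j])

    def test_acetylation_scales_morse_depth(self):
        spec = geo.FiberSpec("a", 147.0,
                             [geo.NucleosomeRecord(73.5, acetylated=True)],
                             [0.0, 0.0])
        p = ForceFieldParams()
        top = build_topology(geo.build_fiber(spec), p)
        assert np.allclose(top.morse_d_e, p.morse_d_e * p.acetyl_unwrap_scale)

    def test_morse_harmonic_limit(self):
        """Near r0 the Morse force constant is 2 d_e a^2 (numeric second
        derivative within 1%)."""
        p = ForceFieldParams()
        d_e, a, r0 = p.morse_d_e, p.morse_a, 25.0
        h = 1e-4

        def u(r):
            return d_e * (1 - math.exp(-a * (r - r0))) ** 2
        curv = (u(r0 + h) - 2 * u(r0) + u(r0 - h)) / h ** 2
        assert curv == pytest.approx(2 * d_e * a ** 2, rel=1e-4)
        # and the configured harmonic-equivalent stiffness matches
        assert curv / 2 == pytest.approx(d_e * a ** 2, rel=0.01)

    def test_dangling_bead_rejected(self):
        spec = geo.FiberSpec.naked_dna("dot", 10.5)    # single bead, no bond
        two = geo.FiberSpec.naked_dna("pair", 21.0)
        sys_ = geo.build_fiber(two)
        sys_.positions = np.vstack([sys_.positions,
                                    geo.build_fiber(spec).positions + 500])
        sys_.fiber_id = np.append(sys_.fiber_id, 1).astype(np.int32)
        sys_.nuc_id = np.append(sys_.nuc_id, -1).astype(np.int32)
        sys_.role = np.append(sys_.role, geo.ROLE_LINKER_DNA).astype(np.int8)
        sys_.fibers.append(spec)
        sys_.fiber_offsets = np.append(sys_.fiber_offsets, 2)
        with pytest.raises(ForceFieldError, match="dangling"):
            build_topology(sys_)

    def test_h1_anchoring_terms(self):
        rec = geo.NucleosomeRecord(73.5, h1=True)
        spec = geo.FiberSpec("chromatosome", 147.0, [rec], [0.0, 0.0])
        system = geo.build_fiber(spec)
        top = build_topology(system)
        h1g = int(np.flatnonzero(system.role == geo.ROLE_H1_GLOBULAR)[0])
        h1t = int(np.flatnonzero(system.role == geo.ROLE_H1_TAIL)[0])
        bonds = {tuple(b) for b in top.bonds.tolist()}
        assert (min(h1g, h1t), max(h1g, h1t)) in bonds
        assert sum(h1g in b for b in bonds) >= 3      # tail + 2 dyad anchors
        assert sum(h1g == a[1] for a in top.angles.tolist()) == 2


class TestMutations:
    @pytest.fixture(scope="class")
    def mixed_system(self):
        spec = geo.FiberSpec.regular(
            "locus", 8, 207.0,
            acetylated=[1, 1, 0, 0, 1, 1, 0, 0],
            brd4=[1, 0, 0, 0, 1, 0, 0, 0],
            h1=[0, 0, 1, 1, 0, 0, 1, 1])
        bg = geo.FiberSpec.regular("bg", 4, 207.0, h1=[1, 0, 0, 1])
        sys1 = geo.build_fiber(spec)
        sys2 = geo.build_fiber(bg)
        sys2.positions += np.array([0.0, 800.0, 0.0])
        return geo._assemble(
            [spec, bg],
            [sys1.positions, sys2.positions],
            [sys1.nuc_id, sys2.nuc_id],
            [sys1.role, sys2.role], None, {})

    def test_delta_interaction(self, mixed_system):
        _, p = apply_mutation(mixed_system, "delta_interaction")
        assert p.eps_0 == 0.06 and p.eps_h == 0.06
        assert p.eps_b == ForceFieldParams().eps_b     # bridging intact

    def test_delta_brd4(self, mixed_system):
        new, _ = apply_mutation(mixed_system, "delta_brd4")
        target = new.nuc_fiber == 0
        assert new.nuc_brd4[target].sum() == 0
        assert new.n_beads == mixed_system.n_beads

    def test_delta_h1_spares_background(self, mixed_system):
        new, _ = apply_mutation(mixed_system, "delta_h1")
        assert not new.nuc_h1[new.nuc_fiber == 0].any()
        assert new.nuc_h1[new.nuc_fiber == 1].sum() == 2
        removed = 4 * 2                                 # 4 H1 x 2 beads
        assert new.n_beads == mixed_system.n_beads - removed
        # background bead count unchanged
        assert (new.fiber_id == 1).sum() == (mixed_system.fiber_id == 1).sum()

    def test_short_linker(self, mixed_system):
        new, _ = apply_mutation(mixed_system, "short_linker", seed=3)
        old_nrl = mixed_system.fibers[0].nrl_bp
        assert new.fibers[0].nrl_bp == pytest.approx(old_nrl - 10.5)
        assert new.fibers[1].nrl_bp == pytest.approx(207.0)
        per_fiber_removed = len(mixed_system.fibers[0].nucleosomes) - 1
        assert (new.fiber_id == 0).sum() == \
            (mixed_system.fiber_id == 0).sum() - per_fiber_removed

    def test_unknown_mode(self, mixed_system):
        with pytest.raises(ForceFieldError):
            apply_mutation(mixed_system, "delta_everything")


class TestLammpsExport:
    def test_round_trip_and_script(self, tmp_path, dinucleosome,
                                   dinucleosome_topology):
        data = tmp_path / "system.data"
        script = tmp_path / "run.in"
        cfg = SimulationConfig(seed=9, n_steps=10 ** 6)
        export_lammps(dinucleosome, dinucleosome_topology, cfg, data, script)
        parsed = read_lammps(data, script)

        top = dinucleosome_topology
        assert len(parsed["types"]) == dinucleosome.n_beads
        assert np.array_equal(parsed["types"], top.bead_type)
        assert np.allclose(parsed["charges"], top.charges)
        assert np.allclose(parsed["positions"], dinucleosome.positions,
                           atol=1e-5)
        assert parsed["dump_interval"] == 100_000

        got_bonds = {(tuple(sorted(p)), c) for p, (_, c) in
                     [(b[0], ("h", b[1])) for b in parsed["bonds"]]}
        want_bonds = {(tuple(sorted((int(i), int(j)))),
                       (round(float(k), 10), round(float(r0), 10)))
                      for (i, j), r0, k in zip(top.bonds, top.bond_r0,
                                               top.bond_k)}
        assert {b[0] for b in got_bonds} == {b[0] for b in want_bonds}
        got_morse = {tuple(sorted(p)) for p, _ in parsed["morse"]}
        assert got_morse == {tuple(sorted((int(i), int(j))))
                             for i, j in top.morse}
        got_angles = {tuple(t) for t, _ in parsed["angles"]}
        assert got_angles == {tuple(map(int, a)) for a in top.angles}

    def test_energy_recomputed_from_export_matches_engine(
            self, tmp_path, dinucleosome, dinucleosome_topology):
        """Independent numpy evaluation of the exported force-field tables
        must reproduce the engine's potential energy on the same frame."""
        from chromodyn.engine import _run

        data = tmp_path / "system.data"
        script = tmp_path / "run.in"
        cfg = SimulationConfig(seed=5, n_steps=2000, dump_interval=2000,
                               dt=0.02)
        export_lammps(dinucleosome, dinucleosome_topology, cfg, data, script)
        parsed = read_lammps(data, script)
        traj = _run(dinucleosome.positions, dinucleosome_topology, cfg)
        frame = traj.final_positions
        engine_pe = _run(frame, dinucleosome_topology,
                         SimulationConfig(seed=5, n_steps=1,
                                          dump_interval=1, dt=1e-9)
                         ).potential_energy[0]

        pe = 0.0
        pos = frame
        n = len(pos)
        lam = 1.0 / parsed["kappa"]
        lj_cut, dh_cut = parsed["lj_cut"], parsed["dh_cut"]
        bonded = set()
        for (i, j), (k, r0) in parsed["bonds"]:
            r = np.linalg.norm(pos[i] - pos[j])
            pe += k * (r - r0) ** 2
            bonded.add((min(i, j), max(i, j)))
        for (i, j), (d_e, a, r0) in parsed["morse"]:
            r = np.linalg.norm(pos[i] - pos[j])
            pe += d_e * (1 - math.exp(-a * (r - r0))) ** 2
            bonded.add((min(i, j), max(i, j)))
        for (i, j, k), (ka, th0_deg) in parsed["angles"]:
            v1, v2 = pos[i] - pos[j], pos[k] - pos[j]
            cth = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            th = math.acos(max(-1, min(1, cth)))
            pe += ka * (th - math.radians(th0_deg)) ** 2
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded:
                    continue
                r = np.linalg.norm(pos[i] - pos[j])
                ti, tj = parsed["types"][i], parsed["types"][j]
                eps, sig = parsed["pair_coeffs"][(min(ti, tj), max(ti, tj))]
                if r < lj_cut:
                    s6 = (sig / r) ** 6
                    s6c = (sig / lj_cut) ** 6
                    pe += 4 * eps * (s6 * s6 - s6) - 4 * eps * (
                        s6c * s6c - s6c)
                qq = parsed["charges"][i] * parsed["charges"][j]
                if qq != 0 and r < dh_cut:
                    pref = COULOMB_KCAL / parsed["dielectric"]
                    pe += pref * qq * (math.exp(-r / lam) / r
                                       - math.exp(-dh_cut / lam) / dh_cut)
        assert pe == pytest.approx(engine_pe, abs=1e-6)
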