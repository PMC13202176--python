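"""Interaction topology, pair potentials and LAMMPS export.

Bead typing: 20 types in 5 interaction classes (linker DNA; canonical,
acetylated and BRD4-associated acetylated nucleosome; linker histone).
Within each nucleosome, harmonic bonds connect every bead pair closer than
38 Å in the reference geometry, keeping the core near-rigid.  The entry and
exit DNA beads are treated specially: each carries a single Morse bond to
its nearest core bead (its other short reference pairs are excluded from
both bonding and nonbonded interactions), which lets the termini detach and
re-attach stochastically - nucleosome breathing.

Nonbonded: Lennard-Jones with class-pair strength (energy-shifted at 3
sigma) plus Debye-Hückel electrostatics between charged beads (linker DNA,
H1), energy-shifted at 5 Debye lengths.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import geometry as geo
from .params import (
    ACETYL_BRD4_NUC,
    ACETYL_NUC,
    CANONICAL_NUC,
    CHARGE_H1,
    CHARGE_LINKER_DNA,
    COULOMB_KCAL,
    LINKER_DNA,
    LINKER_HISTONE,
    SIGMA,
    BOND_CUTOFF,
    ForceFieldParams,
    debye_length,
)


class ForceFieldError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bead type table
# ---------------------------------------------------------------------------

_HIST_NAMES = ("H2A", "H2B", "H3", "H4")


def _make_bead_types():
    """The 20-type enumeration.  Entry/exit beads of BRD4-bound nucleosomes
    share the acetylated entry type (unwrapping energetics follow the
    acetylation level, not BRD4 association)."""
    types = [("linker_dna", LINKER_DNA, CHARGE_LINKER_DNA)]
    for tag, cls in (("c", CANONICAL_NUC), ("a", ACETYL_NUC)):
        types.append((f"nuc_dna_{tag}", cls, 0.0))
        types.append((f"entry_dna_{tag}", cls, 0.0))
        types.extend((f"{h}_{tag}", cls, 0.0) for h in _HIST_NAMES)
    types.append(("nuc_dna_b", ACETYL_BRD4_NUC, 0.0))
    types.extend((f"{h}_b", ACETYL_BRD4_NUC, 0.0) for h in _HIST_NAMES)
    types.append(("h1_globular", LINKER_HISTONE, CHARGE_H1))
    types.append(("h1_tail", LINKER_HISTONE, CHARGE_H1))
    return types


@dataclass
class BeadTypeTable:
    """Per-type name, interaction class and charge; all diameters = sigma."""

    names: list
    classes: list
    charges: np.ndarray
    diameter: float = SIGMA

    @classmethod
    def default(cls) -> "BeadTypeTable":
        t = _make_bead_types()
        return cls(names=[x[0] for x in t], classes=[x[1] for x in t],
                   charges=np.array([x[2] for x in t]))

    @property
    def n_types(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def nucleosome_state(acetylated: bool, brd4: bool) -> str:
    if brd4:
        return ACETYL_BRD4_NUC
    return ACETYL_NUC if acetylated else CANONICAL_NUC


def brd4_rule(state_i: str, state_j: str,
              params: Optional[ForceFieldParams] = None) -> float:
    """Effective LJ strength between two nucleosomes given their states.

    BRD4 enhancement (eps_b) applies whenever at least one partner is
    BRD4-associated and the other is acetylated (with or without BRD4);
    canonical partners never see the enhancement.
    """
    params = params or ForceFieldParams()
    valid = {CANONICAL_NUC, ACETYL_NUC, ACETYL_BRD4_NUC}
    if state_i not in valid or state_j not in valid:
        raise ForceFieldError(f"unknown nucleosome states {state_i}, {state_j}")
    return params.pair_eps(state_i, state_j)


def assign_bead_types(system: geo.SystemStructure,
                      table: Optional[BeadTypeTable] = None) -> np.ndarray:
    """Map every bead to its type index from role + nucleosome state."""
    table = table or BeadTypeTable.default()
    tidx = np.empty(system.n_beads, dtype=np.int32)
    hist_counter = {}
    for i in range(system.n_beads):
        role = system.role[i]
        nuc = system.nuc_id[i]
        if role == geo.ROLE_LINKER_DNA:
            tidx[i] = table.index("linker_dna")
        elif role == geo.ROLE_H1_GLOBULAR:
            tidx[i] = table.index("h1_globular")
        elif role == geo.ROLE_H1_TAIL:
            tidx[i] = table.index("h1_tail")
        else:
            state = nucleosome_state(system.nuc_acetylated[nuc],
                                     system.nuc_brd4[nuc])
            tag = {CANONICAL_NUC: "c", ACETYL_NUC: "a",
                   ACETYL_BRD4_NUC: "b"}[state]
            if role == geo.ROLE_ENTRY_DNA:
                # BRD4 nucleosomes share the acetylated entry type
                tidx[i] = table.index(f"entry_dna_{'a' if tag == 'b' else tag}")
            elif role == geo.ROLE_NUC_DNA:
                tidx[i] = table.index(f"nuc_dna_{tag}")
            else:
                j = hist_counter.get(nuc, 0)
                hist_counter[nuc] = j + 1
                hist = geo.HISTONE_LABELS[j]
                tidx[i] = table.index(f"{hist}_{tag}")
    return tidx


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def lj_energy(r: float, eps: float, sigma: float = SIGMA,
              cutoff: Optional[float] = None) -> float:
    """Energy-shifted 12-6 Lennard-Jones (continuous at the cutoff)."""
    if cutoff is None:
        cutoff = 3.0 * sigma
    if r >= cutoff:
        return 0.0
    def u(x):
        s6 = (sigma / x) ** 6
        return 4.0 * eps * (s6 * s6 - s6)
    return u(r) - u(cutoff)


def dh_energy(r: float, qq: float, salt_mM: float, temperature: float = 300.0,
              dielectric: float = 78.0,
              cutoff_debye: float = 5.0) -> float:
    """Energy-shifted Debye-Hückel; qq is the product of charges (e^2)."""
    lam = debye_length(salt_mM, temperature, dielectric)
    cutoff = cutoff_debye * lam
    if r >= cutoff or qq == 0.0:
        return 0.0
    def u(x):
        return COULOMB_KCAL * qq * math.exp(-x / lam) / (dielectric * x)
    return u(r) - u(cutoff)


def pair_energy(class_i: str, class_j: str, r: float, salt_mM: float = 150.0,
                params: Optional[ForceFieldParams] = None,
                temperature: float = 300.0) -> float:
    """Total nonbonded energy (kcal/mol) between two bead classes at r (Å)."""
    if r <= 0:
        raise ForceFieldError("r must be positive")
    params = params or ForceFieldParams()
    if class_i not in geo_classes() or class_j not in geo_classes():
        raise ForceFieldError(f"unknown class pair ({class_i}, {class_j})")
    e = lj_energy(r, params.pair_eps(class_i, class_j), params.sigma,
                  params.lj_cutoff_factor * params.sigma)
    qi = params.charge_of_class(class_i)
    qj = params.charge_of_class(class_j)
    if qi != 0.0 and qj != 0.0:
        e += dh_energy(r, qi * qj, salt_mM, temperature, params.dielectric,
                       params.dh_cutoff_debye)
    return e


def geo_classes():
    return (LINKER_DNA, CANONICAL_NUC, ACETYL_NUC, ACETYL_BRD4_NUC,
            LINKER_HISTONE)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Complete bonded + nonbonded interaction tables for one system."""

    bonds: np.ndarray            # (nb, 2) int64
    bond_r0: np.ndarray
    bond_k: np.ndarray
    morse: np.ndarray            # (nm, 2) int64
    morse_d_e: np.ndarray
    morse_a: np.ndarray
    morse_r0: np.ndarray
    angles: np.ndarray           # (na, 3) int64
    angle_theta0: np.ndarray
    angle_k: np.ndarray
    bead_type: np.ndarray        # (n,) int32
    type_table: BeadTypeTable
    eps_matrix: np.ndarray       # (T, T) LJ strengths by type pair
    charges: np.ndarray          # (n,) per-bead charge, e
    exclusions: np.ndarray       # (ne, 2) pairs excluded from nonbonded
    params: ForceFieldParams = field(default_factory=ForceFieldParams)

    @property
    def n_beads(self) -> int:
        return len(self.bead_type)

    def exclusion_keys(self) -> np.ndarray:
        n = self.n_beads
        i = np.minimum(self.exclusions[:, 0], self.exclusions[:, 1])
        j = np.maximum(self.exclusions[:, 0], self.exclusions[:, 1])
        return np.unique(i.astype(np.int64) * n + j)


def reference_bond_pairs(coords: np.ndarray,
                         cutoff: float = BOND_CUTOFF):
    """Brute-force scan: all pairs closer than the bond cutoff."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, 1)
    mask = d[iu, ju] < cutoff
    return list(zip(iu[mask].tolist(), ju[mask].tolist(),
                    d[iu, ju][mask].tolist()))


def build_topology(system: geo.SystemStructure,
                   params: Optional[ForceFieldParams] = None) -> Topology:
    params = params or ForceFieldParams()
    table = BeadTypeTable.default()
    bead_type = assign_bead_types(system, table)
    charges = table.charges[bead_type]

    bonds, bond_r0 = [], []
    morse, morse_d, morse_a, morse_r0 = [], [], [], []
    angles, angle_t0, angle_k = [], [], []
    exclusions = set()

    def add_bond(i, j, r0):
        key = (min(i, j), max(i, j))
        if key in exclusions:
            return
        bonds.append(key)
        bond_r0.append(r0)
        exclusions.add(key)

    # --- per-nucleosome internal topology ---------------------------------
    for nuc in range(system.n_nucleosomes):
        beads = system.nucleosome_beads(nuc)
        fib = int(system.nuc_fiber[nuc])
        before = sum(len(f.nucleosomes) for f in system.fibers[:fib])
        rec = system.fibers[fib].nucleosomes[nuc - before]
        ref = geo.build_nucleosome(rec)
        assert len(beads) == len(ref.coords)
        roles = ref.roles
        termini = set(np.flatnonzero(roles == geo.ROLE_ENTRY_DNA).tolist())
        n_dna = rec.n_dna_beads

        scale = params.acetyl_unwrap_scale if rec.acetylated else 1.0
        pairs = reference_bond_pairs(ref.coords)
        if termini and not any(
                (a in termini or b in termini) and abs(a - b) != 1
                for a, b, _ in pairs):
            raise ForceFieldError(
                f"nucleosome {nuc}: terminus has no core partner within "
                f"{BOND_CUTOFF} Å")
        for (a, b, d) in pairs:
            gi, gj = int(beads[a]), int(beads[b])
            chain_pair = abs(a - b) == 1 and a < n_dna and b < n_dna
            if (a in termini or b in termini) and not chain_pair:
                # entry/exit DNA: Morse to every non-chain core partner so
                # the terminus can detach (nucleosome breathing)
                morse.append((min(gi, gj), max(gi, gj)))
                morse_d.append(params.morse_d_e * scale)
                morse_a.append(params.morse_a)
                morse_r0.append(d)
                exclusions.add((min(gi, gj), max(gi, gj)))
            else:
                add_bond(gi, gj, d)

        # H1 anchoring: explicit bonds to the two nearest DNA beads plus the
        # globular-tail bond and two dyad-positioning angles
        if rec.h1:
            g_idx = int(beads[np.flatnonzero(
                roles == geo.ROLE_H1_GLOBULAR)[0]])
            t_idx = int(beads[np.flatnonzero(roles == geo.ROLE_H1_TAIL)[0]])
            gl = np.flatnonzero(roles == geo.ROLE_H1_GLOBULAR)[0]
            tl = np.flatnonzero(roles == geo.ROLE_H1_TAIL)[0]
            dna_local = np.arange(n_dna)
            dist = np.linalg.norm(ref.coords[dna_local] - ref.coords[gl],
                                  axis=1)
            nearest = dna_local[np.argsort(dist)[:2]]
            add_bond(g_idx, t_idx,
                     float(np.linalg.norm(ref.coords[gl] - ref.coords[tl])))
            for a in nearest:
                add_bond(int(beads[a]), g_idx, float(
                    np.linalg.norm(ref.coords[a] - ref.coords[gl])))
                v1 = ref.coords[a] - ref.coords[gl]
                v2 = ref.coords[tl] - ref.coords[gl]
                th0 = math.acos(np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                    -1, 1))
                angles.append((int(beads[a]), g_idx, t_idx))
                angle_t0.append(th0)
                angle_k.append(params.k_angle_h1)

    # --- chain bonds + DNA bending angles along each fiber ----------------
    dna_roles = (geo.ROLE_LINKER_DNA, geo.ROLE_NUC_DNA, geo.ROLE_ENTRY_DNA)
    for fib in range(len(system.fibers)):
        sel = np.flatnonzero(
            (system.fiber_id == fib) & np.isin(system.role, dna_roles))
        # chain order equals bead order by construction
        for a, b in zip(sel, sel[1:]):
            same_nuc = (system.nuc_id[a] == system.nuc_id[b]
                        and system.nuc_id[a] >= 0)
            if not same_nuc:
                add_bond(int(a), int(b), SIGMA)
        for a, b, c in zip(sel, sel[1:], sel[2:]):
            if (system.role[a] == geo.ROLE_LINKER_DNA
                    or system.role[b] == geo.ROLE_LINKER_DNA
                    or system.role[c] == geo.ROLE_LINKER_DNA):
                angles.append((int(a), int(b), int(c)))
                angle_t0.append(math.pi)
                angle_k.append(params.k_angle_dna)

    # --- sanity: no dangling bead -----------------------------------------
    bonded = np.zeros(system.n_beads, dtype=bool)
    for (i, j) in bonds:
        bonded[i] = bonded[j] = True
    for (i, j) in morse:
        bonded[i] = bonded[j] = True
    if system.n_beads > 1 and not bonded.all():
        bad = int(np.flatnonzero(~bonded)[0])
        raise ForceFieldError(f"dangling bead {bad} has no bonds")

    # --- type-pair LJ strength matrix -------------------------------------
    T = table.n_types
    eps = np.empty((T, T))
    for i in range(T):
        for j in range(T):
            eps[i, j] = params.pair_eps(table.classes[i], table.classes[j])

    excl = np.array(sorted(exclusions), dtype=np.int64).reshape(-1, 2)
    return Topology(
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array(bond_r0), bond_k=np.full(len(bonds), params.k_bond),
        morse=np.array(morse, dtype=np.int64).reshape(-1, 2),
        morse_d_e=np.array(morse_d), morse_a=np.array(morse_a),
        morse_r0=np.array(morse_r0),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        angle_theta0=np.array(angle_t0), angle_k=np.array(angle_k),
        bead_type=bead_type, type_table=table, eps_matrix=eps,
        charges=charges, exclusions=excl, params=params)


# ---------------------------------------------------------------------------
# in-silico mutations
# ---------------------------------------------------------------------------

MUTATION_MODES = ("delta_interaction", "delta_brd4", "delta_h1",
                  "short_linker")


def apply_mutation(system: geo.SystemStructure, mode: str,
                   params: Optional[ForceFieldParams] = None,
                   target_fiber: int = 0, seed: int = 0
                   ) -> Tuple[geo.SystemStructure, ForceFieldParams]:
    """Perturbation experiments on the target locus; background untouched.

    delta_interaction: every LJ strength involving canonical nucleosomes is
    reduced to eps_ac (mimicking widespread acetylation without BRD4
    enhancement).  delta_brd4: BRD4-associated nucleosomes demoted to plain
    acetylated.  delta_h1: H1 removed from the target fiber.  short_linker:
    every linker of the target fiber loses one 10.5-bp bead (clamped at 0).
    """
    params = copy.deepcopy(params or ForceFieldParams())
    if mode not in MUTATION_MODES:
        raise ForceFieldError(f"unknown mutation mode {mode!r}")

    if mode == "delta_interaction":
        params.eps_0 = 0.06
        params.eps_h = 0.06
        return system.copy(), params

    if mode == "delta_brd4":
        new = system.copy()
        target_nucs = np.flatnonzero(new.nuc_fiber == target_fiber)
        new.nuc_brd4[target_nucs] = False
        new_records = [
            geo.NucleosomeRecord(r.dyad_position, r.acetylated, False, r.h1,
                                 r.wrap_bp)
            for r in new.fibers[target_fiber].nucleosomes]
        f = new.fibers[target_fiber]
        new.fibers[target_fiber] = geo.FiberSpec(
            f.label + "_dBRD4", f.length_bp, new_records, f.linker_lengths)
        return new, params

    if mode == "delta_h1":
        new = system.copy()
        target_nucs = np.flatnonzero(new.nuc_fiber == target_fiber)
        drop = np.zeros(new.n_beads, dtype=bool)
        for nuc in target_nucs:
            beads = new.nucleosome_beads(nuc)
            h1b = beads[np.isin(new.role[beads],
                                (geo.ROLE_H1_GLOBULAR, geo.ROLE_H1_TAIL))]
            drop[h1b] = True
            new.nuc_h1[nuc] = False
        keep = ~drop
        new.positions = new.positions[keep]
        new.fiber_id = new.fiber_id[keep]
        new.nuc_id = new.nuc_id[keep]
        new.role = new.role[keep]
        new.fiber_offsets = np.searchsorted(
            np.flatnonzero(keep),
            system.fiber_offsets).astype(np.int64)
        f = new.fibers[target_fiber]
        new_records = [
            geo.NucleosomeRecord(r.dyad_position, r.acetylated, r.brd4,
                                 False, r.wrap_bp)
            for r in f.nucleosomes]
        new.fibers[target_fiber] = geo.FiberSpec(
            f.label + "_dH1", f.length_bp, new_records, f.linker_lengths)
        return new, params

    # short_linker: rebuild the target fiber spec with each linker one bead
    # shorter, then regrow it around the untouched background beads
    f = system.fibers[target_fiber]
    new_linkers = []
    for k, l in enumerate(f.linker_lengths):
        internal = 0 < k < len(f.linker_lengths) - 1 or len(
            f.linker_lengths) == 1
        if internal and l > 0:
            shortened = l - geo.BP_PER_BEAD
            if shortened < 0:
                warnings.warn(f"linker {k} shorter than one bead; clamped "
                              f"at 0")
                shortened = 0.0
            new_linkers.append(shortened)
        else:
            if internal and l <= 0:
                warnings.warn(f"linker {k} has length 0; left unchanged")
            new_linkers.append(l)
    shift = 0.0
    new_records = []
    for k, r in enumerate(f.nucleosomes):
        shift += f.linker_lengths[k] - new_linkers[k]
        new_records.append(geo.NucleosomeRecord(
            r.dyad_position - shift, r.acetylated, r.brd4, r.h1, r.wrap_bp))
    new_spec = geo.FiberSpec(
        f.label + "_shortlinker",
        f.length_bp - (sum(f.linker_lengths) - sum(new_linkers)),
        new_records, new_linkers)

    if len(system.fibers) == 1:
        new = geo.build_fiber(new_spec, boundary=system.boundary)
        return new, params
    keep = system.fiber_id != target_fiber
    rng = np.random.default_rng(seed)
    grid = geo._ClashGrid()
    grid.add(system.positions[keep])
    region = system.boundary if system.boundary else \
        {"kind": "sphere",
         "radius": float(np.max(np.linalg.norm(system.positions, axis=1)))
         + 5 * SIGMA}
    if region["kind"] == "slab":
        region = {"kind": "box", "box": region["box"]}
    p, ni, ro = geo._grow_fiber(new_spec, region, grid, rng)
    fibers = list(system.fibers)
    fibers[target_fiber] = new_spec
    order = [target_fiber] + [k for k in range(len(fibers))
                              if k != target_fiber]
    per_pos, per_nid, per_role, per_fib = [], [], [], []
    for k in range(len(fibers)):
        if k == target_fiber:
            per_pos.append(p)
            per_nid.append(ni)
            per_role.append(ro)
        else:
            sel = system.fiber_id == k
            nid = system.nuc_id[sel].copy()
            before_old = sum(len(fb.nucleosomes)
                             for fb in system.fibers[:k])
            nid[nid >= 0] -= before_old
            per_pos.append(system.positions[sel])
            per_nid.append(nid)
            per_role.append(system.role[sel])
        per_fib.append(fibers[k])
    new = geo._assemble(per_fib, per_pos, per_nid, per_role,
                        system.boundary, dict(system.metadata))
    return new, params


# ---------------------------------------------------------------------------
# LAMMPS export / re-import
# ---------------------------------------------------------------------------

def export_lammps(system: geo.SystemStructure, topology: Topology, config,
                  data_path, script_path) -> None:
    """Write a LAMMPS data file (full atom style) and companion input script
    encoding Langevin dynamics at the configured temperature/damping."""
    if system.boundary and system.boundary.get("kind") not in (
            "sphere", "slab", None):
        raise ForceFieldError(
            f"unsupported boundary {system.boundary.get('kind')!r}")
    T = topology.type_table.n_types
    pos = system.positions
    lo = pos.min(axis=0) - 5 * SIGMA
    hi = pos.max(axis=0) + 5 * SIGMA
    if system.boundary and system.boundary["kind"] == "slab":
        lx, ly, lz = system.boundary["box"]
        lo = np.array([-lx / 2, -ly / 2, -lz / 2])
        hi = -lo

    # bond/angle type tables: unique coefficient tuples
    bond_types, bond_of = [], []
    for r0, k in zip(topology.bond_r0, topology.bond_k):
        key = ("harmonic", round(float(k), 10), round(float(r0), 10))
        if key not in bond_types:
            bond_types.append(key)
        bond_of.append(bond_types.index(key))
    for d, a, r0 in zip(topology.morse_d_e, topology.morse_a,
                        topology.morse_r0):
        key = ("morse", round(float(d), 10), round(float(a), 10),
               round(float(r0), 10))
        if key not in bond_types:
            bond_types.append(key)
    morse_of = [bond_types.index(
        ("morse", round(float(d), 10), round(float(a), 10),
         round(float(r0), 10)))
        for d, a, r0 in zip(topology.morse_d_e, topology.morse_a,
                            topology.morse_r0)]
    angle_types, angle_of = [], []
    for t0, k in zip(topology.angle_theta0, topology.angle_k):
        key = (round(float(k), 10), round(float(t0), 10))
        if key not in angle_types:
            angle_types.append(key)
        angle_of.append(angle_types.index(key))

    nb = len(topology.bonds) + len(topology.morse)
    with open(data_path, "w") as fh:
        fh.write("chromodyn coarse-grained chromatin system\n\n")
        fh.write(f"{system.n_beads} atoms\n{nb} bonds\n"
                 f"{len(topology.angles)} angles\n\n")
        fh.write(f"{T} atom types\n{len(bond_types)} bond types\n"
                 f"{max(1, len(angle_types))} angle types\n\n")
        for ax, (l, h) in zip("xyz", zip(lo, hi)):
            fh.write(f"{l:.4f} {h:.4f} {ax}lo {ax}hi\n")
        fh.write("\nMasses\n\n")
        for t in range(T):
            fh.write(f"{t + 1} 1.0\n")
        fh.write("\nAtoms # full\n\n")
        for i in range(system.n_beads):
            q = topology.charges[i]
            x, y, z = pos[i]
            fh.write(f"{i + 1} {system.fiber_id[i] + 1} "
                     f"{topology.bead_type[i] + 1} {q:.4f} "
                     f"{x:.6f} {y:.6f} {z:.6f}\n")
        fh.write("\nBonds\n\n")
        bid = 1
        for (i, j), bt in zip(topology.bonds, bond_of):
            fh.write(f"{bid} {bt + 1} {i + 1} {j + 1}\n")
            bid += 1
        for (i, j), bt in zip(topology.morse, morse_of):
            fh.write(f"{bid} {bt + 1} {i + 1} {j + 1}\n")
            bid += 1
        if len(topology.angles):
            fh.write("\nAngles\n\n")
            for aid, ((i, j, k), at) in enumerate(
                    zip(topology.angles, angle_of), start=1):
                fh.write(f"{aid} {at + 1} {i + 1} {j + 1} {k + 1}\n")

    lam = debye_length(config.salt_mM, config.temperature,
                       topology.params.dielectric)
    lj_cut = topology.params.lj_cutoff_factor * topology.params.sigma
    dh_cut = topology.params.dh_cutoff_debye * lam
    damp = config.damping_steps * config.dt
    kind = (system.boundary or {}).get("kind")
    with open(script_path, "w") as fh:
        w = fh.write
        w("# chromodyn-generated LAMMPS input\n")
        w("# internal units: kcal/mol, Å, unit mass; "
          f"{config.time_scale_ns} ns of physical time per timestep\n")
        w("units real\natom_style full\n")
        w("boundary " + ("p p p" if kind == "slab" else "f f f") + "\n")
        w(f"read_data {data_path}\n\n")
        w(f"pair_style lj/cut/coul/debye {1.0 / lam:.8f} "
          f"{lj_cut:.4f} {dh_cut:.4f}\n")
        w("pair_modify shift yes\n")
        w(f"dielectric {topology.params.dielectric}\n")
        for i in range(T):
            for j in range(i, T):
                w(f"pair_coeff {i + 1} {j + 1} "
                  f"{topology.eps_matrix[i, j]:.6f} "
                  f"{topology.params.sigma:.4f}\n")
        w("\nbond_style hybrid harmonic morse\n")
        for t, key in enumerate(bond_types, start=1):
            if key[0] == "harmonic":
                w(f"bond_coeff {t} harmonic {key[1]} {key[2]}\n")
            else:
                w(f"bond_coeff {t} morse {key[1]} {key[2]} {key[3]}\n")
        w("angle_style harmonic\n")
        if angle_types:
            for t, (k, t0) in enumerate(angle_types, start=1):
                w(f"angle_coeff {t} {k} {math.degrees(t0):.6f}\n")
        else:
            w("angle_coeff 1 1.0 180.0\n")
        w("special_bonds lj/coul 0.0 1.0 1.0\n\n")
        if kind == "sphere":
            r = system.boundary["radius"]
            w(f"region nucleus sphere 0 0 0 {r:.4f} side in\n")
            w(f"fix wall all wall/region nucleus lj126 1.0 "
              f"{topology.params.sigma} "
              f"{topology.params.sigma * 2 ** (1 / 6):.6f}\n")
        w(f"\nvelocity all create {config.temperature} {config.seed}\n")
        w(f"fix lang all langevin {config.temperature} {config.temperature} "
          f"{damp:.6f} {config.seed}\n")
        w("fix integ all nve\n")
        w(f"timestep {config.dt}\n")
        w(f"dump traj all custom {config.dump_interval} traj.lammpstrj "
          "id type x y z\n")
        w(f"thermo {config.dump_interval}\n")
        w(f"run {config.n_steps}\n")


def read_lammps(data_path, script_path) -> dict:
    """Parse exported files back into comparable tables (round-trip check
    and independent energy recomputation)."""
    out = {"bonds": [], "morse": [], "angles": [], "types": [],
           "charges": [], "positions": [], "mol": []}
    section = None
    bond_coeffs, angle_coeffs = {}, {}
    with open(script_path) as fh:
        for line in fh:
            t = line.split("#")[0].split()
            if not t:
                continue
            if t[0] == "bond_coeff":
                bond_coeffs[int(t[1])] = (t[2], tuple(map(float, t[3:])))
            elif t[0] == "angle_coeff":
                angle_coeffs[int(t[1])] = tuple(map(float, t[2:]))
            elif t[0] == "pair_style":
                out["kappa"] = float(t[2])
                out["lj_cut"] = float(t[3])
                out["dh_cut"] = float(t[4])
            elif t[0] == "pair_coeff":
                out.setdefault("pair_coeffs", {})[
                    (int(t[1]) - 1, int(t[2]) - 1)] = (
                    float(t[3]), float(t[4]))
            elif t[0] == "dielectric":
                out["dielectric"] = float(t[1])
            elif t[0] == "dump":
                out["dump_interval"] = int(t[4])

    with open(data_path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].split("#")[0].strip()
        if line in ("Atoms", "Bonds", "Angles", "Masses") or \
                line.startswith("Atoms"):
            section = line.split()[0]
            i += 2
            continue
        if line:
            t = line.split()
            if section == "Atoms":
                out["mol"].append(int(t[1]) - 1)
                out["types"].append(int(t[2]) - 1)
                out["charges"].append(float(t[3]))
                out["positions"].append([float(x) for x in t[4:7]])
            elif section == "Bonds":
                bt = int(t[1])
                style, coeff = bond_coeffs[bt]
                pair = (int(t[2]) - 1, int(t[3]) - 1)
                if style == "harmonic":
                    out["bonds"].append((pair, coeff))
                else:
                    out["morse"].append((pair, coeff))
            elif section == "Angles":
                at = int(t[1])
                out["angles"].append(
                    ((int(t[2]) - 1, int(t[3]) - 1, int(t[4]) - 1),
                     angle_coeffs[at]))
        i += 1
    out["positions"] = np.array(out["positions"])
    out["types"] = np.array(out["types"])
    out["charges"] = np.array(out["charges"])
    return out
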