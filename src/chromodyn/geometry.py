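"""Construction of nucleosome, fiber and multi-fiber system coordinates.

A nucleosome is built as 14 DNA beads on a superhelix of radius 40 Å and
pitch 25 Å (one bead per DNA helical turn, 10.5 bp) plus 8 histone beads on
a coaxial superhelix of radius 18 Å; a chromatosome adds two linker-histone
beads on the dyad axis.  Fibers are bead chains with nucleosomes inserted at
their dyad positions; multi-fiber systems are grown along random
self-avoiding backbones inside a sphere (nucleus-like) or the central region
of an elongated periodic slab box (phase-separation geometry).

All coordinates are in Å internally; reporting helpers convert to nm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .params import (
    BP_PER_BEAD,
    DNA_BEADS_PER_NUC,
    H1_DYAD_DISTANCE,
    H1_TAIL_DISTANCE,
    HISTONE_BEADS,
    SIGMA,
    SUPERHELIX_PITCH,
    SUPERHELIX_R_DNA,
    SUPERHELIX_R_HIST,
    WRAP_BP,
    AVOGADRO,
)

# per-bead role codes
ROLE_LINKER_DNA = 0
ROLE_NUC_DNA = 1
ROLE_ENTRY_DNA = 2      # entry/exit nucleosomal DNA (Morse-bonded termini)
ROLE_HISTONE = 3
ROLE_H1_GLOBULAR = 4
ROLE_H1_TAIL = 5

ROLE_NAMES = {
    ROLE_LINKER_DNA: "linker_dna",
    ROLE_NUC_DNA: "nuc_dna",
    ROLE_ENTRY_DNA: "entry_dna",
    ROLE_HISTONE: "histone",
    ROLE_H1_GLOBULAR: "h1_globular",
    ROLE_H1_TAIL: "h1_tail",
}

# internal role indexing of the eight histone beads along their superhelix
HISTONE_LABELS = ("H3", "H4", "H2A", "H2B", "H2B", "H2A", "H4", "H3")

OVERLAP_TOLERANCE = 0.5 * SIGMA   # pre-relaxation hard-clash distance


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genomic-level records
# ---------------------------------------------------------------------------

@dataclass
class NucleosomeRecord:
    """One nucleosome in genomic coordinates with its epigenetic state."""

    dyad_position: float                  # bp
    acetylated: bool = False
    brd4: bool = False
    h1: bool = False
    wrap_bp: float = float(WRAP_BP)

    def __post_init__(self) -> None:
        if self.brd4 and not self.acetylated:
            raise GeometryError("brd4 implies acetylated")
        n = self.wrap_bp / BP_PER_BEAD
        if abs(n - round(n)) > 1e-9:
            raise GeometryError(
                f"wrap_bp={self.wrap_bp} is not a whole number of "
                f"{BP_PER_BEAD}-bp beads")
        if not (104.5 - 1e-9 <= self.wrap_bp <= 147.0 + 1e-9):
            raise GeometryError("wrap_bp must lie in [104.5, 147]")

    @property
    def n_dna_beads(self) -> int:
        return int(round(self.wrap_bp / BP_PER_BEAD))

    @property
    def n_beads(self) -> int:
        return self.n_dna_beads + HISTONE_BEADS + (2 if self.h1 else 0)


@dataclass
class FiberSpec:
    """Genomic description of one chromatin fiber.

    ``linker_lengths`` has ``len(nucleosomes) + 1`` entries in bp:
    [5' flank, internal linkers..., 3' flank].  A naked-DNA fiber has no
    nucleosomes and a single linker equal to its full length.
    """

    label: str
    length_bp: float
    nucleosomes: list = field(default_factory=list)
    linker_lengths: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.linker_lengths) != len(self.nucleosomes) + 1:
            raise GeometryError(
                "linker_lengths must have len(nucleosomes) + 1 entries")
        if any(l < 0 for l in self.linker_lengths):
            raise GeometryError("linker lengths must be >= 0")
        dyads = [n.dyad_position for n in self.nucleosomes]
        for a, b in zip(self.nucleosomes, self.nucleosomes[1:]):
            min_gap = 0.5 * (a.wrap_bp + b.wrap_bp)
            if b.dyad_position - a.dyad_position < min_gap - 1e-9:
                raise GeometryError(
                    f"overlapping nucleosome footprints at dyads "
                    f"{a.dyad_position} and {b.dyad_position}")
        total = sum(n.wrap_bp for n in self.nucleosomes) + sum(
            self.linker_lengths)
        if abs(total - self.length_bp) > BP_PER_BEAD + 1e-6:
            raise GeometryError(
                f"wraps + linkers = {total} bp but length_bp = "
                f"{self.length_bp} (difference beyond one bead)")
        self._dyads = dyads

    # -- constructors ------------------------------------------------------

    @classmethod
    def regular(cls, label: str, n_nucleosomes: int, nrl_bp: float,
                wrap_bp: float = float(WRAP_BP), acetylated=False,
                brd4=False, h1=False, flank_bp: float = 0.0) -> "FiberSpec":
        """Evenly spaced fiber with a fixed nucleosome repeat length."""
        def flag(value, i):
            return value[i] if isinstance(value, (list, tuple, np.ndarray)) \
                else bool(value)
        linker = nrl_bp - wrap_bp
        if linker < 0:
            raise GeometryError("NRL shorter than the wrap")
        nucs = []
        pos = flank_bp + wrap_bp / 2
        for i in range(n_nucleosomes):
            nucs.append(NucleosomeRecord(
                dyad_position=pos, acetylated=flag(acetylated, i),
                brd4=flag(brd4, i), h1=flag(h1, i), wrap_bp=wrap_bp))
            pos += nrl_bp
        linkers = [flank_bp] + [linker] * max(0, n_nucleosomes - 1) + [flank_bp]
        if n_nucleosomes == 0:
            linkers = [flank_bp]
        length = sum(l for l in linkers) + wrap_bp * n_nucleosomes
        return cls(label, length, nucs, linkers)

    @classmethod
    def naked_dna(cls, label: str, length_bp: float) -> "FiberSpec":
        return cls(label, length_bp, [], [length_bp])

    @classmethod
    def from_dyads(cls, label: str, length_bp: float,
                   records: Sequence[NucleosomeRecord]) -> "FiberSpec":
        """Derive linker lengths from dyad positions on [0, length_bp)."""
        records = sorted(records, key=lambda r: r.dyad_position)
        linkers = []
        prev_end = 0.0
        for r in records:
            start = r.dyad_position - r.wrap_bp / 2
            if start < prev_end - 1e-9:
                raise GeometryError(
                    f"nucleosome at dyad {r.dyad_position} overlaps the "
                    f"previous footprint")
            linkers.append(start - prev_end)
            prev_end = r.dyad_position + r.wrap_bp / 2
        linkers.append(max(0.0, length_bp - prev_end))
        return cls(label, length_bp, list(records), linkers)

    # -- derived quantities ------------------------------------------------

    def linker_bead_counts(self) -> list:
        """Discretized linker beads: each linker independently maps to
        round(linker/10.5) beads; the sub-bead bp remainder is absorbed
        into the genomic length accounting (no bead carries over)."""
        return [int(round(l / BP_PER_BEAD)) for l in self.linker_lengths]

    @property
    def n_beads(self) -> int:
        return sum(r.n_beads for r in self.nucleosomes) + sum(
            self.linker_bead_counts())

    @property
    def nrl_bp(self) -> Optional[float]:
        if len(self.nucleosomes) < 2:
            return None
        d = np.diff([r.dyad_position for r in self.nucleosomes])
        return float(np.mean(d))

    def to_json(self) -> str:
        return json.dumps({
            "label": self.label,
            "length_bp": self.length_bp,
            "linker_lengths": list(map(float, self.linker_lengths)),
            "nucleosomes": [
                {"dyad_position": r.dyad_position,
                 "acetylated": r.acetylated, "brd4": r.brd4, "h1": r.h1,
                 "wrap_bp": r.wrap_bp} for r in self.nucleosomes],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FiberSpec":
        d = json.loads(text)
        nucs = [NucleosomeRecord(**r) for r in d["nucleosomes"]]
        return cls(d["label"], d["length_bp"], nucs, d["linker_lengths"])


def alternating_array(n_nucleosomes: int = 96, block: int = 12,
                      nrl_bp: float = 207.0,
                      label: str = "alternating") -> FiberSpec:
    """Array alternating canonical / acetylated every ``block`` nucleosomes,
    the in-vitro validation construct for checkerboard contact maps."""
    ac = [(i // block) % 2 == 1 for i in range(n_nucleosomes)]
    return FiberSpec.regular(label, n_nucleosomes, nrl_bp, acetylated=ac)


# ---------------------------------------------------------------------------
# single-nucleosome geometry
# ---------------------------------------------------------------------------

# angular step from the fixed 35 Å contour spacing on the superhelix:
# arc length per radian = sqrt(R^2 + (P/2pi)^2)
_ARC_PER_RAD = math.sqrt(SUPERHELIX_R_DNA ** 2 +
                         (SUPERHELIX_PITCH / (2 * math.pi)) ** 2)
DTHETA = SIGMA / _ARC_PER_RAD


@dataclass
class NucleosomeGeometry:
    """Local bead coordinates of one nucleosome in its body frame.

    The superhelix axis is +z, the dyad axis +x, and the center the origin.
    ``entry_index``/``exit_index`` are the first/last DNA beads.
    """

    coords: np.ndarray            # (n, 3) Å
    roles: np.ndarray             # (n,) role codes
    labels: list                  # human-readable per-bead labels
    axis: np.ndarray              # unit vector (0, 0, 1)
    center: np.ndarray            # (0, 0, 0)
    entry_index: int
    exit_index: int


def build_nucleosome(record: NucleosomeRecord) -> NucleosomeGeometry:
    """Place DNA, histone and (optionally) H1 beads in the body frame."""
    n_dna = record.n_dna_beads
    theta = (np.arange(n_dna) - (n_dna - 1) / 2.0) * DTHETA
    z = SUPERHELIX_PITCH * theta / (2 * math.pi)
    dna = np.column_stack([SUPERHELIX_R_DNA * np.cos(theta),
                           SUPERHELIX_R_DNA * np.sin(theta), z])

    # histone beads: evenly spaced over the same angular span, phase-aligned
    # to the DNA midpoint (theta = 0, the dyad)
    span = (n_dna - 1) * DTHETA
    th_h = (np.arange(HISTONE_BEADS) - (HISTONE_BEADS - 1) / 2.0) * (
        span / (HISTONE_BEADS - 1))
    zh = SUPERHELIX_PITCH * th_h / (2 * math.pi)
    hist = np.column_stack([SUPERHELIX_R_HIST * np.cos(th_h),
                            SUPERHELIX_R_HIST * np.sin(th_h), zh])

    coords = [dna, hist]
    roles = [np.full(n_dna, ROLE_NUC_DNA), np.full(HISTONE_BEADS, ROLE_HISTONE)]
    labels = [f"DNA{i + 1}" for i in range(n_dna)] + list(HISTONE_LABELS)
    if record.h1:
        coords.append(np.array([[H1_DYAD_DISTANCE, 0.0, 0.0],
                                [H1_TAIL_DISTANCE, 0.0, 0.0]]))
        roles.append(np.array([ROLE_H1_GLOBULAR, ROLE_H1_TAIL]))
        labels += ["H1g", "H1t"]
    coords = np.concatenate(coords)
    roles = np.concatenate(roles).astype(np.int8)
    roles[0] = ROLE_ENTRY_DNA
    roles[n_dna - 1] = ROLE_ENTRY_DNA
    return NucleosomeGeometry(
        coords=coords, roles=roles, labels=labels,
        axis=np.array([0.0, 0.0, 1.0]), center=np.zeros(3),
        entry_index=0, exit_index=n_dna - 1)


def _frame_rotation(record: NucleosomeRecord) -> np.ndarray:
    """Rotation for the straight-fiber layout: maps the entry->exit chord of
    the body frame onto +x (so the fiber advances monotonically)."""
    geom = build_nucleosome(record)
    chord = geom.coords[geom.exit_index] - geom.coords[geom.entry_index]
    ex = chord / np.linalg.norm(chord)
    # secondary axis: project body +z off ex
    zb = np.array([0.0, 0.0, 1.0])
    ey = zb - np.dot(zb, ex) * ex
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    # rows of R are the target axes expressed in the body frame
    return np.stack([ex, ey, ez])


# ---------------------------------------------------------------------------
# system container
# ---------------------------------------------------------------------------

@dataclass
class SystemStructure:
    """A built multi-fiber bead system.

    Per-bead arrays: ``positions`` (N, 3) Å, ``fiber_id``, ``nuc_id``
    (global nucleosome index, -1 on linker DNA) and ``role`` codes.
    Per-nucleosome arrays carry the epigenetic state flags.
    """

    fibers: list
    fiber_offsets: np.ndarray     # first bead index of each fiber
    positions: np.ndarray
    fiber_id: np.ndarray
    nuc_id: np.ndarray
    role: np.ndarray
    nuc_acetylated: np.ndarray
    nuc_brd4: np.ndarray
    nuc_h1: np.ndarray
    nuc_fiber: np.ndarray         # fiber index of each nucleosome
    boundary: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_nucleosomes(self) -> int:
        return len(self.nuc_acetylated)

    def nucleosome_beads(self, nuc: int) -> np.ndarray:
        return np.flatnonzero(self.nuc_id == nuc)

    def nucleosome_histone_beads(self, nuc: int) -> np.ndarray:
        return np.flatnonzero((self.nuc_id == nuc) & (self.role == ROLE_HISTONE))

    def copy(self) -> "SystemStructure":
        import copy as _copy
        return _copy.deepcopy(self)

    # -- derived bulk properties ------------------------------------------

    def total_bp(self) -> float:
        return float(sum(f.length_bp for f in self.fibers))

    def volume_A3(self) -> float:
        b = self.boundary or {}
        if b.get("kind") == "sphere":
            return 4.0 / 3.0 * math.pi * b["radius"] ** 3
        if b.get("kind") == "slab":
            lx, ly, lz = b["box"]
            return lx * ly * lz
        raise GeometryError("system has no bounded volume")

    def dna_concentration_Mbp_per_um3(self) -> float:
        # 1 um^3 = 1e12 Å^3
        return self.total_bp() / 1e6 / (self.volume_A3() / 1e12)

    def nucleosome_concentration_uM(self) -> float:
        vol_L = self.volume_A3() * 1e-27
        return self.n_nucleosomes / (AVOGADRO * vol_L) * 1e6

    # -- I/O ---------------------------------------------------------------

    def to_xyz(self, path, frame_positions: Optional[np.ndarray] = None):
        pos = self.positions if frame_positions is None else frame_positions
        names = [ROLE_NAMES[r][:2].upper() for r in self.role]
        with open(path, "w") as fh:
            fh.write(f"{self.n_beads}\nchromodyn system\n")
            for nm, p in zip(names, pos):
                fh.write(f"{nm} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")

    def to_pdb(self, path, frames: Optional[np.ndarray] = None):
        """PDB-like export: one residue per bead, one chain per fiber,
        B-factor encodes the bead role code."""
        chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
        frames = (self.positions[None] if frames is None
                  else np.asarray(frames))
        with open(path, "w") as fh:
            for m, pos in enumerate(frames, start=1):
                fh.write(f"MODEL {m:>8d}\n")
                for i in range(self.n_beads):
                    ch = chains[self.fiber_id[i] % len(chains)]
                    name = ROLE_NAMES[self.role[i]][:3].upper()
                    x, y, z = pos[i]
                    fh.write(
                        f"ATOM  {(i % 99999) + 1:>5d} {name:<4s}"
                        f"BED {ch}{(i % 9999) + 1:>4d}    "
                        f"{x / 10:8.3f}{y / 10:8.3f}{z / 10:8.3f}"
                        f"{1.00:6.2f}{float(self.role[i]):6.2f}\n")
                fh.write("ENDMDL\n")

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as h5:
            h5["positions"] = self.positions
            h5["fiber_id"] = self.fiber_id
            h5["nuc_id"] = self.nuc_id
            h5["role"] = self.role
            h5["fiber_offsets"] = self.fiber_offsets
            h5["nuc_acetylated"] = self.nuc_acetylated
            h5["nuc_brd4"] = self.nuc_brd4
            h5["nuc_h1"] = self.nuc_h1
            h5["nuc_fiber"] = self.nuc_fiber
            h5.attrs["boundary"] = json.dumps(self.boundary)
            h5.attrs["fibers"] = json.dumps(
                [json.loads(f.to_json()) for f in self.fibers])
            h5.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def from_hdf5(cls, path) -> "SystemStructure":
        import h5py
        with h5py.File(path, "r") as h5:
            fibers = [FiberSpec.from_json(json.dumps(d))
                      for d in json.loads(h5.attrs["fibers"])]
            boundary = json.loads(h5.attrs["boundary"])
            if boundary and isinstance(boundary.get("box"), list):
                boundary["box"] = tuple(boundary["box"])
            return cls(
                fibers=fibers,
                fiber_offsets=h5["fiber_offsets"][:],
                positions=h5["positions"][:],
                fiber_id=h5["fiber_id"][:], nuc_id=h5["nuc_id"][:],
                role=h5["role"][:],
                nuc_acetylated=h5["nuc_acetylated"][:],
                nuc_brd4=h5["nuc_brd4"][:], nuc_h1=h5["nuc_h1"][:],
                nuc_fiber=h5["nuc_fiber"][:], boundary=boundary,
                metadata=json.loads(h5.attrs["metadata"]))


def _assemble(fibers, per_fiber_positions, per_fiber_nucids, per_fiber_roles,
              boundary, metadata) -> SystemStructure:
    offsets, pos, fid, nid, role = [], [], [], [], []
    ac, brd4, h1, nfib = [], [], [], []
    start = 0
    nuc_offset = 0
    for k, (f, p, ni, ro) in enumerate(zip(
            fibers, per_fiber_positions, per_fiber_nucids, per_fiber_roles)):
        offsets.append(start)
        pos.append(p)
        fid.append(np.full(len(p), k, dtype=np.int32))
        ni = ni.copy()
        ni[ni >= 0] += nuc_offset
        nid.append(ni)
        role.append(ro)
        for r in f.nucleosomes:
            ac.append(r.acetylated)
            brd4.append(r.brd4)
            h1.append(r.h1)
            nfib.append(k)
        start += len(p)
        nuc_offset += len(f.nucleosomes)
    return SystemStructure(
        fibers=list(fibers), fiber_offsets=np.array(offsets, dtype=np.int64),
        positions=np.concatenate(pos) if pos else np.zeros((0, 3)),
        fiber_id=np.concatenate(fid), nuc_id=np.concatenate(nid),
        role=np.concatenate(role),
        nuc_acetylated=np.array(ac, dtype=bool),
        nuc_brd4=np.array(brd4, dtype=bool),
        nuc_h1=np.array(h1, dtype=bool),
        nuc_fiber=np.array(nfib, dtype=np.int32),
        boundary=boundary, metadata=metadata)


# ---------------------------------------------------------------------------
# straight fiber layout
# ---------------------------------------------------------------------------

def _fiber_beads_straight(spec: FiberSpec):
    """Lay the fiber along +x: linker beads at 35 Å spacing, each nucleosome
    oriented so its entry->exit chord continues the chain."""
    positions, nucids, roles = [], [], []
    counts = spec.linker_bead_counts()
    point = np.zeros(3)
    started = False

    def add_linker(n):
        nonlocal point, started
        for _ in range(n):
            if started:
                point = point + np.array([SIGMA, 0.0, 0.0])
            positions.append(point.copy())
            nucids.append(-1)
            roles.append(ROLE_LINKER_DNA)
            started = True

    for i, rec in enumerate(spec.nucleosomes):
        add_linker(counts[i])
        geom = build_nucleosome(rec)
        rot = _frame_rotation(rec)
        entry_local = geom.coords[geom.entry_index]
        entry_target = (point + np.array([SIGMA, 0.0, 0.0])) if started \
            else point.copy()
        shift = entry_target - geom.coords[geom.entry_index] @ rot.T
        world = geom.coords @ rot.T + shift
        positions.extend(world)
        nucids.extend([i] * len(world))
        roles.extend(geom.roles)
        point = world[geom.exit_index]
        started = True
    add_linker(counts[-1])
    return (np.array(positions, dtype=np.float64).reshape(-1, 3),
            np.array(nucids, dtype=np.int32),
            np.array(roles, dtype=np.int8))


def build_fiber(spec: FiberSpec, boundary: Optional[dict] = None
                ) -> SystemStructure:
    """Single straight-path fiber system."""
    p, n, r = _fiber_beads_straight(spec)
    if len(p) == 0:
        raise GeometryError("fiber has no beads")
    return _assemble([spec], [p], [n], [r], boundary,
                     {"layout": "straight",
                      "histone_convention":
                          "8 beads evenly spaced over the DNA angular span, "
                          "phase-aligned to the dyad"})


# ---------------------------------------------------------------------------
# random growth inside bounded regions
# ---------------------------------------------------------------------------

class _ClashGrid:
    """Spatial hash for 0.5-sigma clash rejection during growth.

    ``add`` returns the cell keys of the inserted points so that the most
    recent insertions can be undone (growth backtracking)."""

    def __init__(self, cell: float = SIGMA):
        self.cell = cell
        self.cells = {}

    def _key(self, p):
        return (int(math.floor(p[0] / self.cell)),
                int(math.floor(p[1] / self.cell)),
                int(math.floor(p[2] / self.cell)))

    def add(self, points):
        keys = []
        for p in np.atleast_2d(points):
            k = self._key(p)
            self.cells.setdefault(k, []).append(np.asarray(p))
            keys.append(k)
        return keys

    def remove_last(self, keys):
        """Undo the insertions that produced ``keys`` (most recent first)."""
        for k in reversed(keys):
            self.cells[k].pop()
            if not self.cells[k]:
                del self.cells[k]

    def clashes(self, points, tol: float) -> bool:
        tol2 = tol * tol
        for p in np.atleast_2d(points):
            kx, ky, kz = self._key(p)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for q in self.cells.get((kx + dx, ky + dy, kz + dz),
                                                ()):
                            d = p - q
                            if d @ d < tol2:
                                return True
        return False


def _inside(region, p, margin) -> bool:
    if region["kind"] == "sphere":
        return float(np.linalg.norm(p)) <= region["radius"] - margin
    lx, ly, lz = region["box"]
    frac = region.get("central_fraction", 1.0)
    half = np.array([lx / 2 - margin, ly / 2 - margin,
                     lz / 2 * frac - margin])
    return bool(np.all(np.abs(p) <= half))


def _random_point(region, rng, margin):
    if region["kind"] == "sphere":
        r = region["radius"] - margin
        while True:
            p = rng.uniform(-r, r, 3)
            if p @ p <= r * r:
                return p
    lx, ly, lz = region["box"]
    frac = region.get("central_fraction", 1.0)
    half = np.array([lx / 2 - margin, ly / 2 - margin, lz / 2 * frac - margin])
    return rng.uniform(-half, half)


def _random_unit(rng):
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _grow_fiber(spec: FiberSpec, region: dict, grid: _ClashGrid,
                rng: np.random.Generator, max_restarts: int = 20,
                max_tries: int = 60, backtrack_units: int = 8,
                max_backtracks: int = 4000):
    """Grow one fiber unit-by-unit along a self-avoiding random backbone.

    Units are single linker beads (35 Å steps within a persistence cone) or
    whole rigid nucleosomes at a random orientation, the entry bead
    continuing the chain.  A candidate closer than 0.5 sigma to any placed
    bead (own or other fibers') or outside the region is re-drawn; if a unit
    cannot be placed, growth backtracks a few units and tries a different
    path.  A full restart only happens when backtracking is exhausted.
    """
    # unit plan: interleave linker beads and nucleosomes
    counts = spec.linker_bead_counts()
    nuc_geoms = [build_nucleosome(r) for r in spec.nucleosomes]
    plan = []
    for i in range(len(spec.nucleosomes)):
        plan.extend([("linker", None)] * counts[i])
        plan.append(("nuc", i))
    plan.extend([("linker", None)] * counts[-1])

    for _ in range(max_restarts):
        positions, nucids, roles = [], [], []
        local_grid = _ClashGrid()
        start_point = _random_point(region, rng, margin=SIGMA)
        start_dir = _random_unit(rng)
        # journal entry per placed unit: (n_beads, grid keys, point, dir)
        journal = []
        backtracks = 0
        u = 0
        failed = False

        def clash(pts):
            return (grid.clashes(pts, OVERLAP_TOLERANCE)
                    or local_grid.clashes(pts, OVERLAP_TOLERANCE))

        def state():
            if journal:
                return journal[-1][2], journal[-1][3]
            return start_point, start_dir

        while u < len(plan):
            kind, i = plan[u]
            point, direction = state()
            placed = False
            for _try in range(max_tries):
                step = direction + 0.9 * _random_unit(rng)
                step /= np.linalg.norm(step)
                anchor = (point + SIGMA * step) if journal else point
                if kind == "linker":
                    if not _inside(region, anchor, SIGMA / 2) or \
                            clash(anchor):
                        continue
                    keys = local_grid.add(anchor)
                    positions.append(np.array(anchor))
                    nucids.append(-1)
                    roles.append(ROLE_LINKER_DNA)
                    journal.append((1, keys, np.array(anchor),
                                    step if journal else direction))
                else:
                    geom = nuc_geoms[i]
                    rot = _random_rotation(rng)
                    world = geom.coords @ rot.T
                    world += anchor - world[geom.entry_index]
                    if not all(_inside(region, w, SIGMA / 2)
                               for w in world):
                        continue
                    if clash(world):
                        continue
                    keys = local_grid.add(world)
                    positions.extend(world)
                    nucids.extend([i] * len(world))
                    roles.extend(geom.roles)
                    chord = world[geom.exit_index] - world[geom.entry_index]
                    journal.append((len(world), keys,
                                    world[geom.exit_index].copy(),
                                    chord / np.linalg.norm(chord)))
                placed = True
                break
            if placed:
                u += 1
                continue
            # backtrack a few units and retry along a different path
            backtracks += 1
            if backtracks > max_backtracks or not journal:
                failed = True
                break
            for _ in range(min(backtrack_units, len(journal))):
                nb, keys, _, _ = journal.pop()
                local_grid.remove_last(keys)
                del positions[-nb:]
                del nucids[-nb:]
                del roles[-nb:]
                u -= 1
        if not failed:
            grid.add(np.asarray(positions))
            return (np.asarray(positions, dtype=np.float64).reshape(-1, 3),
                    np.asarray(nucids, dtype=np.int32),
                    np.asarray(roles, dtype=np.int8))
    raise GeometryError(
        f"could not pack fiber '{spec.label}' ({spec.n_beads} beads) in the "
        f"region after {max_restarts} restarts; packing too dense or region "
        f"too small")


def grow_system(target: FiberSpec, background: Iterable[FiberSpec],
                sphere_radius: float, seed: int,
                expected_density_Mbp_um3: Optional[float] = 12.4
                ) -> SystemStructure:
    """Grow the target locus plus background fibers inside a sphere.

    ``sphere_radius`` is in Å.  If ``expected_density_Mbp_um3`` is given the
    realized DNA concentration must match it within 10%.
    """
    background = list(background)
    fibers = [target] + background
    volume = 4.0 / 3.0 * math.pi * sphere_radius ** 3
    density = sum(f.length_bp for f in fibers) / 1e6 / (volume / 1e12)
    if expected_density_Mbp_um3 is not None:
        if abs(density - expected_density_Mbp_um3) > \
                0.1 * expected_density_Mbp_um3:
            raise GeometryError(
                f"input fibers realize {density:.2f} Mbp/um^3, more than 10% "
                f"from the requested {expected_density_Mbp_um3}")
    rng = np.random.default_rng(seed)
    grid = _ClashGrid()
    region = {"kind": "sphere", "radius": float(sphere_radius)}
    built = [_grow_fiber(f, region, grid, rng) for f in fibers]
    return _assemble(fibers, [b[0] for b in built], [b[1] for b in built],
                     [b[2] for b in built],
                     {"kind": "sphere", "radius": float(sphere_radius)},
                     {"seed": int(seed), "layout": "random-backbone growth",
                      "density_Mbp_um3": density})


def design_background_fibers(target: FiberSpec, sphere_radius: float,
                             density_Mbp_um3: float = 12.4,
                             n_fibers: int = 5, nrl_bp: float = 195.0,
                             acetyl_fraction: float = 0.20,
                             h1_fraction: float = 0.31,
                             brd4_of_acetyl: float = 0.167,
                             seed: int = 0) -> list:
    """Background (non-target) fibers sized so the sphere reaches the
    requested DNA density, with flat-probability epigenetic states at the
    locus-average fractions."""
    volume_um3 = 4.0 / 3.0 * math.pi * (sphere_radius / 1e4) ** 3 * 1e-0
    volume_um3 = 4.0 / 3.0 * math.pi * sphere_radius ** 3 / 1e12
    needed_bp = density_Mbp_um3 * 1e6 * volume_um3 - target.length_bp
    if needed_bp <= 0:
        return []
    rng = np.random.default_rng(seed)
    per = needed_bp / n_fibers
    fibers = []
    for i in range(n_fibers):
        n_nuc = max(1, int(round(per / nrl_bp)))
        ac = rng.random(n_nuc) < acetyl_fraction
        h1 = rng.random(n_nuc) < h1_fraction
        brd4 = ac & (rng.random(n_nuc) < brd4_of_acetyl)
        fibers.append(FiberSpec.regular(
            f"background_{i}", n_nuc, nrl_bp, acetylated=ac.tolist(),
            brd4=brd4.tolist(), h1=h1.tolist()))
    return fibers


def build_slab_system(copies: int, fiber: FiberSpec, box, seed: int = 1,
                      central_fraction: float = 0.2) -> SystemStructure:
    """Place ``copies`` of ``fiber`` in an elongated periodic box, initially
    confined to the central slab region (fraction of the long z axis)."""
    if copies < 1:
        raise GeometryError("copies must be >= 1")
    lx, ly, lz = (float(v) for v in box)
    if min(lx, ly, lz) < 4 * SIGMA:
        raise GeometryError("box too small")
    rng = np.random.default_rng(seed)
    grid = _ClashGrid()
    region = {"kind": "box", "box": (lx, ly, lz),
              "central_fraction": central_fraction}
    fibers = [FiberSpec(f"{fiber.label}_{i}", fiber.length_bp,
                        fiber.nucleosomes, fiber.linker_lengths)
              for i in range(copies)]
    built = [_grow_fiber(f, region, grid, rng) for f in fibers]
    system = _assemble(fibers, [b[0] for b in built], [b[1] for b in built],
                       [b[2] for b in built],
                       {"kind": "slab", "box": (lx, ly, lz)},
                       {"seed": int(seed),
                        "central_fraction": central_fraction})
    system.metadata["initial_nucleosome_uM"] = \
        system.nucleosome_concentration_uM()
    return system
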