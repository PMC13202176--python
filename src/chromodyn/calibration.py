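"""Calibration routines for the constants that are fit, not printed.

The DNA bending constant targets the salt-dependent persistence length of
naked DNA; the Morse well depth targets the spontaneous-unwrapping
equilibrium constant of a canonical dinucleosome (K_eq ~ 0.10), and the
acetylation scale its ~3-fold increase on acetylated nucleosomes.  The
resulting defaults are stored in ``ForceFieldParams``; these routines let a
user re-derive or re-target them.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from . import geometry as geo
from .analysis import persistence_length, unwrapping_keq
from .engine import run_langevin
from .forcefield import build_topology
from .params import SIGMA, ForceFieldParams, SimulationConfig, kbt


def bending_constant_for_lp(target_lp_nm: float,
                            bond_length: float = SIGMA,
                            temperature: float = 300.0) -> float:
    """Analytic discrete-WLC mapping: for E = K (theta - pi)^2 the mean
    squared bend per joint is kBT/K, so l_p = 2 b K / kBT."""
    return target_lp_nm * 10.0 * kbt(temperature) / (2.0 * bond_length)


def lp_for_bending_constant(k_angle: float, bond_length: float = SIGMA,
                            temperature: float = 300.0) -> float:
    return 2.0 * bond_length * k_angle / kbt(temperature) / 10.0


def measure_persistence_length(k_angle: float, salt_mM: float = 150.0,
                               n_beads: int = 100, n_steps: int = 400_000,
                               seed: int = 11, charged: bool = True,
                               dt: float = 0.05) -> float:
    """Simulated l_p (nm) of naked DNA at the given bending constant."""
    params = ForceFieldParams(k_angle_dna=k_angle)
    fiber = geo.FiberSpec.naked_dna("dna", n_beads * 10.5)
    system = geo.build_fiber(fiber)
    top = build_topology(system, params)
    if not charged:
        top.charges[:] = 0.0
    cfg = SimulationConfig(salt_mM=salt_mM, dt=dt, n_steps=n_steps,
                           dump_interval=max(2000, n_steps // 200),
                           seed=seed)
    traj = run_langevin(system, top, cfg)
    burn = len(traj.frames) // 4
    return persistence_length(traj.frames[burn:])


def make_dinucleosome(acetylated: bool = False) -> geo.SystemStructure:
    """Two nucleosomes joined by a 63-bp linker, the unwrapping testbed."""
    spec = geo.FiberSpec(
        "dinucleosome", 2 * 147 + 63,
        [geo.NucleosomeRecord(73.5, acetylated=acetylated),
         geo.NucleosomeRecord(73.5 + 147 + 63, acetylated=acetylated)],
        [0, 63, 0])
    return geo.build_fiber(spec)


def measure_keq(params: ForceFieldParams, acetylated: bool = False,
                n_steps: int = 3_000_000, dump_interval: int = 500,
                seed: int = 21, dt: float = 0.05):
    """Unwrapping K_eq of the dinucleosome at the given parameters."""
    system = make_dinucleosome(acetylated)
    top = build_topology(system, params)
    cfg = SimulationConfig(dt=dt, n_steps=n_steps,
                           dump_interval=dump_interval, seed=seed)
    traj = run_langevin(system, top, cfg)
    burn = len(traj.frames) // 10
    return unwrapping_keq(traj.frames[burn:], top, system)


def calibrate_morse_depth(target_keq: float = 0.10,
                          d_values: Optional[Sequence[float]] = None,
                          n_steps: int = 1_500_000, seed: int = 21,
                          base: Optional[ForceFieldParams] = None):
    """Scan Morse well depths, fit ln K_eq vs D (linear in the well depth)
    and return (d_e at target, scan table)."""
    base = base or ForceFieldParams()
    d_values = list(d_values) if d_values is not None else \
        [0.4, 0.55, 0.7, 0.85]
    table = []
    for d in d_values:
        p = dataclasses.replace(base, morse_d_e=d)
        k, err = measure_keq(p, acetylated=False, n_steps=n_steps, seed=seed)
        table.append((d, k, err))
    ds = np.array([t[0] for t in table])
    lnk = np.log(np.maximum([t[1] for t in table], 1e-6))
    slope, intercept = np.polyfit(ds, lnk, 1)
    d_star = (math.log(target_keq) - intercept) / slope
    return float(d_star), table


def nucleosome_pair(acetylated: bool = False, separation: float = 70.0
                    ) -> geo.SystemStructure:
    """Two free mononucleosomes, coaxially stacked at the given center
    separation (Å) - the umbrella-sampling testbed for the stacking PMF."""
    recs = [geo.NucleosomeRecord(73.5, acetylated=acetylated)
            for _ in range(2)]
    specs = [geo.FiberSpec(f"nuc{i}", 147.0, [recs[i]], [0.0, 0.0])
             for i in range(2)]
    geoms = [geo.build_nucleosome(r) for r in recs]
    pos = [geoms[0].coords.copy(),
           geoms[1].coords + np.array([0.0, 0.0, separation])]
    return geo._assemble(
        specs, pos, [g.roles * 0 + np.where(
            g.roles == geo.ROLE_LINKER_DNA, -1, 0) for g in geoms],
        [g.roles for g in geoms], None, {"separation": separation})


def default_pmf_windows() -> list:
    """Dense stiff windows across the contact region, sparser soft windows
    over the unbound plateau."""
    return ([(float(c), 0.4) for c in np.arange(55.0, 100.0, 2.5)]
            + [(float(c), 0.15) for c in np.arange(100.0, 146.0, 5.0)])


def stacking_pmf(acetylated: bool = False,
                 params: Optional[ForceFieldParams] = None,
                 windows: Optional[list] = None,
                 steps_bound: int = 300_000, steps_far: int = 80_000,
                 seed: int = 5, dt: float = 0.05,
                 colvar_interval: int = 40, orient_k: float = 5.0,
                 bound_limit: float = 100.0):
    """PMF along the nucleosome-nucleosome distance in the stacked
    configuration, via umbrella sampling + WHAM.

    The stacked configuration is conditioned by window-independent
    orientation restraints that operationalize the stacking definition
    (center distance as the collective variable; superhelix axes kept
    parallel and aligned with the separation vector, with an angular
    tolerance of ~15 deg rms at the default stiffness, i.e. within the
    30-degree stacking cone).  Because the bias is identical in every
    window, WHAM over the distance umbrella alone reconstructs the exact
    PMF of the orientation-conditioned ensemble; the azimuthal spin of
    the two nucleosomes stays free, so bound windows are sampled longer
    (``steps_bound`` below ``bound_limit`` Å) than plateau windows.
    Returns (well depth in kBT, bin centers, free energy/kBT).
    """
    from .analysis import pmf_well_depth, wham
    from .engine import UmbrellaWindow, _run
    params = params or ForceFieldParams()
    windows = windows or default_pmf_windows()
    system = nucleosome_pair(acetylated, separation=max(windows[0][0], 63.0))
    top = build_topology(system, params)
    ga = np.flatnonzero(system.fiber_id == 0)
    gb = np.flatnonzero(system.fiber_id == 1)
    # histone beads follow the 14 DNA beads within each 22-bead nucleosome;
    # the first/last four sit below/above the disk midplane
    hist1 = ga[14:22]
    hist2 = gb[14:22]
    orient = [{"groups": [hist1[:4], hist1[4:], hist2[:4], hist2[4:]],
               "k": orient_k, "tilt": True}]
    pos = system.positions.copy()
    results = []
    for w, (center, k) in enumerate(windows):
        steps = steps_bound if center < bound_limit else steps_far
        cfg = SimulationConfig(dt=dt, n_steps=steps, dump_interval=steps,
                               seed=seed + 1000 * (w + 1))
        traj = _run(pos, top, cfg,
                    restraints=[{"group_a": ga, "group_b": gb,
                                 "center": float(center), "k": float(k)}],
                    orient_restraint=orient,
                    colvar_interval=colvar_interval)
        burn = len(traj.colvar) // 5
        results.append(UmbrellaWindow(center=float(center), k=float(k),
                                      samples=traj.colvar[burn:].copy()))
        pos = traj.final_positions
    centers, free = wham(results, jacobian=True)
    return pmf_well_depth(centers, free), centers, free


def calibrate_acetyl_scale(params: ForceFieldParams,
                           target_keq: float = 0.32,
                           scales: Optional[Sequence[float]] = None,
                           n_steps: int = 1_500_000, seed: int = 22):
    """Scan the acetyl Morse-depth scale factor toward the acetylated
    unwrapping target."""
    scales = list(scales) if scales is not None else [0.5, 0.65, 0.8]
    table = []
    for s in scales:
        p = dataclasses.replace(params, acetyl_unwrap_scale=s)
        k, err = measure_keq(p, acetylated=True, n_steps=n_steps, seed=seed)
        table.append((s, k, err))
    xs = np.array([t[0] for t in table]) * params.morse_d_e
    lnk = np.log(np.maximum([t[1] for t in table], 1e-6))
    slope, intercept = np.polyfit(xs, lnk, 1)
    d_star = (math.log(target_keq) - intercept) / slope
    return float(d_star / params.morse_d_e), table
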