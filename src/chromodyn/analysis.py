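"""Trajectory observables: compaction, contacts/compartments, dynamics,
polymer statistics, breathing equilibria, WHAM free energies and slab
coexistence densities.

Conventions: trajectory coordinates are in Å; all reported lengths are nm.
Contact definition: two nucleosomes are in contact in a frame when the
minimum distance between any of their beads is below the cutoff
(default 1.5 sigma = 52.5 Å); the cutoff is logged in every ContactMatrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .params import AVOGADRO, SIGMA, kbt

CONTACT_CUTOFF = 1.5 * SIGMA      # Å


class AnalysisError(ValueError):
    pass


@dataclass
class ObservableSeries:
    """A named per-frame or per-lag observable."""

    name: str
    values: np.ndarray
    index: np.ndarray             # frame indices, lag times, ...
    units: str = ""
    replica: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AnalysisError(f"{self.name}: non-finite values")
        if len(self.index) > 1 and np.any(np.diff(self.index) <= 0):
            raise AnalysisError(f"{self.name}: index must increase strictly")


# ---------------------------------------------------------------------------
# compaction
# ---------------------------------------------------------------------------

def radius_of_gyration(frames: np.ndarray, subset=None,
                       name: str = "Rg") -> ObservableSeries:
    """Mass-uniform radius of gyration per frame, reported in nm."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise AnalysisError("need at least one frame")
    x = frames if subset is None else frames[:, np.asarray(subset)]
    com = x.mean(axis=1, keepdims=True)
    rg = np.sqrt(((x - com) ** 2).sum(axis=2).mean(axis=1))
    return ObservableSeries(name, rg / 10.0, np.arange(len(rg)), units="nm")


def nucleosome_centers(frame: np.ndarray, nuc_id: np.ndarray,
                       n_nuc: Optional[int] = None) -> np.ndarray:
    """Centroid of each nucleosome's beads in one frame (Å)."""
    n_nuc = n_nuc if n_nuc is not None else int(nuc_id.max()) + 1
    out = np.zeros((n_nuc, 3))
    counts = np.zeros(n_nuc)
    sel = nuc_id >= 0
    np.add.at(out, nuc_id[sel], frame[sel])
    np.add.at(counts, nuc_id[sel], 1.0)
    return out / counts[:, None]


def scaling_exponent(frames: np.ndarray, nuc_id: np.ndarray,
                     dyads_bp: np.ndarray, nucs: Optional[np.ndarray] = None,
                     region_sizes_kb: Sequence = (5, 10, 15, 20, 25, 30),
                     ) -> Tuple[float, ObservableSeries]:
    """Fractal scaling: mean R_g of N-kb sub-regions ~ N^(1/D); returns D.

    Sub-regions slide along the fiber; the fit is log(Rg) vs log(N).
    """
    if len(region_sizes_kb) < 3:
        raise AnalysisError("need at least 3 region sizes")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    nucs = np.arange(len(dyads_bp)) if nucs is None else np.asarray(nucs)
    dyads = np.asarray(dyads_bp, dtype=float)
    centers = np.stack([nucleosome_centers(f, nuc_id)[nucs] for f in frames])
    mean_rg = []
    for size_kb in region_sizes_kb:
        size = size_kb * 1000.0
        rgs = []
        step = max(1, len(dyads) // 25)
        for s in range(0, len(dyads), step):
            in_reg = np.flatnonzero((dyads >= dyads[s])
                                    & (dyads < dyads[s] + size))
            if len(in_reg) < 3 or dyads[in_reg[-1]] - dyads[s] < 0.7 * size:
                continue
            sub = centers[:, in_reg]
            com = sub.mean(axis=1, keepdims=True)
            rgs.append(np.sqrt(((sub - com) ** 2).sum(axis=2).mean(axis=1)
                               ).mean())
        if not rgs:
            raise AnalysisError(f"no {size_kb}-kb region fits in the locus")
        mean_rg.append(np.mean(rgs))
    sizes = np.asarray(region_sizes_kb, dtype=float)
    slope = np.polyfit(np.log(sizes), np.log(mean_rg), 1)[0]
    series = ObservableSeries("region_Rg", np.asarray(mean_rg) / 10.0,
                              sizes, units="nm")
    return float(1.0 / slope), series


# ---------------------------------------------------------------------------
# contact maps & compartments
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    counts: np.ndarray
    n_frames: int
    normalization: str = "raw"     # raw | distance | correlation
    cutoff: float = CONTACT_CUTOFF
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
            raise AnalysisError("contact matrix must be square symmetric")
        self.counts = c

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def to_tsv(self, path):
        np.savetxt(path, self.counts, delimiter="\t", fmt="%.6g",
                   header=f"normalization={self.normalization} "
                          f"frames={self.n_frames} cutoff={self.cutoff}")


def contact_map(frames: np.ndarray, nuc_id: np.ndarray,
                cutoff: float = CONTACT_CUTOFF, burn_in: int = 0,
                nucs: Optional[np.ndarray] = None) -> ContactMatrix:
    """Nucleosome-level contact counts over frames (after burn-in).

    Contact: minimum inter-bead distance between the two nucleosomes'
    beads < cutoff.  The diagonal is defined as the frame count.
    """
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if burn_in >= len(frames):
        raise AnalysisError("burn_in leaves no frames")
    nuc_id = np.asarray(nuc_id)
    all_nucs = np.arange(int(nuc_id.max()) + 1)
    nucs = all_nucs if nucs is None else np.asarray(nucs)
    keep = np.isin(nuc_id, nucs) & (nuc_id >= 0)
    bead_idx = np.flatnonzero(keep)
    remap = -np.ones(int(nuc_id.max()) + 1, dtype=np.int64)
    remap[nucs] = np.arange(len(nucs))
    bead_nuc = remap[nuc_id[bead_idx]]
    n = len(nucs)
    counts = np.zeros((n, n))
    used = frames[burn_in:]
    for f in used:
        tree = cKDTree(f[bead_idx])
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ni = bead_nuc[pairs[:, 0]]
        nj = bead_nuc[pairs[:, 1]]
        mask = ni != nj
        pij = np.unique(np.stack([np.minimum(ni[mask], nj[mask]),
                                  np.maximum(ni[mask], nj[mask])], axis=1),
                        axis=0)
        counts[pij[:, 0], pij[:, 1]] += 1
    counts = counts + counts.T
    np.fill_diagonal(counts, len(used))
    return ContactMatrix(counts, n_frames=len(used), cutoff=cutoff,
                         metadata={"burn_in": burn_in})


def normalize(matrix: ContactMatrix, mode: str = "distance") -> ContactMatrix:
    """Distance (observed/expected) or correlation normalization."""
    c = matrix.counts.copy()
    n = matrix.n
    if matrix.normalization == "raw" and mode in ("distance", "correlation"):
        idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        expected = np.array([np.mean(np.diag(c, k)) if np.mean(
            np.diag(c, k)) > 0 else np.nan for k in range(n)])
        with np.errstate(invalid="ignore"):
            c = c / expected[idx]
        c[~np.isfinite(c)] = 0.0
        out = ContactMatrix(0.5 * (c + c.T), matrix.n_frames, "distance",
                            matrix.cutoff, dict(matrix.metadata))
        if mode == "distance":
            return out
        matrix = out
        c = matrix.counts
    if mode == "correlation":
        if matrix.normalization != "distance":
            raise AnalysisError("correlation requires distance-normalized")
        sd = c.std(axis=1)
        ok = sd > 0
        corr = np.zeros_like(c)
        sub = np.corrcoef(c[np.ix_(ok, ok)])
        corr[np.ix_(ok, ok)] = sub
        return ContactMatrix(0.5 * (corr + corr.T), matrix.n_frames,
                             "correlation", matrix.cutoff,
                             dict(matrix.metadata))
    raise AnalysisError(f"unknown normalization {mode!r}")


def compartment_pc1(matrix: ContactMatrix,
                    acetylation: Optional[np.ndarray] = None
                    ) -> Tuple[np.ndarray, Optional[float]]:
    """First principal component of the correlation contact map.

    Sign is fixed to correlate positively with acetylation when a per-bin
    acetylation signal is supplied; returns (pc1, Pearson r or None).
    """
    if matrix.normalization != "correlation":
        raise AnalysisError("PC1 requires the correlation-normalized map")
    c = matrix.counts - matrix.counts.mean(axis=0, keepdims=True)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    pc1 = v[:, -1]
    r = None
    if acetylation is not None:
        sig = log_normalize_signal(np.asarray(acetylation, dtype=float))
        r = float(np.corrcoef(pc1, sig)[0, 1])
        if r < 0:
            pc1 = -pc1
            r = -r
    return pc1, r


def log_normalize_signal(signal: np.ndarray,
                         pseudocount: float = None) -> np.ndarray:
    """log(signal / mean signal) with a small pseudocount for empty bins."""
    s = np.asarray(signal, dtype=float)
    if pseudocount is None:
        pos = s[s > 0]
        pseudocount = 0.1 * pos.min() if len(pos) else 1.0
    s = s + pseudocount
    return np.log(s / s.mean())


def insulation_score(matrix: ContactMatrix, window: int = 10) -> np.ndarray:
    """log2(diamond mean / genome-wide expected diamond mean) per bin."""
    if window < 2:
        raise AnalysisError("window must be >= 2 bins")
    c = matrix.counts
    n = matrix.n
    vals = np.full(n, np.nan)
    for i in range(window, n - window):
        vals[i] = c[i - window:i, i + 1:i + 1 + window].mean()
    mean = np.nanmean(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(vals / mean)
    return out


def compartmentalization_coefficient(matrix: ContactMatrix,
                                     pc1: np.ndarray) -> float:
    """COMP = (sum AA + sum BB - 2 sum AB) / (sum AA + sum BB + 2 sum AB)
    over the off-diagonal observed/expected map, with A/B = sign of PC1."""
    if matrix.normalization == "raw":
        matrix = normalize(matrix, "distance")
    c = matrix.counts.copy()
    np.fill_diagonal(c, 0.0)
    a = np.asarray(pc1) >= 0
    aa = c[np.ix_(a, a)].sum()
    bb = c[np.ix_(~a, ~a)].sum()
    ab = c[np.ix_(a, ~a)].sum()
    denom = aa + bb + 2 * ab
    if denom == 0:
        raise AnalysisError("empty contact matrix")
    return float((aa + bb - 2 * ab) / denom)


# ---------------------------------------------------------------------------
# regulatory-element distances & structure clustering
# ---------------------------------------------------------------------------

def pair_distance_series(frames: np.ndarray, nuc_id: np.ndarray,
                         element_nucs: dict) -> dict:
    """Per-frame distances (nm) between all element pairs; each element's
    position is the centroid of its nucleosomes."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    names = sorted(element_nucs)
    cents = {}
    n_nuc = int(nuc_id.max()) + 1
    for f_i, f in enumerate(frames):
        nc = nucleosome_centers(f, nuc_id, n_nuc)
        for nm in names:
            cents.setdefault(nm, []).append(
                nc[np.asarray(element_nucs[nm])].mean(axis=0))
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = np.linalg.norm(np.asarray(cents[a]) - np.asarray(cents[b]),
                               axis=1) / 10.0
            out[f"{a}-{b}"] = ObservableSeries(
                f"{a}-{b}", d, np.arange(len(d)), units="nm")
    return out


def cluster_structures(distance_features: np.ndarray, k: int = 3,
                       seed: int = 0, n_init: int = 50):
    """K-means over standardized pair-distance features; returns
    (labels, centers in original units)."""
    from sklearn.cluster import KMeans
    x = np.asarray(distance_features, dtype=float)
    if x.ndim != 2:
        raise AnalysisError("expected (frames, features)")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.all(sd == 0):
        # identical frames: a single nonempty cluster
        return np.zeros(len(x), dtype=int), x[:1].copy()
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(xs)
    centers = km.cluster_centers_ * sd + mu
    return km.labels_, centers


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def msd(frames: np.ndarray, subset=None, time_per_frame: float = 1.0,
        max_lags: int = 80) -> ObservableSeries:
    """Mean squared displacement (nm^2) vs lag time, averaged over beads and
    time origins (log-spaced lags)."""
    frames = np.asarray(frames, dtype=float)
    x = frames if subset is None else frames[:, np.asarray(subset)]
    F = len(x)
    if F < 3:
        raise AnalysisError("need >= 3 frames for MSD")
    lags = np.unique(np.round(np.logspace(
        0, math.log10(F - 1), min(max_lags, F - 1))).astype(int))
    vals = []
    for lag in lags:
        d = x[lag:] - x[:-lag]
        vals.append((d ** 2).sum(axis=2).mean() / 100.0)   # Å^2 -> nm^2
    return ObservableSeries("MSD", np.asarray(vals), lags * time_per_frame,
                            units="nm^2")


def msd_fit(series: ObservableSeries,
            fit_range: Optional[Tuple[float, float]] = None
            ) -> Tuple[float, float]:
    """Power-law fit MSD = K_alpha * tau^alpha over pre-plateau lags.

    Without an explicit fit range, the plateau onset is detected from the
    local log-log slope falling below half its initial value.
    """
    tau = series.index
    m = series.values
    if np.all(m <= 0):
        raise AnalysisError("immobile beads: MSD is identically zero, "
                            "fit rejected")
    ok = m > 0
    tau, m = tau[ok], m[ok]
    if fit_range is not None:
        sel = (tau >= fit_range[0]) & (tau <= fit_range[1])
    else:
        lt, lm = np.log(tau), np.log(m)
        slopes = np.gradient(lm, lt)
        ref = np.median(slopes[:max(3, len(slopes) // 5)])
        cut = np.flatnonzero(slopes < 0.5 * ref)
        end = cut[0] if len(cut) else len(tau)
        sel = np.zeros(len(tau), dtype=bool)
        sel[:max(end, 5)] = True
    if sel.sum() < 3:
        raise AnalysisError("fit range leaves fewer than 3 lags")
    slope, intercept = np.polyfit(np.log(tau[sel]), np.log(m[sel]), 1)
    return float(slope), float(math.exp(intercept))


def persistence_length(frames: np.ndarray, bond_length: float = SIGMA
                       ) -> float:
    """Persistence length (nm) of a linear bead chain from the exponential
    decay of the tangent-tangent correlation over its first decade.

    Returns inf for a rigid rod (no measurable decay).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    bonds = frames[:, 1:] - frames[:, :-1]
    t = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
    nb = t.shape[1]
    max_sep = nb - 1
    corr = np.empty(max_sep + 1)
    corr[0] = 1.0
    for s in range(1, max_sep + 1):
        corr[s] = np.mean((t[:, :-s] * t[:, s:]).sum(axis=2))
    # fit over the first decade of decay
    sel = np.flatnonzero(corr > 0.1)
    sel = sel[sel <= max_sep]
    if len(sel) < 3 or corr[min(len(corr) - 1, 5)] > 0.999:
        return math.inf
    s = np.arange(len(corr))[sel]
    slope = np.polyfit(s[1:], np.log(corr[sel][1:]), 1)[0]
    if slope >= 0:
        return math.inf
    return float(-bond_length / slope / 10.0)


# ---------------------------------------------------------------------------
# sedimentation
# ---------------------------------------------------------------------------

ETA_WATER_20C = 1.002e-3       # Pa s
RHO_WATER_20C = 998.23         # kg/m^3
VBAR_CHROMATIN = 0.65e-3       # m^3/kg (0.65 mL/g)


def sedimentation_coefficient(frames: np.ndarray, masses: np.ndarray,
                              bead_radius: float = SIGMA / 2,
                              vbar: float = VBAR_CHROMATIN,
                              eta: float = ETA_WATER_20C,
                              rho: float = RHO_WATER_20C) -> float:
    """Ensemble-average s_20,w (Svedberg) via the Kirkwood bead model:
    f = n 6 pi eta a / (1 + (a/n) sum_{i != j} <1/R_ij>)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    a = bead_radius * 1e-10
    mass_kg = float(np.sum(masses)) / 1000.0 / AVOGADRO * 1.0  # kg per chain
    inv_sum = 0.0
    if n > 1:
        iu, ju = np.triu_indices(n, 1)
        for f in frames:
            d = np.linalg.norm(f[iu] - f[ju], axis=1) * 1e-10
            inv_sum += 2.0 * np.sum(1.0 / d)
        inv_sum /= len(frames)
    f_coef = n * 6 * math.pi * eta * a / (1.0 + (a / n) * inv_sum)
    s = mass_kg * (1.0 - vbar * rho) / f_coef
    return float(s / 1e-13)    # Svedberg


# ---------------------------------------------------------------------------
# nucleosome breathing
# ---------------------------------------------------------------------------

def terminus_morse_bonds(topology, system) -> dict:
    """Map each entry/exit bead to its Morse partners and thresholds."""
    from . import geometry as geo
    out = {}
    offset = topology.params.unwrap_offset
    for b, (i, j) in enumerate(topology.morse):
        for t, p in ((i, j), (j, i)):
            if system.role[t] == geo.ROLE_ENTRY_DNA:
                out.setdefault(int(t), []).append(
                    (int(p), float(topology.morse_r0[b] + offset)))
    return out


def unwrapping_keq(frames: np.ndarray, topology, system,
                   n_blocks: int = 10) -> Tuple[float, float]:
    """Unwrapping equilibrium constant K_eq = f_unwrapped / f_wrapped.

    A terminus is unwrapped in a frame when every one of its Morse bonds is
    stretched beyond r0 + 2/a.  The error is a block bootstrap over time.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    termini = terminus_morse_bonds(topology, system)
    if not termini:
        raise AnalysisError("no Morse-bonded termini in this system")
    F = len(frames)
    unwrapped = np.zeros((F, len(termini)), dtype=bool)
    for col, (t, partners) in enumerate(sorted(termini.items())):
        flags = np.ones(F, dtype=bool)
        for (p, thresh) in partners:
            d = np.linalg.norm(frames[:, t] - frames[:, p], axis=1)
            flags &= d > thresh
        unwrapped[:, col] = flags

    def keq_of(rows):
        fu = unwrapped[rows].mean()
        return fu / (1.0 - fu) if fu < 1.0 else math.inf

    k = keq_of(np.arange(F))
    rng = np.random.default_rng(12345)
    blocks = np.array_split(np.arange(F), n_blocks)
    est = []
    for _ in range(200):
        pick = rng.integers(0, n_blocks, n_blocks)
        rows = np.concatenate([blocks[b] for b in pick])
        est.append(keq_of(rows))
    return float(k), float(np.std(est))


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham(windows, temperature: float = 300.0, n_bins: int = 120,
         tol: float = 1e-6, max_iter: int = 50000, jacobian: bool = False,
         bin_range: Optional[Tuple[float, float]] = None):
    """Weighted-histogram reconstruction of the free-energy profile from
    umbrella windows (each with .center, .k and .samples; bias
    0.5 k (x - c)^2).

    Returns (bin centers, free energy in kBT units, zeroed at its minimum
    or, with jacobian=True, at the large-distance plateau after removing
    the 2 kT ln r radial entropy).
    """
    kt = kbt(temperature)
    samples = [np.asarray(w.samples, dtype=float) for w in windows]
    lo = min(s.min() for s in samples) if bin_range is None else bin_range[0]
    hi = max(s.max() for s in samples) if bin_range is None else bin_range[1]
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.stack([np.histogram(s, bins=edges)[0] for s in samples])
    n_k = hists.sum(axis=1).astype(float)
    total = hists.sum(axis=0).astype(float)
    bias = np.stack([0.5 * w.k * (centers - w.center) ** 2 for w in windows])
    boltz = np.exp(-bias / kt)

    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (n_k[:, None] * np.exp(f[:, None] / kt) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        znew = (boltz * p[None, :]).sum(axis=1)
        fnew = -kt * np.log(np.where(znew > 0, znew, 1e-300))
        fnew -= fnew[0]
        if np.max(np.abs(fnew - f)) < tol:
            f = fnew
            break
        f = fnew
    with np.errstate(divide="ignore"):
        free = -np.log(np.where(p > 0, p, np.nan))     # in kBT
    if jacobian:
        # radial colvar in 3D: P(r) ~ r^2 exp(-W/kT)
        free = free + 2.0 * np.log(centers)
        tail = free[np.isfinite(free)][-max(3, n_bins // 8):]
        free = free - np.nanmean(tail)
    else:
        free = free - np.nanmin(free)
    return centers, free


def pmf_well_depth(centers: np.ndarray, free_kbt: np.ndarray,
                   plateau_fraction: float = 0.15) -> float:
    """Well depth in kBT: plateau (mean over the largest distances) minus
    the PMF minimum."""
    ok = np.isfinite(free_kbt)
    c, fe = centers[ok], free_kbt[ok]
    n_tail = max(3, int(len(fe) * plateau_fraction))
    plateau = fe[-n_tail:].mean()
    return float(plateau - fe.min())


# ---------------------------------------------------------------------------
# slab coexistence densities
# ---------------------------------------------------------------------------

def slab_densities(frames: np.ndarray, nuc_id: np.ndarray, box,
                   n_bins: int = 50, axis: int = 2,
                   ratio_threshold: float = 5.0):
    """Coexisting dilute/condensed nucleosome concentrations (μM) from the
    density profile along the long axis of a periodic slab box.

    The profile is re-centered on its densest bin; the condensed phase is
    the plateau around the center (inner half of the above-midpoint
    region), the dilute phase the outer 30% of the box.
    Returns (dilute_uM, condensed_uM, phase_separated_flag).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    lx, ly, lz = (float(v) for v in box)
    L = (lx, ly, lz)[axis]
    others = [lx, ly, lz]
    others.pop(axis)
    bin_vol_L = (L / n_bins) * others[0] * others[1] * 1e-27
    n_nuc = int(np.max(nuc_id)) + 1
    per_frame = []
    for f in frames:
        z = nucleosome_centers(f, nuc_id, n_nuc)[:, axis]
        z = z - L * np.floor(z / L + 0.5)          # wrap to [-L/2, L/2)
        h, _ = np.histogram(z, bins=n_bins, range=(-L / 2, L / 2))
        per_frame.append(h)
    per_frame = np.asarray(per_frame, dtype=float)

    # uniformity pre-test on the uncentered total profile: if its spread is
    # consistent with Poisson counting noise there is a single phase
    raw = per_frame.sum(axis=0)
    m = raw.mean()
    if m == 0 or (raw.max() - raw.min()) < max(6.0 * math.sqrt(max(m, 1.0)),
                                               0.5 * m):
        mean_conc = float(m / len(frames) / (AVOGADRO * bin_vol_L) * 1e6)
        return mean_conc, mean_conc, False

    # recenter each frame on its densest bin, then average
    prof = np.zeros(n_bins)
    for h in per_frame:
        prof += np.roll(h, n_bins // 2 - int(np.argmax(h)))
    prof /= len(frames)
    conc = prof / (AVOGADRO * bin_vol_L) * 1e6      # μM

    mid = 0.5 * (conc.max() + conc.min())
    center = n_bins // 2
    above = np.flatnonzero(conc >= mid)
    half_width = max(1, int((above.max() - above.min() + 1) * 0.25))
    condensed = float(conc[center - half_width:center + half_width + 1]
                      .mean())
    n_out = max(2, int(0.15 * n_bins))
    dilute = float(np.concatenate([conc[:n_out], conc[-n_out:]]).mean())
    flag = dilute == 0 or (condensed / max(dilute, 1e-12) > ratio_threshold)
    return dilute, condensed, bool(flag)
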