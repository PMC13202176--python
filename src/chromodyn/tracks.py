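"""Genomic tracks -> stochastic single-cell chromatin fiber.

Nucleosome dyads come from greedy peak calling on a chemical-mapping-style
positioning score (exclusion zone = one nucleosome footprint).  ChIP-seq
signals for H3K27ac, linker histone H1 and BRD4 define per-nucleosome
Bernoulli probabilities, rescaled so the expected state fractions hit the
locus-average targets (20% acetylated, 31% H1-bound, 16.7% of acetylated
nucleosomes BRD4-bound); BRD4 is drawn only among acetylated nucleosomes.

A synthetic-track generator emulates the statistical structure of the real
data (regular positioning peaks, ~12.5-kb alternating acetylation blocks,
broad H1 signal anti-correlated with acetylation, BRD4 peaks nested inside
acetylation peaks) so the whole pipeline runs without downloads.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import FiberSpec, NucleosomeRecord
from .params import WRAP_BP

FOOTPRINT_BP = 147
DYAD_WINDOW_BP = 73              # signal-at-dyad averaging half-window
DEFAULT_FRACTIONS = (0.20, 0.31, 0.167)   # acetyl, H1, BRD4|acetyl


class TrackError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GenomicTrack
# ---------------------------------------------------------------------------

@dataclass
class GenomicTrack:
    """bedGraph-semantics coverage track: sorted, non-overlapping, 0-based
    half-open intervals with finite non-negative values."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.ends <= self.starts):
            raise TrackError("intervals must have end > start")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise TrackError("intervals must be sorted and non-overlapping")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise TrackError("values must be finite and >= 0")

    def value_at(self, positions) -> np.ndarray:
        """Signal at bp positions (0 outside covered intervals)."""
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < self.ends[np.clip(idx, 0, None)])
        out = np.zeros(len(pos))
        out[ok] = self.values[idx[ok]]
        return out

    def mean_over(self, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end)."""
        s = np.maximum(self.starts, start)
        e = np.minimum(self.ends, end)
        w = np.maximum(e - s, 0)
        total = w.sum()
        span = end - start
        base = float((self.values * w).sum())
        return base / span if span > 0 else 0.0

    def rasterize(self, start: int, end: int, step: int = 1) -> np.ndarray:
        return self.value_at(np.arange(start, end, step))

    def covers(self, start: int, end: int) -> bool:
        if len(self.starts) == 0:
            return False
        return self.starts[0] <= start and self.ends[-1] >= end

    def scaled(self, factor: float) -> "GenomicTrack":
        return GenomicTrack(self.chrom, self.starts.copy(), self.ends.copy(),
                            self.values * factor)

    # -- I/O ----------------------------------------------------------------

    def to_bedgraph(self, path):
        df = pd.DataFrame({"chrom": self.chrom, "start": self.starts,
                           "end": self.ends, "value": self.values})
        df.to_csv(path, sep="\t", header=False, index=False,
                  float_format="%.6g")

    @classmethod
    def from_bedgraph(cls, path, chrom: Optional[str] = None
                      ) -> "GenomicTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(("track", "browser", "#")) or \
                        not line.strip():
                    continue
                t = line.split()
                rows.append((t[0], int(t[1]), int(t[2]), float(t[3])))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        if chrom is None:
            chrom = df["chrom"].iloc[0]
        df = df[df["chrom"] == chrom].sort_values("start")
        return cls(chrom, df["start"].values, df["end"].values,
                   df["value"].values)

    @classmethod
    def from_bigwig(cls, path, chrom: str, start: int, end: int
                    ) -> "GenomicTrack":
        import pyBigWig
        bw = pyBigWig.open(path)
        ivals = bw.intervals(chrom, start, end) or []
        bw.close()
        return cls(chrom, np.array([i[0] for i in ivals]),
                   np.array([i[1] for i in ivals]),
                   np.array([i[2] for i in ivals]))

    @classmethod
    def from_arrays(cls, chrom, positions, values, step: int = 1
                    ) -> "GenomicTrack":
        positions = np.asarray(positions, dtype=np.int64)
        return cls(chrom, positions, positions + step,
                   np.asarray(values, dtype=float))


def read_bed(path) -> list:
    """BED intervals as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            t = line.split()
            out.append((t[0], int(t[1]), int(t[2]),
                        t[3] if len(t) > 3 else f"feature_{len(out)}"))
    return out


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def call_nucleosome_positions(track: GenomicTrack,
                              locus: Tuple[int, int],
                              min_spacing: int = FOOTPRINT_BP
                              ) -> np.ndarray:
    """Greedy descending-score dyad calling with an exclusion zone.

    Candidates are taken at the track's base-pair resolution within the
    locus; the highest remaining score wins until nothing positive is left.
    Scale-invariant: multiplying the track by a positive constant changes
    no calls.
    """
    start, end = locus
    if not track.covers(start, end):
        if len(track.starts) == 0 or track.mean_over(start, end) == 0:
            warnings.warn("track is empty over the locus; no dyads called")
            return np.array([], dtype=np.int64)
    sig = track.rasterize(start, end)
    if np.all(sig <= 0):
        warnings.warn("uniform zero signal; no dyads called")
        return np.array([], dtype=np.int64)
    order = np.lexsort((np.arange(len(sig)), -sig))
    taken = np.zeros(len(sig), dtype=bool)
    dyads = []
    for p in order:
        if sig[p] <= 0:
            break
        if taken[p]:
            continue
        dyads.append(p + start)
        lo = max(0, p - min_spacing + 1)
        taken[lo:p + min_spacing] = True
    return np.sort(np.asarray(dyads, dtype=np.int64))


# ---------------------------------------------------------------------------
# state assignment
# ---------------------------------------------------------------------------

@dataclass
class StateAssignment:
    """Per-nucleosome epigenetic flags plus the Bernoulli probabilities and
    seed that produced them (reproducible)."""

    acetylated: np.ndarray
    h1: np.ndarray
    brd4: np.ndarray
    p_acetyl: np.ndarray
    p_h1: np.ndarray
    p_brd4: np.ndarray
    seed: int

    def __post_init__(self):
        if np.any(self.brd4 & ~self.acetylated):
            raise TrackError("brd4 implies acetylated")

    def to_tsv(self, path, dyads=None):
        df = pd.DataFrame({
            "dyad": dyads if dyads is not None
            else np.arange(len(self.acetylated)),
            "acetylated": self.acetylated.astype(int),
            "h1": self.h1.astype(int), "brd4": self.brd4.astype(int),
            "p_acetyl": self.p_acetyl, "p_h1": self.p_h1,
            "p_brd4": self.p_brd4})
        df.to_csv(path, sep="\t", index=False)


def _probabilities(signal: np.ndarray, target: float) -> np.ndarray:
    """p_i proportional to signal, rescaled to the target mean, capped at 1
    (one further rescale of the uncapped mass keeps the expectation on
    target when feasible)."""
    s = np.asarray(signal, dtype=float)
    if target <= 0:
        return np.zeros(len(s))
    if len(s) == 0:
        return s.copy()
    if s.sum() <= 0:
        raise TrackError(
            "all-zero signal cannot realize a positive target fraction")
    p = s * (target * len(s) / s.sum())
    for _ in range(50):
        over = p > 1.0
        if not over.any():
            break
        deficit = np.sum(p[over] - 1.0)
        p[over] = 1.0
        under = ~over & (p > 0)
        if not under.any() or p[under].sum() == 0:
            break
        p[under] *= 1.0 + deficit / p[under].sum()
    return np.clip(p, 0.0, 1.0)


def assign_states(dyads: np.ndarray, ac_track: GenomicTrack,
                  h1_track: GenomicTrack, brd4_track: GenomicTrack,
                  target_fractions: Sequence[float] = DEFAULT_FRACTIONS,
                  seed: int = 0) -> StateAssignment:
    """Stochastic single-cell realization of nucleosome states.

    Signal at a dyad is the mean over the nucleosome footprint
    (dyad +- 73 bp); acetylation and H1 are independent Bernoulli draws,
    BRD4 is drawn only among acetylated nucleosomes at the conditional
    target fraction.
    """
    dyads = np.asarray(dyads, dtype=np.int64)
    f_ac, f_h1, f_brd4 = target_fractions

    def at_dyads(track):
        return np.array([track.mean_over(d - DYAD_WINDOW_BP,
                                         d + DYAD_WINDOW_BP + 1)
                         for d in dyads])

    rng = np.random.default_rng(seed)
    p_ac = _probabilities(at_dyads(ac_track), f_ac)
    p_h1 = _probabilities(at_dyads(h1_track), f_h1)
    ac = rng.random(len(dyads)) < p_ac
    h1 = rng.random(len(dyads)) < p_h1
    brd4 = np.zeros(len(dyads), dtype=bool)
    p_b = np.zeros(len(dyads))
    brd4_sig = at_dyads(brd4_track)
    if ac.any() and f_brd4 > 0:
        if brd4_sig[ac].sum() <= 0:
            if brd4_sig.sum() > 0:
                raise TrackError("BRD4 signal absent on all acetylated "
                                 "nucleosomes; target infeasible")
            # zero BRD4 signal everywhere -> zero flags, by construction
        else:
            p_b[ac] = _probabilities(brd4_sig[ac], f_brd4)
            brd4[ac] = rng.random(ac.sum()) < p_b[ac]
    return StateAssignment(ac, h1, brd4, p_ac, p_h1, p_b, seed)


def fiber_from_tracks(label: str, locus: Tuple[int, int],
                      positions_track: GenomicTrack,
                      ac_track: GenomicTrack, h1_track: GenomicTrack,
                      brd4_track: GenomicTrack,
                      target_fractions=DEFAULT_FRACTIONS,
                      min_spacing: int = FOOTPRINT_BP, seed: int = 0
                      ) -> Tuple[FiberSpec, np.ndarray, StateAssignment]:
    """Full pipeline: peak calling + state assignment -> FiberSpec."""
    start, end = locus
    dyads = call_nucleosome_positions(positions_track, locus, min_spacing)
    dyads = dyads[(dyads - start >= WRAP_BP / 2)
                  & (end - dyads >= WRAP_BP / 2)]
    states = assign_states(dyads, ac_track, h1_track, brd4_track,
                           target_fractions, seed)
    records = [NucleosomeRecord(float(d - start),
                                acetylated=bool(states.acetylated[i]),
                                brd4=bool(states.brd4[i]),
                                h1=bool(states.h1[i]))
               for i, d in enumerate(dyads)]
    return (FiberSpec.from_dyads(label, end - start, records), dyads, states)


# ---------------------------------------------------------------------------
# synthetic tracks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrackParams:
    """Statistical structure of the emulated experimental tracks."""

    nrl_bp: float = 195.0             # positioning-peak spacing
    peak_sd_bp: float = 20.0          # positioning peak width
    position_jitter_bp: float = 10.0
    block_scale_bp: float = 12500.0   # alternating acetylation interval
    block_jitter: float = 0.10        # relative sd of block lengths
    ac_peak_spacing_bp: float = 1500.0
    ac_peak_sd_bp: float = 300.0
    h1_smooth_bp: float = 2000.0      # H1 broadness
    h1_anticorrelation: float = 1.0   # 0 = none, 1 = full
    brd4_fraction_of_ac_peaks: float = 0.35
    brd4_peak_sd_bp: float = 150.0
    step_bp: int = 25                 # raster step of the output tracks


def synth_tracks(locus_length: int,
                 params: Optional[SyntheticTrackParams] = None,
                 seed: int = 0, chrom: str = "chrS"):
    """Generate (positions, H3K27ac, H1, BRD4) tracks over [0, length).

    Acetylation alternates between active and inactive blocks of
    ~block_scale_bp; BRD4 peaks sit inside acetylation peaks; H1 is broad
    and anti-correlated with acetylation.
    """
    p = params or SyntheticTrackParams()
    rng = np.random.default_rng(seed)
    step = p.step_bp
    grid = np.arange(0, locus_length, step)

    # nucleosome positioning: sharp peaks every ~NRL with jitter
    pos_sig = np.zeros(len(grid))
    centers = []
    x = p.nrl_bp / 2
    while x < locus_length - p.nrl_bp / 4:
        c = x + rng.normal(0, p.position_jitter_bp)
        centers.append(c)
        x += p.nrl_bp
    for c in centers:
        amp = 1.0 + 0.5 * rng.random()
        pos_sig += amp * np.exp(-0.5 * ((grid - c) / p.peak_sd_bp) ** 2)

    # alternating activity blocks
    edges = [0.0]
    active_first = bool(rng.integers(0, 2))
    while edges[-1] < locus_length:
        L = max(p.block_scale_bp * 0.3,
                rng.normal(p.block_scale_bp,
                           p.block_jitter * p.block_scale_bp))
        edges.append(edges[-1] + L)
    active = np.zeros(len(grid), dtype=bool)
    for k in range(len(edges) - 1):
        if (k % 2 == 0) == active_first:
            active |= (grid >= edges[k]) & (grid < edges[k + 1])

    # acetylation: peaky signal inside active blocks + low background
    ac_sig = np.full(len(grid), 0.02)
    ac_peaks = []
    for k in range(len(edges) - 1):
        if not ((k % 2 == 0) == active_first):
            continue
        lo, hi = edges[k], min(edges[k + 1], locus_length)
        c = lo + p.ac_peak_spacing_bp / 2
        while c < hi:
            amp = 0.6 + rng.random()
            ac_peaks.append((c, amp))
            ac_sig += amp * np.exp(-0.5 * ((grid - c) / p.ac_peak_sd_bp) ** 2)
            c += p.ac_peak_spacing_bp * (0.8 + 0.4 * rng.random())

    # H1: broad baseline minus smoothed acetylation
    from scipy.ndimage import gaussian_filter1d
    smooth = gaussian_filter1d(ac_sig, p.h1_smooth_bp / step, mode="nearest")
    noise = gaussian_filter1d(rng.normal(size=len(grid)),
                              p.h1_smooth_bp / step / 2, mode="nearest")
    noise_sd = noise.std() if noise.std() > 0 else 1.0
    base = 1.0 + 0.1 * noise / noise_sd
    h1_sig = np.clip(
        base - p.h1_anticorrelation * smooth / max(smooth.max(), 1e-9), 0.02,
        None)

    # BRD4: narrow peaks nested inside a subset of acetylation peaks
    brd4_sig = np.zeros(len(grid))
    for (c, amp) in ac_peaks:
        if rng.random() < p.brd4_fraction_of_ac_peaks:
            brd4_sig += amp * np.exp(
                -0.5 * ((grid - c) / p.brd4_peak_sd_bp) ** 2)

    def mk(v):
        return GenomicTrack.from_arrays(chrom, grid, v, step=step)

    return mk(pos_sig), mk(ac_sig), mk(h1_sig), mk(brd4_sig)


def measure_block_scale(track: GenomicTrack,
                        smooth_bp: float = 2000.0) -> float:
    """Characteristic alternation scale of an activity track: the signal is
    smoothed over ~2 kb, thresholded at its mean, and the mean run length of
    the resulting active/inactive segments is returned (equal to the block
    scale for an ideal alternating-block signal)."""
    from scipy.ndimage import gaussian_filter1d
    step = int(track.ends[0] - track.starts[0])
    sig = gaussian_filter1d(track.values, smooth_bp / step, mode="nearest")
    active = sig > sig.mean()
    runs = []
    count = 1
    for a, b in zip(active, active[1:]):
        if a == b:
            count += 1
        else:
            runs.append(count)
            count = 1
    runs.append(count)
    # drop boundary-truncated runs when possible
    interior = runs[1:-1] if len(runs) > 2 else runs
    return float(np.mean(interior)) * step


POU5F1_LOCUS = ("chr17", 35_484_600, 35_534_600)


def load_regulatory_elements():
    """Packaged E1/E2/P1/P2 intervals of the Pou5f1 locus (mm10)."""
    from importlib.resources import files
    path = files("chromodyn").joinpath("data/pou5f1_elements.bed")
    return read_bed(str(path))


def map_elements_to_nucleosomes(elements, dyads, locus_start: int = 0):
    """Element name -> indices of nucleosomes whose dyad falls inside the
    element interval (nearest dyad when none does)."""
    dyads = np.asarray(dyads) + locus_start
    out = {}
    for chrom, start, end, name in elements:
        hit = np.flatnonzero((dyads >= start) & (dyads < end))
        if len(hit) == 0:
            hit = np.array([int(np.argmin(np.abs(dyads - (start + end) / 2)))])
        out[name] = hit
    return out
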