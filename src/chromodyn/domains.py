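"""Per-frame spatial chromatin domains and local fiber organization.

Domains are communities of the frame's contact graph (nucleosomes are
nodes; unweighted edges join pairs whose minimum bead distance is below the
contact cutoff), found by minimizing the two-level map equation.  The
search runs igraph's Infomap over several seeded trials plus a greedy
merge refinement under the in-package map-equation scorer; the partition
with the lowest description length wins.

Clutches are maximal runs of consecutive nucleosomes whose sliding-window
radius of gyration stays strictly below the trajectory average; stacking is
a face-to-face contact (center distance < 7.5 nm, axis angle < 30 deg).
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .analysis import CONTACT_CUTOFF, nucleosome_centers

STACK_DISTANCE = 75.0     # Å (7.5 nm)
STACK_ANGLE = 30.0        # degrees


# ---------------------------------------------------------------------------
# map equation
# ---------------------------------------------------------------------------

def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def map_equation(edges: np.ndarray, n_nodes: int,
                 labels: Sequence[int]) -> float:
    """Two-level map equation L(M) in bits for an undirected unweighted
    graph (isolated nodes contribute nothing to the flow)."""
    labels = np.asarray(labels)
    deg = np.zeros(n_nodes)
    for (i, j) in edges:
        deg[i] += 1
        deg[j] += 1
    two_m = deg.sum()
    if two_m == 0:
        return 0.0
    p = deg / two_m
    mods = np.unique(labels)
    q = np.zeros(len(mods))
    pm = np.zeros(len(mods))
    mindex = {m: k for k, m in enumerate(mods)}
    for k, m in enumerate(mods):
        pm[k] = p[labels == m].sum()
    for (i, j) in edges:
        if labels[i] != labels[j]:
            q[mindex[labels[i]]] += 1.0 / two_m
            q[mindex[labels[j]]] += 1.0 / two_m
    q_tot = q.sum()
    term1 = _plogp(np.array([q_tot])).sum()
    term2 = -2.0 * _plogp(q).sum()
    term3 = -_plogp(p).sum()
    term4 = _plogp(q + pm).sum()
    return float(term1 + term2 + term3 + term4)


def exhaustive_best_partition(edges: np.ndarray, n_nodes: int):
    """Globally optimal map-equation partition by enumerating all set
    partitions (Bell-number growth: practical to ~12 nodes); the
    independent oracle for tests."""
    if n_nodes > 13:
        raise ValueError("exhaustive search limited to 13 nodes")
    # pure-python scorer: enumeration calls it Bell(n) times
    edge_list = [(int(i), int(j)) for i, j in edges]
    deg = [0.0] * n_nodes
    for i, j in edge_list:
        deg[i] += 1.0
        deg[j] += 1.0
    two_m = sum(deg)
    if two_m == 0:
        return np.arange(n_nodes), 0.0
    log2 = math.log2
    term3 = -sum(d / two_m * log2(d / two_m) for d in deg if d > 0)

    def score(labels):
        pm = {}
        q = {}
        for v in range(n_nodes):
            pm[labels[v]] = pm.get(labels[v], 0.0) + deg[v] / two_m
            q.setdefault(labels[v], 0.0)
        for i, j in edge_list:
            li, lj = labels[i], labels[j]
            if li != lj:
                q[li] += 1.0 / two_m
                q[lj] += 1.0 / two_m
        q_tot = sum(q.values())
        out = q_tot * log2(q_tot) if q_tot > 0 else 0.0
        out += term3
        for m in pm:
            if q[m] > 0:
                out -= 2.0 * q[m] * log2(q[m])
            s = q[m] + pm[m]
            if s > 0:
                out += s * log2(s)
        return out

    best, best_l = None, math.inf

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first = collection[0]
        for smaller in partitions(collection[1:]):
            for k, subset in enumerate(smaller):
                yield smaller[:k] + [[first] + subset] + smaller[k + 1:]
            yield [[first]] + smaller

    for part in partitions(list(range(n_nodes))):
        labels = [0] * n_nodes
        for m, group in enumerate(part):
            for v in group:
                labels[v] = m
        l = score(labels)
        if l < best_l - 1e-12:
            best_l, best = l, np.asarray(labels, dtype=np.int64)
    return best, best_l


def _greedy_merge(edges: np.ndarray, n_nodes: int, labels: np.ndarray):
    """Merge pairs of connected modules while the map equation improves."""
    labels = labels.copy()
    adj_mods = set()
    current = map_equation(edges, n_nodes, labels)
    improved = True
    while improved:
        improved = False
        adj_mods = {(min(labels[i], labels[j]), max(labels[i], labels[j]))
                    for (i, j) in edges if labels[i] != labels[j]}
        best_gain, best_pair = 0.0, None
        for (a, b) in adj_mods:
            trial = labels.copy()
            trial[trial == b] = a
            l = map_equation(edges, n_nodes, trial)
            if current - l > best_gain + 1e-12:
                best_gain, best_pair = current - l, (a, b)
        if best_pair is not None:
            a, b = best_pair
            labels[labels == b] = a
            current -= best_gain
            improved = True
    return labels, current


# ---------------------------------------------------------------------------
# domain detection
# ---------------------------------------------------------------------------

@dataclass
class DomainPartition:
    frame_index: int
    labels: np.ndarray            # per-nucleosome domain id (0..k-1)
    map_equation_bits: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return len(np.unique(self.labels))

    def members(self, domain: int) -> np.ndarray:
        return np.flatnonzero(self.labels == domain)

    def domain_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    def domain_rg_nm(self, centers: np.ndarray) -> np.ndarray:
        out = []
        for d in range(self.n_domains):
            x = centers[self.members(d)]
            out.append(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1)
                               .mean()) / 10.0)
        return np.asarray(out)


def contact_graph(frame: np.ndarray, nuc_id: np.ndarray,
                  cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Unweighted edges between nucleosomes whose minimum bead distance is
    below the cutoff."""
    sel = np.flatnonzero(nuc_id >= 0)
    tree = cKDTree(frame[sel])
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    ni = nuc_id[sel][pairs[:, 0]]
    nj = nuc_id[sel][pairs[:, 1]]
    mask = ni != nj
    e = np.stack([np.minimum(ni[mask], nj[mask]),
                  np.maximum(ni[mask], nj[mask])], axis=1)
    return np.unique(e, axis=0).astype(np.int64)


def infomap_domains(frame: np.ndarray, nuc_id: np.ndarray,
                    cutoff: float = CONTACT_CUTOFF, seed: int = 0,
                    trials: int = 10, frame_index: int = 0,
                    edges: Optional[np.ndarray] = None) -> DomainPartition:
    """Two-level map-equation community detection on the frame's contact
    graph; isolated nucleosomes become singleton domains."""
    n_nuc = int(np.max(nuc_id)) + 1
    if n_nuc < 2:
        raise ValueError("need at least 2 nucleosomes")
    if edges is None:
        edges = contact_graph(frame, nuc_id, cutoff)
    if len(edges) == 0:
        labels = np.arange(n_nuc)
        return DomainPartition(frame_index, labels, 0.0,
                               {"cutoff": cutoff, "note": "empty graph"})
    import igraph
    igraph.set_random_number_generator(random.Random(seed))
    g = igraph.Graph(n=n_nuc, edges=[tuple(e) for e in edges])
    best_labels, best_l = None, math.inf
    for t in range(max(1, trials)):
        comm = g.community_infomap(trials=1)
        labels = np.asarray(comm.membership, dtype=np.int64)
        l = map_equation(edges, n_nuc, labels)
        if l < best_l:
            best_l, best_labels = l, labels
    refined, l_ref = _greedy_merge(edges, n_nuc, best_labels)
    if l_ref < best_l:
        best_labels, best_l = refined, l_ref
    # canonical ids: relabel by first occurrence
    _, labels = np.unique(best_labels, return_inverse=True)
    order = {}
    canon = np.empty_like(labels)
    nxt = 0
    for i, l in enumerate(labels):
        if l not in order:
            order[l] = nxt
            nxt += 1
        canon[i] = order[l]
    return DomainPartition(frame_index, canon, best_l,
                           {"cutoff": cutoff, "seed": seed,
                            "trials": trials})


# ---------------------------------------------------------------------------
# domain tracking
# ---------------------------------------------------------------------------

@dataclass
class DomainEvent:
    kind: str                 # split | merge | birth | death
    frame_index: int
    parents: tuple
    children: tuple


def track_domains(partitions: Sequence[DomainPartition],
                  min_overlap: float = 0.3) -> list:
    """Match domains across consecutive frames by maximal Jaccard overlap
    and emit split/merge/birth/death events."""
    events = []
    for prev, cur in zip(partitions, partitions[1:]):
        if len(prev.labels) != len(cur.labels):
            raise ValueError("partitions must share the node set")
        prev_sets = {d: set(prev.members(d)) for d in range(prev.n_domains)}
        cur_sets = {d: set(cur.members(d)) for d in range(cur.n_domains)}
        # map each current domain to matching parents and vice versa
        child_parents = {c: [] for c in cur_sets}
        parent_children = {p: [] for p in prev_sets}
        for c, cs in cur_sets.items():
            for p, ps in prev_sets.items():
                j = len(cs & ps) / len(cs | ps)
                if j >= min_overlap:
                    child_parents[c].append(p)
                    parent_children[p].append(c)
        for p, children in parent_children.items():
            if len(children) > 1:
                events.append(DomainEvent("split", cur.frame_index, (p,),
                                          tuple(sorted(children))))
            elif len(children) == 0 and len(prev_sets[p]) > 1:
                events.append(DomainEvent("death", cur.frame_index, (p,),
                                          ()))
        for c, parents in child_parents.items():
            if len(parents) > 1:
                events.append(DomainEvent("merge", cur.frame_index,
                                          tuple(sorted(parents)), (c,)))
            elif len(parents) == 0 and len(cur_sets[c]) > 1:
                events.append(DomainEvent("birth", cur.frame_index, (),
                                          (c,)))
    return events


# ---------------------------------------------------------------------------
# clutches
# ---------------------------------------------------------------------------

@dataclass
class ClutchSegment:
    frame_index: int
    start: int                # first nucleosome (inclusive)
    end: int                  # last nucleosome (inclusive)
    window_rg: np.ndarray     # nm, windows fully inside the segment

    @property
    def n_nucleosomes(self) -> int:
        return self.end - self.start + 1


def window_rg(centers: np.ndarray, window: int = 4) -> np.ndarray:
    """Sliding-window R_g (nm) over consecutive nucleosome centers; value w
    covers nucleosomes [w, w + window - 1]."""
    n = len(centers)
    if n < window:
        raise ValueError("fiber shorter than the window")
    out = np.empty(n - window + 1)
    for w in range(n - window + 1):
        x = centers[w:w + window]
        out[w] = math.sqrt(float(((x - x.mean(axis=0)) ** 2).sum(axis=1)
                                 .mean())) / 10.0
    return out


def clutch_threshold(frames: np.ndarray, nuc_id: np.ndarray,
                     nucs: np.ndarray, window: int = 4) -> float:
    """Trajectory-average sliding-window R_g (nm), the clutch threshold."""
    vals = []
    n_nuc = int(np.max(nuc_id)) + 1
    for f in np.atleast_3d(frames.reshape(-1, frames.shape[-2],
                                          3)):
        c = nucleosome_centers(f, nuc_id, n_nuc)[nucs]
        vals.append(window_rg(c, window))
    return float(np.mean(vals))


def clutch_detect(centers: np.ndarray, threshold: float, window: int = 4,
                  frame_index: int = 0) -> list:
    """Maximal runs of windows with R_g strictly below the threshold; each
    clutch spans all nucleosomes covered by its below-threshold windows."""
    rg = window_rg(centers, window)
    below = rg < threshold
    clutches = []
    w = 0
    while w < len(below):
        if below[w]:
            start = w
            while w < len(below) and below[w]:
                w += 1
            clutches.append(ClutchSegment(
                frame_index, start, (w - 1) + window - 1,
                rg[start:w].copy()))
        else:
            w += 1
    return clutches


def clutch_intervals(clutches: list, n_nucleosomes: int) -> list:
    """Complement segments (gaps between clutches), tiling the fiber."""
    out = []
    prev_end = -1
    for c in clutches:
        if c.start > prev_end + 1:
            out.append((prev_end + 1, c.start - 1))
        prev_end = max(prev_end, c.end)
    if prev_end < n_nucleosomes - 1:
        out.append((prev_end + 1, n_nucleosomes - 1))
    return out


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def nucleosome_axis(frame: np.ndarray, histone_beads: np.ndarray
                    ) -> np.ndarray:
    """Superhelix axis from the eight histone beads: the unit vector between
    the centroids of the two half-octamers (the beads below and above the
    disk midplane, i.e. the first and last four along the superhelix).

    This geometric estimator is robust where a principal-component fit is
    not: the histone ring's axial span is comparable to its radius, so the
    covariance eigenvalues are nearly degenerate."""
    x = frame[histone_beads]
    half = len(x) // 2
    v = x[half:].mean(axis=0) - x[:half].mean(axis=0)
    return v / np.linalg.norm(v)


def stacking_classify(frame: np.ndarray, system, i: int, j: int,
                      distance_cutoff: float = STACK_DISTANCE,
                      angle_cutoff_deg: float = STACK_ANGLE,
                      contact_cutoff: float = CONTACT_CUTOFF) -> str:
    """Classify a nucleosome pair as 'stacked', 'contact-unstacked' or
    'no-contact'.  Axes are undirected (angle folded to [0, 90] deg)."""
    bi = system.nucleosome_beads(i)
    bj = system.nucleosome_beads(j)
    ci = frame[bi].mean(axis=0)
    cj = frame[bj].mean(axis=0)
    dist = float(np.linalg.norm(ci - cj))
    ai = nucleosome_axis(frame, system.nucleosome_histone_beads(i))
    aj = nucleosome_axis(frame, system.nucleosome_histone_beads(j))
    cosang = abs(float(ai @ aj))
    angle = math.degrees(math.acos(min(1.0, cosang)))
    if dist < distance_cutoff and angle < angle_cutoff_deg:
        return "stacked"
    dmin = np.min(np.linalg.norm(frame[bi][:, None, :] - frame[bj][None],
                                 axis=2))
    if dmin < contact_cutoff:
        return "contact-unstacked"
    return "no-contact"


def nearest_neighbor_stacking_stats(frame: np.ndarray, system,
                                    contact_cutoff: float = CONTACT_CUTOFF,
                                    long_range_sep: int = 10) -> dict:
    """For every nucleosome, classify its minimum-center-distance contact
    partner; report the stacked fraction and the long-range share among
    stacked pairs (genomic separation >= long_range_sep nucleosomes)."""
    n = system.n_nucleosomes
    centers = nucleosome_centers(frame, system.nuc_id, n)
    tree = cKDTree(centers)
    d, idx = tree.query(centers, k=2)
    results = []
    for i in range(n):
        j = int(idx[i, 1])
        cls = stacking_classify(frame, system, i, j,
                                contact_cutoff=contact_cutoff)
        if cls == "no-contact":
            continue
        results.append((i, j, cls))
    stacked = [(i, j) for (i, j, c) in results if c == "stacked"]
    frac = len(stacked) / len(results) if results else 0.0
    if stacked:
        lr = np.mean([
            abs(i - j) >= long_range_sep
            or system.nuc_fiber[i] != system.nuc_fiber[j]
            for (i, j) in stacked])
    else:
        lr = 0.0
    return {"stacked_fraction": frac, "long_range_share": float(lr),
            "n_pairs": len(results)}


# ---------------------------------------------------------------------------
# same-domain frequency
# ---------------------------------------------------------------------------

def same_domain_frequency(partitions: Sequence[DomainPartition],
                          acetylated: np.ndarray,
                          nucs: Optional[np.ndarray] = None,
                          max_sep: Optional[int] = None) -> dict:
    """Fraction of frames in which nucleosome pairs share a domain, binned
    by genomic separation (in nucleosomes), split by pair class."""
    acetylated = np.asarray(acetylated, dtype=bool)
    nucs = np.arange(len(acetylated)) if nucs is None else np.asarray(nucs)
    n = len(nucs)
    max_sep = max_sep or n - 1
    classes = {"can-can": [], "can-ac": [], "ac-ac": []}
    sums = {k: np.zeros(max_sep + 1) for k in classes}
    cnts = {k: np.zeros(max_sep + 1) for k in classes}
    label_mat = np.stack([p.labels for p in partitions])
    for a in range(n):
        for b in range(a + 1, min(n, a + max_sep + 1)):
            sep = b - a
            same = np.mean(label_mat[:, nucs[a]] == label_mat[:, nucs[b]])
            ai, bi = acetylated[nucs[a]], acetylated[nucs[b]]
            key = "ac-ac" if (ai and bi) else (
                "can-can" if (not ai and not bi) else "can-ac")
            sums[key][sep] += same
            cnts[key][sep] += 1
    out = {}
    for k in classes:
        with np.errstate(invalid="ignore"):
            out[k] = np.where(cnts[k] > 0, sums[k] / np.maximum(cnts[k], 1),
                              np.nan)
    return out
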