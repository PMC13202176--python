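# Methods

## The model

chromodyn implements a nucleosome-resolution coarse-grained chromatin model
in which every particle is a 35 Å bead: one bead per DNA helical turn
(10.5 bp), one bead per core histone protein (8 per nucleosome), and two
beads per linker histone H1 (globular domain + C-terminal tail).  A
canonical nucleosome is 14 DNA beads on a left-handed superhelix of radius
40 Å and pitch 25 Å plus 8 histone beads on a coaxial superhelix of radius
18 Å; with H1 bound it is a 24-bead chromatosome, the H1 beads sitting on
the dyad axis at 70 Å and 105 Å from the center.

The paper-level geometric constants (radii, pitch, bead size, H1 placement,
charges, the 38 Å bond rule, the printed Lennard-Jones strengths) are fixed;
everything that is a genuine gap is listed below with the convention chosen.

### Geometry conventions (chosen, not given)

- **Angular step of the superhelix.**  Only the radius and pitch are given;
  the angular step between consecutive DNA beads follows from the fixed
  35 Å contour spacing: dtheta = 35 / sqrt(R² + (P/2π)²) ≈ 0.8707 rad.
  Fourteen beads then span ~1.80 superhelical turns.  The chord between
  consecutive nucleosomal DNA beads is 33.9 Å (the 35 Å is arc length);
  consecutive linker DNA beads are placed at exactly 35 Å.
- **Histone placement.**  The 8 histone beads are evenly spaced over the
  same angular span as the DNA, phase-aligned to the dyad.  Any even
  spacing satisfies the stated geometry; this one makes the half-octamer
  centroids clean markers for the superhelix axis.
- **H1 tail bead** sits one bead diameter beyond the globular bead on the
  dyad axis (105 Å from center).
- **Straight-fiber layout.**  For regular arrays each nucleosome is rotated
  so its entry-to-exit chord continues the +x chain direction; mild initial
  strain is removed by the soft-core relaxation stage.
- **Random growth.**  Multi-fiber systems grow unit-by-unit (linker beads
  within a persistence cone, nucleosomes as rigid bodies at uniformly
  random orientation) along a self-avoiding backbone, rejecting candidates
  closer than 0.5 sigma to any placed bead and backtracking a few units
  when stuck.  Growth is deterministic for a given seed, which is what
  makes exported simulation inputs bit-reproducible.

## Interactions

Twenty bead types collapse onto five interaction classes: linker DNA,
canonical nucleosome, acetylated nucleosome, BRD4-associated acetylated
nucleosome, and linker histone.

- **Bonded.**  Harmonic bonds E = k (r − r0)² with k = 10 kcal/mol/Å²
  between every bead pair closer than 38 Å in the reference nucleosome
  geometry and between consecutive linker beads (r0 = 35 Å).  The core is
  then effectively rigid (thermal bond fluctuation ≈ 0.17 Å).  DNA bending
  angles E = K(θ − π)² act on every chain triplet that involves a linker
  bead; K = 4.2 kcal/mol/rad² targets a persistence length of ~50 nm at
  physiological salt via the discrete worm-like-chain relation
  l_p = 2 b K / kBT (the screened electrostatic stiffening at 150 mM adds
  only a few Å on top).
- **Nucleosome breathing.**  The entry and exit DNA beads are special: each
  of their sub-38 Å reference pairs to non-adjacent core beads (three per
  terminus in this geometry) is a Morse bond
  E = D(1 − exp(−a(r − r0)))² instead of a harmonic one, so the termini
  detach and re-attach stochastically.  D = 2.0 kcal/mol and a = 0.8 1/Å
  were calibrated so a canonical dinucleosome (63-bp linker, 300 K, 150 mM)
  shows a spontaneous-unwrapping equilibrium constant K_eq ≈ 0.10;
  acetylation multiplies D by 0.87, raising K_eq roughly three-fold
  (≈ 0.32).  A terminus counts as unwrapped when **all** of its Morse bonds
  are stretched past r0 + 2/a.
- **Nonbonded.**  12-6 Lennard-Jones with σ = 35 Å for all pairs,
  energy-shifted at 3σ; strengths by class pair: ε0 = 0.115 (canonical-
  canonical), ε_ac = 0.06 (acetyl-acetyl), ε_h = sqrt(ε0 ε_ac) ≈ 0.083
  (canonical-acetyl, geometric-mean mixing), ε_B = 0.23 for a
  BRD4-associated nucleosome with any acetylated partner (bridging;
  canonical partners are never enhanced), ε_H1 = 0.8 between H1 beads and
  linker DNA, and a weak 0.06 excluded-volume strength for everything
  else.  ε_B and ε_H1 are not printed anywhere; the defaults were
  calibrated in-package (ε_B: BRD4 association restores condensation of
  acetylated fibers in the reduced slab analog; ε_H1: H1 measurably
  compacts a 12-mer fiber).  Charged beads (linker DNA −7.35e, each H1
  bead +5e) additionally interact through a Debye-Hückel potential with
  ε_r = 78, energy-shifted at 5 Debye lengths (≈ 39 Å at 150 mM).
  Directly bonded (1-2) pairs are excluded from nonbonded interactions;
  1-3 pairs are not.

## Dynamics

BAOAB-splitting Langevin dynamics at 300 K with unit mass per bead; this
splitting keeps configurational averages accurate at large timesteps.
Units are Å / kcal/mol / unit mass, timestep dt = 0.05 internal units by
default (the stiffest bond oscillates with period ≈ 28 dt).  The Langevin
damping time is 140 ns on the mapped physical-time axis with 1.4 ns of
physical time per timestep — i.e. 100 timesteps — the mapping itself being
pure metadata calibrated against nucleosome-diffusion observations; it
never enters the forces.  Nonbonded forces use a Verlet pair list (skin
0.3σ) rebuilt on a half-skin displacement criterion, built by an O(n²)
scan below 2000 beads and by cell binning above.  Boundaries: a purely
repulsive (WCA) spherical wall for nucleus-like systems, or a fully
periodic elongated box for slab phase-separation runs.  Initial structures
are de-clashed by a near-zero-temperature run with a force-capped purely
repulsive soft-core potential.

Determinism: one seeded random stream per run; the engine is
single-threaded, so results are trivially independent of thread count, and
identical seeds give bit-identical trajectories.

## Umbrella sampling and the stacking PMF

The free-energy difference between stacked and unbound nucleosome pairs is
measured with harmonic umbrella windows on the center-center distance of
two free mononucleosomes, reconstructed by self-consistent WHAM (tolerance
1e-6) with the radial Jacobian removed (W = −kT ln P + 2 kT ln r), zeroed
on the large-distance plateau.

An unconditioned distance PMF for this system is nearly flat (< 1 kBT)
even though the stacked energy minimum is ≈ 7 kBT deep: the orientational
entropy of two free disks overwhelms the short-ranged face-to-face
attraction.  The quantity of interest is therefore the PMF *in the stacked
configuration*, implemented as an exactly conditional PMF: a
window-independent restraint keeps the two superhelix axes parallel and
aligned with the separation vector (k = 5 kcal/mol, ≈ 15° rms, inside the
30° cone of the stacking definition below).  Because that bias is the same
in every window, WHAM over the distance umbrella alone gives the exact PMF
of the conditioned ensemble.  The azimuthal spin of each nucleosome stays
free — it is not part of the stacking definition — so windows in the
contact region (< 100 Å) are sampled longer (300k steps vs 80k) to let the
bead-bead registry equilibrate.  With the printed ε0 = 0.115 this yields a
canonical well depth of 4.8 ± 0.9 kBT (three seeds) and an acetylated
depth of 1.5-2.1 kBT — emergent numbers, not fitted.  The depth is
protocol-sensitive at the ±1.5 kBT level: conditioning the azimuthal
registry as well (a fully rigid stacked pose) deepens the canonical well
to ≈ 6.3 kBT.

## Genomic-track mapping

Nucleosome dyads are called greedily from a positioning-score track
(highest score first, 147-bp exclusion zone), which is scale-invariant by
construction.  Epigenetic states are Bernoulli draws per nucleosome with
probability proportional to the mean ChIP-style signal over the dyad ± 73
bp footprint, rescaled (and capped at 1, with the excess redistributed) so
the expected fractions hit the locus-average targets: 20% acetylated, 31%
H1-bound, 16.7% of acetylated nucleosomes BRD4-bound.  BRD4 is drawn only
among acetylated nucleosomes.  Background fibers use flat-signal
assignment at the same fractions.  All genomic arithmetic is 0-based
half-open.

### What the synthetic tracks emulate — and what they do not

`synth_tracks` generates four coupled tracks over a locus: sharp
positioning peaks every ~195 bp (the called NRL), acetylation organized in
alternating active/inactive blocks of ~12.5 kb with peaky structure inside
active blocks, a broad H1 signal anti-correlated with acetylation, and
BRD4 peaks nested inside a subset of acetylation peaks.  These reproduce
the *statistical* structure that drives the model (state fractions, block
alternation scale, H1/acetylation anticorrelation, BRD4 nesting) so the
entire pipeline is testable offline.  They do not reproduce real-locus
specifics: actual peak positions and amplitudes, enhancer/promoter
architecture, replication-timing or CTCF context, mappability artifacts,
or cell-to-cell epigenetic heterogeneity.  Tests passing on synthetic
tracks therefore validate the machinery and the model's response to the
encoded statistics, not locus-specific biology.

## Trajectory analysis conventions

- **Contacts:** two nucleosomes are in contact when the minimum distance
  between any of their beads is below 1.5σ = 52.5 Å; the cutoff is logged
  in every contact matrix.  Normalization: observed/expected by genomic
  separation, then Pearson correlation; compartments are the sign of PC1
  of the correlation map, sign-fixed to correlate positively with
  acetylation (log signal over mean signal).
- **Compartmentalization coefficient:**
  (ΣAA + ΣBB − 2ΣAB)/(ΣAA + ΣBB + 2ΣAB) over the off-diagonal
  observed/expected map with A/B from the PC1 sign.
- **Insulation:** log2 of the diamond-window mean (10 nucleosomes by
  default) over its genome-wide mean.
- **MSD:** log-spaced lags, power-law fit before the confinement plateau
  (detected where the local log-log slope falls below half its initial
  value); time axis in mapped ns.
- **Persistence length:** exponential fit of the tangent correlation over
  its first decay decade; a rigid rod reports infinity.
- **Sedimentation:** Kirkwood bead hydrodynamics with bead radius σ/2,
  partial specific volume 0.65 mL/g, water at 20 °C.
- **Spatial domains:** per-frame community detection on the unweighted
  contact graph by two-level map-equation minimization (igraph's Infomap
  over 10 seeded trials plus a greedy merge refinement under the
  in-package scorer; the lowest description length wins).  Domain lineages
  are matched across frames by Jaccard overlap (≥ 0.3) to emit
  split/merge/birth/death events.
- **Clutches:** maximal runs of 4-nucleosome sliding windows whose R_g is
  strictly below the trajectory-average window R_g (the average over the
  whole trajectory, not per frame — "remains below average").
- **Stacking:** center distance < 7.5 nm and axis angle < 30°, axes
  undirected (folded to [0°, 90°]) and estimated as the unit vector
  between the two half-octamer centroids — a principal-component fit is
  degenerate here because the histone ring's axial span is comparable to
  its radius.
- **Slab coexistence:** nucleosome-center density profile along the long
  axis; frames are re-centered on their densest bin before averaging, and
  a Poisson-noise pre-test on the uncentered profile reports a single
  uniform phase when no contrast beyond counting noise exists.

## Reduced problem sizes

Everything in the test suite and acceptance script is desk-scale by
design: dinucleosome breathing uses 2-10 million timesteps (hundreds of
wrap/unwrap transitions across four termini), the stacking PMF 28 windows
of 80-300k steps, and the slab analog five 6-nucleosome fibers in a
45 × 45 × 280 nm box for 200k steps.  For the slab analog the damping time
is raised ten-fold: coexistence densities are equilibrium observables and
therefore damping-independent (an invariant the suite also checks), while
transport — the rate-limiting step for the acetylated control to dissolve —
speeds up proportionally.  Full-locus (50-120 kb, seconds-of-physical-time)
runs are meant to be executed from the exported LAMMPS inputs on a cluster
and analyzed with the same `analysis`/`domains` functions.

## Known limitations

- No DNA torsional elasticity or sequence-dependent flexibility (by
  design); consequently no 10-bp periodicity in NRL-dependent compaction.
- No cohesin/loop extrusion, no explicit histone tails, no cell-to-cell
  epigenetic heterogeneity.
- The Morse constants, ε_B, ε_H1 and the bonded stiffnesses are
  calibrated, not literature constants; recalibration helpers live in
  `chromodyn.calibration`.
- The stacking PMF depends on the stacked-pose conditioning protocol at
  the ±1.5 kBT level (documented above).
- The internal engine is single-core and intended for ≤ ~5 × 10^4 beads;
  larger systems should go through the LAMMPS export.
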