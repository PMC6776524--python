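# Methods

This note documents the models, conventions and numerical choices behind
`piezomd`, what the synthetic generators do and do not emulate, and the
known limitations.  Units are Å for lengths, ns for times, degrees for
angles, mmHg for pressures unless stated otherwise.

## Trajectory core

Trajectories are dense arrays of frames (Å) with per-frame orthorhombic
box lengths and strictly increasing time stamps.  Only orthorhombic boxes
are supported — the simulation systems this package targets use
rectangular cells (190.1 × 190.1 × 177.5 Å³ scale) — and triclinic input
raises an explicit error rather than being silently mishandled.

- **File formats.** Multi-model PDB is read and written by a small
  in-package fixed-column reader/writer so that molecule boundaries (TER
  records and chain changes), duplicate atom serials (re-indexed 0..N−1
  with a warning) and malformed records (error naming the line) are
  handled exactly.  DCD/XTC/TRR go through MDAnalysis coordinate readers
  and writers.  Binary formats store engine-dependent time units, so frame
  times default to `index × 1.2 ns`, the trajectory output interval the
  analyses assume; it is configurable per load.
- **Selections.** A small grammar (`resid a-b`, `name`, `element`,
  `resname`, `chain`, `index`, `backbone`, `heavy`, boolean operators)
  evaluated against the topology.  `backbone` means atoms named N, CA, C,
  O; this is a convention, overridable by an explicit `name …` selection.
- **Re-imaging** translates each molecule by integer box multiples so its
  centroid falls within half a box length of the anchor selection's
  centroid per axis (the "make the protein contiguous" step before any
  geometric analysis).  Whole-molecule shifts only, so intra-molecule
  geometry is exactly preserved.
- **Superposition** is the standard least-squares (Kabsch/SVD) rotation
  with a determinant check forbidding reflections; selections of fewer
  than 3 non-collinear atoms are rejected.  RMSD series superpose each
  frame on the same selection they measure.  The reference structure
  defaults to frame 0 and is configurable; an experimental model could be
  loaded as an extra frame and used instead.

## Membrane curvature

The dome pipeline works per frame and per leaflet:

1. **Leaflet assignment**: a lipid is "upper" iff its head atom group sits
   above its designated tail atom in z.  This is valid as long as the dome
   never folds past vertical, which holds for the channel dome and for
   everything the generator produces.
2. **Gridding**: mass-weighted headgroup centers of mass are tiled into
   their eight adjacent x–y periodic images (9× the points), a regular
   grid of spacing 4.6 Å (about twice the phosphate radius) is laid out
   covering all original points plus one spacing of padding per edge, and
   heights are piecewise-linearly interpolated from the tiled scatter
   (`scipy.interpolate.griddata`).  Tiled points farther than three grid
   spacings from the grid are dropped before triangulation purely to save
   time; they cannot influence the interpolant.
3. **Smoothing** (optional, on by default): a uniform local-mean kernel of
   size `ceil(sqrt(nx·ny)/4)` grid cells (13 for a 52 × 50 grid) with
   wrap-mode edge handling.
4. **Dome fit**: least squares of
   `z(x,y) = z0 + zh·exp(−((x−rx)² + (y−ry)²)/σ²)`, initialized
   deterministically (z0 = grid median; zh = extremum − median using the
   extremum of larger magnitude; (rx, ry) at that extremum; σ = a quarter
   of the smaller grid extent, bounded in (1 Å, grid diagonal)).
5. **Radius**: `d = −2 zh/σ²` (the peak second derivative) and
   `R = (1+d²)^{3/2}/d`, implemented exactly in this printed form.  The
   `(1+d²)^{3/2}` factor is dimensionally odd when d carries units of 1/Å,
   and the textbook peak curvature of this surface is simply `1/|d|`; in
   the dome regime (|d| ≈ 0.01 1/Å) the two differ by under 0.03%, far
   below every tolerance used here, so the formula is kept as printed
   rather than "corrected".  zh = 0 returns an infinite sentinel (flat
   membrane).

**Why recovery runs disable the smoothing kernel.**  Convolving the
surface with a ~13-cell (≈ 60 Å) box kernel is a visual-smoothing device:
it widens the apparent dome and shallows it, which biases the fitted
(zh, σ) and hence R by far more than the interpolation error (a box of
width w adds roughly w²/12 of variance per axis to the Gaussian's σ²/2).
Time-series plots benefit from it; quantitative parameter recovery does
not.  `curvature_timeseries(..., smooth_grid=False)` is therefore the
validated configuration, and all recovery tests and the acceptance script
use it.  The per-frame time series can additionally be LOESS-smoothed over
time (default span 4.7% of the series, the convention for these plots),
which is independent of the spatial kernel.

Degenerate inputs: a per-frame fit failure yields a missing value in the
series rather than aborting; upper- and lower-leaflet pipelines never mix.

## Ligand mobility

RMSF per window is `sqrt(mean over window frames and ligand heavy atoms of
the squared deviation from the window-mean atomic positions)`, computed on
a trajectory already superposed on the protein.  Windows are
non-overlapping, default 20 frames (24 ns at the 1.2 ns output interval,
matching the accumulation cadence used for these systems); a trailing
partial window is dropped.  Hydrogens are excluded; using all heavy atoms
rather than the COM means internal tumbling of an otherwise tethered
ligand still registers.  Stability ranking averages RMSF over a
configurable tail interval (default: the last half of the windows) so that
an early diffusive phase does not penalize a ligand that settles; exact
ties are broken by label order and flagged.

Contacts: a residue is in contact in a frame when any ligand heavy atom is
within 4.0 Å (configurable; no published criterion exists for this
system) of any residue heavy atom; residues with contact fraction ≥ 0.5
over the analysis interval form the reported site.  Entry classification
uses the membrane slab [mean lower-headgroup z, mean upper-headgroup z]
per frame; the first crossing of the ligand COM into the slab fixes the
entry side.

## Dynamical networks

Node displacements are Cα positions minus their time mean; the correlation
is the scalar dot-product convention
`C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)` (not a 3×3 tensor), matching
the established network-analysis tools for protein trajectories.  Edges
exist only between residues in persistent contact (any heavy-atom pair
within 4.5 Å in ≥ 75% of frames — the documented convention of those
tools) with |C| > 0; a |C| = 0 pair gets no edge rather than a capped
weight.  Each edge carries two weights: the affinity |C| and the distance
−log|C|.  Girvan–Newman removes, at each step, the edge of highest
betweenness under weighted shortest paths (distance weight); exact
betweenness ties are broken by the lexicographically smallest node pair,
making the removal history reproducible.  Among all partitions along the
removal sequence (including the initial connected components) the one
maximizing modularity is returned; modularity uses the affinity weight,
the only dimensionally sensible choice (with −log|C| a perfectly coupled
edge would carry zero weight and vanish from Q).  A zero-variance node
keeps a unit diagonal and zero off-diagonal correlations.

## Arm PCA and tilt/twist

PCA eigendecomposes the 3N×3N covariance of the selected Cα coordinates
over an interval, after least-squares superposition of every interval
frame on the interval's first frame (configurable off).  Eigenvalues are
population variances (Å²); variance fractions are λ_k/Σλ.  Each
eigenvector is oriented so that its projection increases over the
interval — a sign convention that makes "the direction of motion under
stretch" positive.  Projections are dot products of (frame − mean) with
the eigenvectors, in Å of total Cα displacement; the mean structure
projects to zero.

Tilt and twist are defined through the spherical angles of the arm axis —
the vector from the proximal to the distal Cα centroid — relative to the
membrane normal (z): tilt is the change of the polar angle versus a
reference frame, twist the change of the (unwrapped) azimuth.  This is the
simplest convention consistent with an outward tilt of the distal arm and
a twist of the distal end; it is a package convention, documented rather
than inherited, and both angles are zero at the reference frame by
construction.

## Pore ions

Occupancy counts, per sampled frame (default stride 20 frames = 24 ns),
the ions of each species with any atom within 5.0 Å of any region atom,
using minimum-image distances in the orthorhombic box
(`scipy.spatial.cKDTree` with `boxsize`).  The region is an arbitrary
selection; for a pore vestibule it would be the backbone atoms of the
pore-lining residue range.  The selectivity summary is the ratio of
time-averaged counts with an infinite sentinel when the minority species
is never observed; the acceptance script instead reports a
Haldane–Anscombe (+0.5) corrected ratio so the exclusion limit stays
finite and comparable across seeds.

## Functional assays

ΔF/F₀ = (max post-stimulus F − F at t = 0)/F at t = 0, with the maximum
searched only after the stimulus time (agonist added mid-recording;
default 10 s).  The Boltzmann fit uses the signed-slope parameterization
`I = I_max/(1+exp((P50−P)/k))` so suction protocols (negative pressures,
negative k) need no sign gymnastics; initialization is deterministic from
the 50%-of-scale crossing of the linearly interpolated data.  The
Mann–Whitney U test enumerates all assignments of the pooled midranks for
combined n ≤ 12 (exact, ties included, two-tailed by |U − n₁n₂/2|) and
otherwise uses the normal approximation with the standard tie correction
and a 0.5 continuity correction.  ROI segmentation of image stacks is out
of scope; traces enter as arrays/CSV.

## Synthetic generators

Every generator emits its ground truth beside the data, and every
recovery test consumes only the data.  All generators are
seed-deterministic (NumPy `default_rng`).

- **Dome membrane**: two leaflets of 2-atom (head/tail) pseudo-lipids on a
  jittered lattice, heads on the analytic dome surface ± half the bilayer
  thickness (38 Å) plus Gaussian noise (default sd 1 Å), default depth
  −30 Å and width 70 Å so the analytic radius (≈ 8.2 nm) sits in the dome
  regime of the channel; optional linear depth ramp emulates flattening
  under tension.  Full lipid chemistry is irrelevant to the implemented
  math and is deliberately absent.
- **Ligand ensembles**: bound ligands follow a discrete first-order
  mean-reverting process (memory 0.9/frame) with stationary sd 0.5 Å about
  pocket sites flanked by three pocket residues at ~3 Å; free ligands
  random-walk in the membrane slab with 3 Å steps; one scripted entry
  event crosses the slab boundary at a configurable frame and side.
  Defaults (2 bound, 18 free, 400 frames) mirror a 20-ligand sampling
  ensemble at a ~5 mM box concentration.
- **Communities**: residues of a community share a per-frame latent 3-D
  displacement (amplitude 3 Å) plus independent noise (0.5 Å); an optional
  global component correlates everything.  The emitted contact mask
  connects residues within a community (full mutual contact by default —
  a compact helical bundle — configurable down to chain neighbors) plus
  explicit bridges.  Frame-independent latents make the planted
  correlation structure exact.
- **Arms**: rigid rods of ≥ 5 pseudo-atoms rotated about a hinge per
  explicit or linear tilt/twist schedules (defaults 80°/65°/68° maxima,
  the asymmetric-arm regime), plus isotropic noise; the schedule itself is
  the analytic angle ground truth.
- **Ion box**: rejection sampling with acceptance 1 near a charge site and
  e^−β away for cations (reciprocal for anions), giving an e^β density
  enhancement within 5 Å of the sites (default β = 2, three clustered
  sites mimicking a glutamate triad).
- **Assays**: a saturating-exponential fluorescence rise after the
  stimulus (exact baseline before it), a Boltzmann pressure–response table
  (P50 = −45 mmHg, k = −8 mmHg), and two normal samples with a prescribed
  location shift.

What the generators do **not** emulate: force fields, water, real lipid
chemistry, protein internal dynamics beyond the planted structure,
correlated noise, and finite-sampling artifacts of real microsecond
trajectories.  Passing recovery tests therefore demonstrates that the
analysis code computes what it claims on data with known structure at the
right numerical scales — not that those structures are what a real
trajectory would show.

## Problem sizes and tolerances

The test suite and acceptance script use desk-scale problems chosen to
exercise the same numerical regimes as the full systems: dome recovery
over 200 random (zh ∈ [−60,−10] Å, σ ∈ [40,120] Å) geometries in a
4σ-wide box (lipid lattice 4 Å noiseless, 8 Å at 1 Å noise; fitted R
within 0.5% and 10% respectively); 100-seed ligand ensembles (20 ligands,
400 frames); 50-seed three-community systems (30 residues, 300 frames);
1000-draw closed-form and rank-sum calibrations.  The exact closed-form
property is checked against symbolic evaluation; contacts, occupancy,
superposition and exact rank-sum p-values are checked against brute-force
O(N²)/enumeration oracles.

## Limitations

- Triclinic boxes and velocity/force data are unsupported.
- The PDB reader covers the ATOM/HETATM/TER/MODEL/CRYST1 subset it writes,
  not the full format zoo (altlocs, insertion codes, SEGID conventions).
- Girvan–Newman is O(E²·N) and intended for residue-level graphs up to a
  few thousand edges, not atom-level networks.
- The dome fit assumes a single radial indentation; multi-dome or strongly
  anisotropic surfaces need a different surface model.
- `curvature_timeseries` assigns leaflets at frame 0; lipid flip-flop over
  a series would require per-frame reassignment.
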