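# piezomd

Trajectory analysis for molecular-dynamics simulations of Piezo1-style
mechanosensitive channels, plus the functional-assay statistics used to
validate simulation predictions at the bench.

Piezo1 is a trimeric cation channel whose three curved "arms" bend the
surrounding bilayer into an inverted dome; membrane tension flattens the
dome and drives arm motions that open the pore, and the small-molecule
agonist Yoda1 modulates this coupling from a pocket between Piezo repeats.
Analyzing such simulations requires a specific set of computations that
`piezomd` implements as a tested, reusable library:

- **trajectory core** — PDB/DCD/XTC reading and writing, an atom-selection
  language, molecule-wise periodic re-imaging to an anchor, least-squares
  (Kabsch) superposition, and RMSD series;
- **membrane curvature** — leaflet assignment, headgroup-COM gridding with
  periodic tiling and optional local-mean smoothing, a radial Gaussian dome
  fit `z(x,y) = z₀ + z_h·exp(−((x−r_x)² + (y−r_y)²)/σ²)`, and the peak
  curvature radius `d = −2 z_h/σ²`, `R = (1+d²)^{3/2}/d`;
- **ligand mobility** — windowed RMSF per ligand, stability ranking to find
  spontaneous binders, per-residue contact fractions, and classification of
  the membrane leaflet of entry;
- **dynamical networks** — Pearson correlations of Cα motion on a
  persistent-contact mask, Girvan–Newman community detection maximizing
  weighted modularity, and inter-community contact summaries;
- **arm PCA** — eigenmodes of the Cα coordinate covariance with variance
  fractions, per-frame mode projections, and per-arm tilt/twist angles;
- **pore ions** — minimum-image ion occupancy counts near a region
  selection and cation/anion selectivity summaries;
- **functional assays** — calcium-imaging ΔF/F₀, Boltzmann
  pressure–response fits `I/I_max = 1/(1+exp((P₅₀−P)/k))`, and two-tailed
  Mann–Whitney U tests (exact for small samples);
- **synthetic data** — generators for every input class above with known
  ground truth (analytic dome radius, planted communities, scripted tilt
  schedules, …), so each stage is verifiable without multi-microsecond
  trajectories.

## Worked example

`examples/02_membrane_curvature.py` builds a bilayer of 2450 two-atom
pseudo-lipids on a Gaussian dome (depth −30 Å, width 70 Å, 1 Å headgroup
noise) whose depth ramps toward −10 Å over six frames, and runs the whole
curvature pipeline:

```
bilayer: 2450 lipids, analytic R at frame 0 = 81.7 Å (8.17 nm)
 time_ns leaflet    R_A  R_nm  residual_A
    0.00   upper  83.75  8.38        0.70
    1.20   upper  93.74  9.37        0.68
    2.40   upper 109.96 11.00        0.70
    3.60   upper 142.68 14.27        0.70
    4.80   upper 186.52 18.65        0.71
    6.00   upper 254.43 25.44        0.72
    0.00   lower  82.75  8.28        0.68
    ...
```

The fitted radius at frame 0 (≈ 8.3–8.4 nm) recovers the analytic 8.17 nm
of the generated dome — the curvature regime of the channel's inverted
dome — and grows monotonically as the dome flattens, exactly as a membrane
under increasing tension behaves.  The other examples
(`examples/01…07_*.py`) each demonstrate one capability the same way:
build a small synthetic input, run the analysis, print what it recovers.

## Layout

```
src/piezomd/     core, curvature, ligands, network, pca, ions, assays,
                 synthetic (+ pdbio, selections)
examples/        one narrative script per capability
tests/           unit, property and end-to-end recovery tests
docs/methods.md  models, conventions, parameter choices, limitations
```
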