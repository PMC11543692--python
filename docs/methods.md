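# Methods

## Fibril representation and conventions

A fibril model is an ordered stack of layers, one protein chain per layer
(the lysozyme fibril has a single protofilament, so layer = chain; models
with several protofilaments would need a chain→protofilament map, which this
package does not implement). The fibril axis is the global z axis, the frame
in which helical fibril models are deposited; `align_axis_to_z` is available
as a pre-step for models in other frames. Layers are indexed by ascending
mean Cα z with lexicographic chain-id tie-break, so indexing is deterministic
for any input order. Coordinates are Å throughout; the separation statistics
report nm (the natural unit of the 0.7 nm loosening threshold). Residue
numbering is 1-based mature-lysozyme numbering (1–130); file numbering is
taken as-is. Alternate conformers are reduced to the highest-occupancy copy
on reading.

## Helical symmetry

Symmetry expansion places layer k at R_z(k·Δφ)·x₀ + k·Δz·ẑ — the same
operation as the pdbsymm-style multiplication used to build deposited fibril
stacks. Estimation inverts this: each adjacent layer pair is superposed by
least squares (Kabsch, SVD with determinant correction) on Cα atoms matched
by residue number, the signed rotation angle about +z (right-handed positive,
so a left-handed fibril has negative twist) is read from the rotation matrix
as atan2(R₁₀−R₀₁, R₀₀+R₁₁), and the rise is the z component of the
translation — exact whenever the true rotation axis is z, regardless of axis
offset in xy. Per-pair values are averaged. If the rotation axis tilts more
than 5° from z the estimator warns rather than fails: at small twist
amplitudes coordinate noise makes the axis direction ill-conditioned even
when the angle and rise remain accurate (the parameter-recovery test shows
±0.05° / ±0.05 Å under 0.1 Å noise despite such warnings). Cα-only fitting
is deliberate: it is robust to side-chain differences and matches the
Cα-based z-extent convention.

The crossover distance is Δz·180°/|Δφ| — the half period of the helix as
seen in projection; it is undefined at zero twist and independent of
handedness. Fibril width is the maximal heavy-atom pairwise distance in xy
projection (convex-hull accelerated) plus twice a 1.5 Å margin approximating
a carbon van der Waals envelope; a model-based width is only a consistency
companion to micrograph-measured widths, not a replacement.

## Interactions

All interaction criteria are geometric distance rules, chosen because the
reference observations report counts and identities, not energies:

| quantity | rule | default |
|---|---|---|
| disulfide | Cys Sγ–Sγ distance | ≤ 2.5 Å |
| layer contact | any heavy-atom pair between layers | ≤ 4.5 Å (scanned 4.0–5.0) |
| ion pair | Asp/Glu carboxylate O vs Lys Nζ / Arg guanidinium N / His imidazole N | ≤ 4.0 Å |
| hydrophobic cluster | side-chain heavy-atom adjacency over {A,V,L,I,M,F,W,P} | ≤ 5.0 Å, ≥ 3 residues |

His counts as positively charged because the buried Asp67–His78 pair is part
of the fibril's interaction inventory. The hydrophobic set is the
conventional hydropathy-positive set plus Pro, excluding Gly; it is
configurable. Contact counting uses a k-d tree but is tested for exact
agreement with O(N²) enumeration; `contact_count_vs_cutoff` reports the
layer-contact census across cutoffs because an interface-area criterion
(PISA-style) and a distance criterion need not agree at a single cutoff.

Burial classification uses an in-package Shrake–Rupley SASA (Fibonacci
sphere, 960 points, probe 1.4 Å, Bondi radii), cross-checked in the tests
against an independent implementation. Relative exposure divides the
residue's SASA — computed for the mid-layer copy with all atoms within 12 Å
as occluders — by the Tien et al. (2013) theoretical Gly-X-Gly maximum;
relative SASA < 0.15 is buried. Note that a fully isolated residue can
exceed 1.0 by this normalization, since it lacks even the Gly neighbors of
the reference state.

## Cavities

Cavity detection voxelizes the stack (default 0.5 Å spacing), blocks voxels
within r_vdW + probe of any heavy atom (probe 1.4 Å — a water molecule, so
reported cavities are at least water-sized), flood-fills the exterior with
6-connectivity, and clusters the remaining free voxels with 26-connectivity
(asymmetric connectivity is conservative: the exterior cannot leak through
diagonal gaps, while cavities are not artificially fragmented). Clusters
under 20 Å³ (~1.7 water volumes) are discarded as grid noise.

Two choices deal with the fact that a fibril is an open-ended helical object
rather than a globule:

1. **Central slab.** Analysis is restricted to a slab of thickness 3× rise
   centered on the stack midpoint, so cavity cross-sections are evaluated in
   a fully packed environment rather than at frayed stack ends.
2. **Lateral-only exterior.** The flood fill seeds only from the four x/y
   faces of the box. The z faces of the slab are periodic fibril boundaries,
   not solvent: a channel that runs along the fibril axis (the kind of
   continuous density feature that can thread a hydrophobic cavity) must
   register as a cavity, not as exterior.

Polarity of a cavity is decided by its lining (heavy atoms within 4.5 Å of a
cavity voxel): hydrophobic if more than half of the lining side-chain atoms
are carbon/sulfur belonging to hydrophobic residues. Axial continuity
requires a z span of at least two rises with no gap over twice the grid
spacing. Cavity volumes converge under grid refinement (<15% change on
halving the spacing, tested against the analytic volume of a hollow shell);
counts and polarity labels are nevertheless sensitive to probe and slab
choices, so the defaults are centralized and every run logs them.

## Aggregation consensus

The consensus score counts, per residue, how many of five predictors call the
residue aggregation-prone. Thresholds are strict inequalities ("above 0.1"
excludes 0.1 exactly): TANGO β-aggregation > 0.1; WALTZ > 75 on its 0–100
scale; FoldAmyloid > 0.062 sustained over at least five consecutive residues
(residues in shorter runs never count); PASTA 2.0 < −2.8 energy units;
Aggrescan has no published fixed cutoff, so its hot-spot threshold travels in
the track-file header and can be overridden in config. The predictors
themselves are external web servers; they enter as two-column per-residue
track files. `scale_window_score` (a centered sliding-window average of a
propensity scale, Kyte–Doolittle by default) provides a simple stand-in track
generator — it is a windowed scale score, not a reimplementation of any
predictor. The consensus integer is written into the B-factor column for
structure coloring and survives a file round trip exactly.

## Layer separation (trajectory statistic)

For a layer pair (i, j) the distance between equivalent residues — by
default their Cα atoms, since the statistic is defined over "equivalent
amino acids" without naming atoms; side-chain centroid and minimum heavy-atom
variants are selectable — is computed per frame in raw coordinates. No
trajectory fitting is applied: an inter-chain distance is a relative
quantity, and pre-fitting would only matter for whole-system rigid motion,
which cancels anyway. The per-residue maximum is taken over frames at t ≥
50 ns (burn-in, excluding the equilibration transient), per replica; the
replica mean and SEM = sd/√n over the six replicas are reported. Taking the
maximum per replica and then averaging (rather than pooling all frames) is
the reading consistent with quoting an SEM across runs; the pooled variant is
available via `pooled=True`. Residues whose mean maximum exceeds 0.7 nm are
flagged as loosened and merged into maximal contiguous regions; the default
layer pair is the penultimate/top pair of the stack (the fibril tip, where
dissociation initiates). `compare_variants` differences two profiles (e.g.
patient G87 vs the reverted D87 wild-type model) and reports residues where
exactly one variant crosses the threshold.

The wild-type homology model is built by `mutate_residue`: backbone N/Cα/C/O
are kept bit-for-bit (so backbone dihedrals are untouched) and the new side
chain comes from the CCD ideal-geometry template rigidly superposed on the
local N/Cα/C frame — a single idealized rotamer with no clash relief, since
relaxation is the job of the downstream MD engine, not the model builder.

## Synthetic data generator

The generator produces the study conditions at toy scale, with ground truth
recorded for every output:

- **Layer**: a planar β-arch — two straight strands joined by a semicircular
  arc (default radius 8 Å), Cα at exactly 3.8 Å spacing on the strands,
  z = 0, centered on the helical axis — with minimal backbone atoms (N, C, O
  placed along the local tangent, carbonyl O and alternating Cβ out of
  plane). Default sequence: the 130-residue patient (G87) lysozyme sequence.
- **Stack**: the layer expanded with twist −1.4°, rise 4.8 Å (the refined
  values; 6 layers by default, the MD system size; 9 for model-building
  scenarios), plus optional i.i.d. Gaussian coordinate noise.
- **Trajectory**: 201 frames at 1 ns emulating a 200 ns production run;
  i.i.d. Gaussian jitter of 0.03 nm per coordinate (a stable cross-β core
  fluctuates a few tenths of an Å; this keeps the intact-fibril maximum
  statistic near 0.55–0.65 nm, below the 0.7 nm threshold, which is the
  physically intended regime); optional detachment displaces a chosen residue
  range of a chosen layer along +x with a linear ramp from an onset time to
  the final frame. Six replicas derive their seeds from one root seed.
- **Tracks**: per-predictor background noise clamped to the no-hit side of
  each threshold, with planted ranges driven safely past it.

What the generator does *not* emulate: real side-chain packing, solvent,
correlated dynamics, partial/noisy detachment, or predictor-specific score
distributions. Passing the recovery tests therefore demonstrates that the
estimators and statistics are correct as algorithms — exact inverse of the
symmetry operation, exact region recovery when the planted amplitude clears
the threshold — not that they are robust to every pathology of real
trajectories or predictor output.

## Numerical choices and problem sizes

Kabsch uses SVD with the determinant-sign correction; zero-rise/zero-twist
stacks are legal inputs to the estimator (it returns 0, 0). Width falls back
from the convex hull to all-pairs distances for degenerate (collinear) point
sets. The run-length mask uses a single linear scan. Ties in layer ordering
break lexicographically. The test and acceptance workloads use 9-layer
stacks of the 130-residue sequence for geometry, ~12–40-residue stacks for
oracle-equivalence checks, and six 201-frame replicas for the separation
statistic — sizes at which every brute-force oracle is exact and the whole
suite runs in well under a minute.

## Known limitations

- Single-protofilament geometry only; no map (MRC) handling, no refinement
  or validation metrics, no interface energies (distance criteria only), no
  hydrogen-bond enumeration with angular terms.
- The model-based width is an envelope approximation and is not expected to
  match micrograph widths exactly.
- Cavity counts depend on probe/slab/spacing; treat them with the logged
  parameters, and use `detect_cavities(..., return_grid=True)` to audit the
  voxel partition.
- Binary trajectory formats are not read directly; trajectories enter as
  multi-model PDB (converters from XTC/DCD exist in mdtraj/MDAnalysis).
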