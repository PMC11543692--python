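# fibrilkit

Structural analysis of cross-β amyloid fibril models — built around the
ex vivo fibril of the D87G variant of human lysozyme, the protein behind
hereditary systemic ALys amyloidosis, but applicable to any single-protofilament
helical stack.

Amyloid fibrils are helical polymers: each protein molecule occupies one
*layer*, and layer *k* + 1 is layer *k* rotated by a twist Δφ about the fibril
axis and translated by a rise Δz along it. `fibrilkit` implements the
computations a structural study of such a fibril performs on the atomic model:

- **Helical geometry** — symmetry expansion of one layer into an *n*-layer
  stack (x<sub>k</sub> = R<sub>z</sub>(kΔφ)·x₀ + kΔz·ẑ), the inverse problem
  (estimating Δφ, Δz from a stack by Kabsch superposition of adjacent layers),
  the crossover distance Δz·180°/|Δφ|, fibril width, and per-chain z extent.
- **Interactions** — disulfide bridges (Sγ–Sγ distance), the number of layers
  in contact with a given layer, buried ion pairs (including Asp–His), and
  connected clusters of hydrophobic side chains.
- **Cavities** — grid/flood-fill detection of internal cavities in the stack
  cross-section, their volumes, polarity of the lining residues, and
  continuity along the fibril axis.
- **Aggregation consensus** — the 0–5 per-residue consensus of five
  aggregation predictors (TANGO > 0.1, WALTZ > 75, FoldAmyloid > 0.062 over
  ≥ 5 consecutive residues, Aggrescan, PASTA 2.0 < −2.8 PEU), ingested as
  per-residue score tracks, plus mapping of the consensus onto the structure's
  B-factor column.
- **Layer separation** — the MD statistic for local loosening: per-residue
  distances between equivalent residues of two adjacent layers over a
  trajectory, the per-replica maximum after a 50 ns burn-in, mean ± SEM
  across replicas, and contiguous regions exceeding the 0.7 nm loosening
  threshold; plus the backbone-preserving point mutation (e.g. G87 → D87)
  used to build the hypothetical wild-type fibril.
- **Synthetic data** — β-arch layers, helical stacks, trajectories with
  programmed detachment, and predictor tracks with planted hits, all with
  known ground truth, so every stage is testable without downloads.

## Worked example

Generate a nine-layer synthetic stack at the refined helical parameters of the
lysozyme fibril and recover its geometry:

```sh
$ fibril synth fibril --out stack.pdb --layers 9 --twist -1.4 --rise 4.8
$ fibril geometry --in stack.pdb --report geometry.json
{
  "twist_deg": -1.3999977244605684,
  "rise_A": 4.799999999999998,
  "crossover": 617.1438602394204,
  "width": 240.42922239058947,
  "z_extent_per_chain": 0.0,
  "handedness": "left"
}
```

The estimator recovers the generating twist and rise to PDB coordinate
precision (it is exact to 1e-6 in memory). The crossover of 617 Å predicted
from −1.4°/4.8 Å falls inside the 584 ± 58 Å range measured on micrographs of
the real fibril. The width and z extent describe the *synthetic* layer — a
planar β-arch hairpin whose Cα atoms all sit at z = 0 (hence z extent 0),
unlike the real fibril protein, which meanders laterally (width ~106 Å) and
climbs 19 Å along the axis.

The same operations are available as a library:

```python
from fibrilkit import GeneratorSpec, make_fibril, estimate_params

model = make_fibril(GeneratorSpec(n_layers=9, twist=-1.4, rise=4.8))
params = estimate_params(model)   # HelicalParams(twist=-1.4, rise=4.8)
```

Other subcommands: `fibril contacts`, `fibril cavities`, `fibril aggscore`,
`fibril layersep`, `fibril synth`, and `fibril all` for the end-to-end report
(geometry.json, disulfides.csv, contacts.csv, ion_pairs.csv, clusters.csv,
cavities.csv, consensus.csv, separation.csv, summary.json).

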