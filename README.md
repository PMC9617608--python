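# spinemesh

Cytoskeleton network morphometrics for electron tomograms of dendritic
spines.

Dendritic spines — the submicron protrusions that receive most excitatory
synapses — are shaped by a dense mesh of actin filaments and associated
proteins. Electron tomography resolves that mesh at nanometre scale, but
turning a 3D grayscale volume into quantitative structure requires a
chain of image analysis and graph computation. `spinemesh` implements
that chain:

1. **Segmentation** — mask the cytosol, denoise with a Gaussian filter
   (σ = 2 nm), and binarize with a local threshold `T = m − k·s` over a
   20 nm window, which adapts to the luminance drift along the beam axis.
2. **Skeletonization** — reduce the binarized filaments to a one-voxel
   skeleton by distance-transform-ordered, topology-preserving thinning
   (simple-point deletion under the (26, 6) connectivity pair, branch
   ends and volume-boundary anchors protected), then prune sub-4 nm
   stubs.
3. **Graph model** — junction voxels cluster into nodes (centre of
   mass), degree-2 chains become branches with smoothed polylines
   (sliding weights (1,2,3,2,1)/9), arc length and tortuosity
   `t = L_arc / L_span` per branch.
4. **Statistics** — node ranks and densities, branch lengths,
   membrane-relative orientations via the distance-transform gradient,
   spatially resolved profiles, rank-3 branching-angle triples with a
   standardized coordinate frame, elementary loops (shortest weighted
   cycle through each branch) with best-fit-plane PCA, and
   inverse-length minimum-spanning-tree pruning with rank-2 merging.
5. **Null models** — the references these statistics are judged against:
   the sin(α) orientation law (mean 57.3°), sorted pairwise angles of
   random 3-way branching (53.6°/95.3°/121.1°, SDs 24.4°/27.1°/30.9°),
   the rigid-rod orientation constraint near a flat membrane, the Euler
   buckling force `F = π²κ/L²`, and the isosceles-triangle reading of
   tortuosity (`θ = arccos(1/t)`).
6. **Synthetic phantoms** — spine-shaped masks with a known filament
   network, rendered into tomogram-like volumes (8 nm tubes, PSF blur,
   z-drift, noise), so every stage is testable and end-to-end parameter
   recovery can be asserted.

The package is a library first (see `examples/`), with a thin
`spinemesh` CLI (`simulate`, `segment`, `skeletonize`, `analyze`,
`nulls`, `report`) for shell use.

## Worked example

`examples/01_phantom_to_graph.py` builds a spine phantom with a known
network, images it, and runs the full pipeline:

```text
cytosol volume:          0.0016 um^3
junction nodes:          truth 150, recovered 140
mean branch length:      truth 16.2 nm, recovered 16.9 nm
junction density:        8.71e+04 per um^3
cytoskeleton volume:     22.2% of cytosol
neck width estimate:     62.1 nm
```

The recovered graph tracks the ground truth (junction count within 7%,
mean branch length within 5% here), and the derived quantities —
junction density near 10⁵ μm⁻³, cytoskeleton occupying ~20% of the
cytosol — sit in the range reported for real spines. The other examples
print the null-model reference numbers, the elementary-loop/pore-size
analysis, the spanning-tree pruning summary, and membrane-relative
orientation profiles.

Library use in three lines:

```python
from spinemesh import AnalysisConfig, read_volume, read_mask, run_pipeline
bundle = run_pipeline(AnalysisConfig(), read_volume("spine.mrc"), read_mask("mask.mrc"))
bundle.write("report/")   # nodes.csv, branches.csv, per-statistic tables
```

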