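# isquant

Quantification of B-cell immune-synapse fluorescence microscopy.

When a B cell meets a surface-tethered antigen — for instance an
antibody-coated 3-μm bead — it builds an immune synapse: the centrosome and
lysosomes (LAMP1⁺ compartments) reorient toward the contact site, the BCR
clusters centrally, actin remodels, and lysosomes dock at the synaptic
membrane to extract antigen. `isquant` implements the image-analysis half of
that biology as a tested, reusable library and CLI:

- **Polarity index** of any fluorescent label. With Cellmc and Beadmc the
  centers of mass of the cell and the bead and **c** the label's
  fluorescence center of mass, the index is the signed scalar projection

  PI = ((**c** − Cellmc) · **û**) / ‖Beadmc − Cellmc‖,  **û** the unit
  cell→bead axis,

  ranging from −1 (anti-polarized) through 0 (unpolarized) to +1 (fully
  polarized, label at the bead center).
- **Around-bead fraction**: label intensity within a concentric disc
  (default radius 3.5 μm) around the bead, normalized to the whole cell.
- **Antigen extraction**: percent of bead fluorescence remaining per time
  point, normalized to time 0.
- **Spreading area**, **circularity** 4πA/P², **BCR recruitment index**
  (central-quarter vs total fluorescence density − 1) and **focus counts**
  (particle analysis with a 0.10–4.00 μm² size window) at the synaptic
  plane.
- **3D voxel models**: threshold → per-slice erosion → z-linkage into 3D
  compartments, volume by voxel counting; pairwise marker intersections;
  all-or-nothing selection of compartments containing a second marker
  (LAMP1⁺Ag⁺, LAMP1⁺Ag⁺SNX5⁺); per-cell volume binning (<6, 6–12, >12 μm³);
  Pearson and Manders M1 colocalization coefficients.
- **Synthetic scenes**: because such studies rarely deposit raw stacks, a
  simulator renders cell + bead + labeled compartments with a controllable
  polarization parameter and analytic ground truth, so every metric is
  testable end-to-end.

## Worked example

```python
import isquant as iq

spec = iq.SceneSpec(polarization=0.8, seed=3)   # strongly polarized cell
scene, truth = iq.generate_scene(spec)

cfg = iq.PipelineConfig(seed=3)
row = iq.quantify_scene(scene, cfg, "demo")

print(row["polarity_LAMP1"])          # 0.3176
print(row["around_bead_LAMP1"])       # 0.4285
print(row["pct_containing_antigen"])  # 94.94
print(row["pearson_r"])               # 0.8185
print(truth.expected_index["LAMP1"])  # 0.4044  (analytic, pre-noise)
```

The measured LAMP1 polarity index (0.32) sits close to the value implied by
the generative placement (0.40) — blur, shot noise and voxelization account
for the gap; at `polarization=0` both settle near 0. 94.9% of the LAMP1⁺
compartment volume contains antigen signal under the default marker
co-occupancy, and the Pearson coefficient of the LAMP1/antigen channels
inside the cell is 0.82.

From the shell:

```sh
isquant generate  --config cohort.yaml --out scenes/
isquant quantify  --config cohort.yaml --scenes scenes/scene_000.ome.tif --out metrics.csv
isquant summarize metrics.csv --by condition --out summary.csv
```

`quantify` emits one row per cell with every metric plus provenance (config
hash, seed, version); `summarize` reduces to per-group mean ± SEM. Exit
codes: 0 success, 2 partial (failed scenes logged, cohort continues), 1
fatal/config error.

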