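# Methods

This note documents the measurement definitions, the synthetic-scene model,
the numerical choices, and the limitations of `isquant`.

## Conventions

Voxel grids are indexed `(z, y, x)`; physical coordinates are `(x, y, z)`
in μm; a voxel's center sits at `index × spacing`, 0-based. Anisotropy is
carried, never resampled: volumes are voxel counts × `dz·dy·dx`, in-plane
areas pixel counts × `dy·dx`. No background subtraction is applied by
default; a constant offset can be configured (`background_offset`).

## Polarity index

For a label with fluorescence center of mass **c**, cell center of mass
Cellmc (uniform weighting of the cell mask) and bead center Beadmc (bead
geometry), the index is the signed projection of **c** − Cellmc onto the
unit cell→bead axis divided by the axis length. The distinction in
weighting matters: cell and bead centers are geometric, label centers are
intensity-weighted. Values outside [−1, +1] — possible when a label's
center lies beyond the bead along the axis — are clamped and flagged
(`clamped` field, WARNING log); clamping keeps group means comparable while
the flag preserves the information. An alternative would be excluding such
cells; both conventions are defensible, and the flag lets users re-filter.
The computation is dimension-agnostic, so a 2D single-plane mode comes for
free for epifluorescence-style data. A coincident cell and bead center is a
degenerate axis and a hard error, never a silent 0.

## Around-bead fraction and antigen extraction

Both operate on sum projections along z. The around-bead fraction divides
the intensity of cell pixels within `analysis_radius` (default **3.5 μm**,
read as the disc *radius*: it must contain a 3-μm bead plus its docking
rim; a 3.5 μm diameter could not) of the bead center by the total cell
intensity; it is bounded in [0, 1] and monotone in the radius. Extraction
time courses measure a fixed disc around the bead per time point and
normalize to time 0, which is therefore exactly 100%.

## Segmentation chain

`threshold → erode_slices → link_roi_3d` mirrors the classic per-slice
pipeline: a global or per-slice Otsu (or fixed) threshold, one-pixel 2D
erosion with a 3×3 structuring element to refine boundaries, then
connection of in-plane ROIs across consecutive z-slices. A machine-learned
pre-segmentation step is deliberately not reproduced; user-supplied masks
can be imported instead. In-plane connectivity is 8 by default (4 as an
option — tools differ and the original setting is not recorded); across z,
two voxels link only when they share the same (y, x) column in consecutive
slices, the minimal reading of "adjacent along z". Particle analysis
bounds are inclusive at both ends (a printed closed range like
0.10–4.00 μm² includes its endpoints), with a 1e-9 relative epsilon so
that exact physical areas survive float products.

## Compartment selection and colocalization

Selection of compartments "containing" a second marker is all-or-nothing:
one overlapping voxel selects the whole compartment volume, regardless of
the amount of marker inside; `min_overlap_voxels` raises that bar for
sensitivity analyses. The nested fraction reports (i) selected volume /
total compartment volume and (ii) the marker2-overlap volume of the
selection relative to the marker2 overlap of all compartments. Zero
denominators flag the value as undefined (`None`) rather than reporting 0.

Volume bins for `<e1, e1–e2, >e2` labels use [0, e1), [e1, e2], (e2, ∞):
closed middle bin, values on interior edges to the lower bin; the
convention is fixed here because printed labels leave it ambiguous.
Percentages are volume-weighted per cell and sum to 100.

Pearson's r is the sample correlation of paired voxel intensities over the
masked z-stack. Manders M1 is the fraction of a channel's integrated
intensity falling inside a *binary reference model* derived from
segmentation of the reference channel (colocalization plugins differ on
thresholded vs raw references; the segmentation provenance is recorded on
the model). Per-cell values are summarized across cells as mean ± SEM;
inferential statistics are out of scope.

## Synaptic-plane metrics

The synaptic plane is supplied explicitly or chosen as the z-slice of
maximal integrated intensity of a template channel (phalloidin-like, since
the original selection was by eye from the actin label). Spreading area is
the physical area of the outline (pixel count × pixel area, or exact
polygon area). The recruitment index scales the outline by a linear factor
0.5 about its centroid (¼ area) and reports central density / total
density − 1: 0 uniform, −1 fully peripheral, +3 fully central; a log2
variant is config-switchable because the formula behind the published
sign convention is not fully specified. For raster outlines the central
region is the exact affine image of the mask under the 0.5 scaling
(membership tested by inverse mapping), which generalizes the polygon rule
to arbitrary shapes without an area-bisection search.

Circularity is 4πA/P². For polygons, area and length are exact. For raster
masks the perimeter comes from marching-squares contour tracing of the
mask smoothed by a 1-pixel Gaussian: on a hard binary mask the traced
contour staircases and overestimates smooth perimeters by ~6%, while the
smoothed 0.5-level set places the boundary at subpixel accuracy (<1% error
on discs and ellipses, ~2% corner rounding on rectangles — verified
against a Crofton-formula estimator). Consequence: circularity of very
small raster regions (a few pixels across) is unreliable and can exceed 1;
the metric is intended for whole-cell outlines hundreds of pixels across.
Multi-component masks are rejected with instructions to pass the largest
component, keeping the choice explicit.

## Synthetic scenes

The generator emulates what the metrics were designed to measure: an
ellipsoidal cell (default semi-axes 4 μm — a ~8-μm B cell), a bead of
radius 1.5 μm docked tangent to the cell surface, and `n` spherical
compartments (default 40, radius 0.4 ± 0.08 μm, lysosome-sized). Each
compartment carries each marker independently with the `marker_table`
probabilities (default LAMP1 1.0, Ag 0.6, SNX5 0.6), producing compartments
with one, two or three labels and hence non-trivial intersection volumes.

Placement: with probability `p` (`polarization`) the center direction is
drawn from a von Mises–Fisher kernel (κ = 8) peaked at the bead direction,
otherwise uniformly on the sphere; the radial coordinate is uniform in
volume within the cell shrunk by the compartment radius, so compartments
sit strictly inside the cell (impossible placements raise a named error).
This gives a monotone, roughly linear map p → polarity index saturating
near 0.5 at p = 1 for the default geometry (the attainable maximum is
bounded by cell radius / axis length ≈ 0.73, and the vMF spread plus
volume-uniform radii keep the expectation below it).

Rendering: solid-sphere indicators × amplitude (100), Gaussian PSF blur
(σ = 0.2 μm), then Poisson shot noise (1 photon per intensity unit) and
Gaussian read noise (σ = 2), clipped at 0. Sampling is confocal-like:
0.25 μm in-plane, 0.5 μm in z, within the 0.25–0.5 μm z-step regime the
metrics assume. Ground truth (centers, radii, volumes, marker membership,
label centers of mass, expected polarity per label, pairwise pre-blur
overlap volumes) is computed from the pre-noise geometry. One
`numpy.random.default_rng(seed)` stream drives everything, so a (spec,
seed) pair is voxel-reproducible.

`expected_polarity` is a placement-only Monte-Carlo oracle: it simulates
compartment placements without rendering and returns the mean ± sd of the
volume-weighted polarity index. Parameter-recovery tests compare the full
render→segment→measure path against it; with the default 20-compartment-
to-40-compartment scenes the two agree to well under 0.15 mean absolute
error across p ∈ {0, 0.25, 0.5, 0.75, 1}.

What the simulator does *not* model: realistic PSFs (Airyscan,
depth-dependent aberration), bleaching/blinking, camera gain, vesicle
shapes other than spheres, cytoskeletal texture, and cell-to-cell
morphology variation. Passing tests therefore demonstrate correctness of
the *measurement arithmetic* under known geometry, not robustness to every
property of real microscopy data — segmentation quality on real stacks
remains the user's responsibility (hence the user-supplied-mask escape
hatch).

## Pipeline

`PipelineConfig` (pydantic) validates every tunable before computation and
is hashed into each output row together with seed and package version.
Scenes are processed independently; a failing scene is logged with an
event code and skipped (CLI exit code 2 signals partial success). Missing
metrics are explicit nulls, never 0. Reruns with the same config are
byte-identical; no timestamps enter the tables. Problem sizes used in the
test and acceptance suites (48² × 20 voxel grids, 20 seeds per condition,
100 random oracle grids ≤ 13³) were chosen so the full validation runs in
seconds while keeping Monte-Carlo standard errors an order of magnitude
below the tolerances being checked.
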