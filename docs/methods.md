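# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `mibipipe`, in the spirit of a methods supplement.

## Imaging model and geometry

Channels are nonnegative ion-count images, one per antibody mass tag.
The physical scale is set by `pixel_size_um = field_width_um / raster_px`;
the default high-resolution geometry is a 400 µm field at 1024 × 1024 px
(0.390625 µm/px), with a 512 × 512 low-resolution variant. All pixel-radius
↔ µm conversions in the spatial module derive from this ratio, e.g.
50 px ≈ 20 µm, 100 px ≈ 39 µm, 300 px ≈ 117 µm.

## Preprocessing

**Background removal.** Signal on the bare gold slide correlates with the
Au channel. The mask is `gaussian(Au, R) ≥ T · max(gaussian(Au, R))` with
defaults R = 1 px and T = 0.15 (midpoint of the sensible 0.1–0.2 range;
both exposed in config). Masked pixels are zeroed in every non-background
channel — zeroing, not scaled subtraction, is the implemented reading of
"removing" background. An all-zero background channel yields an empty mask
rather than a degenerate full one. The op is idempotent: the Au channel
itself is never modified, so the mask is stable under re-application.

**FFT denoising.** A radially symmetric low-pass at a normalized cutoff
frequency (default 0.3 cycles/px; dense channels may warrant other values —
the cutoff is configurable and echoed to the run log). Negative ringing is
clipped to zero. Clipping breaks strict idempotence on images with ringing;
on smooth images the op is idempotent to 1e−9, and DC (the mean) is
preserved to well under 1 %. In the full `preprocess_stack` chain the
background mask is re-applied after the low-pass so blur leakage cannot
paint tissue signal back onto the slide.

**Spillover.** Adduct/oxide contamination is compensated pairwise and
sequentially in configured list order: `target ← max(target − c·source, 0)`,
with coefficients in [0, 1). No joint matrix inversion is attempted — the
known contamination list is pairwise and sparse. Where no clipping occurs,
compensation after forward mixing with the same coefficients is an exact
identity (verified to machine precision).

## Stitching

Registration uses declared grid offsets only; acquisition offsets are known
in this modality, so no cross-correlation refinement is performed. Overlap
zones are linearly feather-blended (a dialect choice — blending equal
content is exact, and weights renormalize so no vignetting is introduced).
Flat-field correction builds an intensity-response map per tile (downsample
×8, Gaussian smooth σ = 2, renormalized to mean 1 inside the tissue mask)
and divides it out; `per_channel` uses each channel's own map,
`all_channel` the channel average (which averages out biologically distinct
distributions, leaving detector response). Maps are floored at an additive
epsilon inside tissue. Edge cropping removes `floor(0.01·dim)` px per side.
After assembly each channel passes a median filter with a 2-px disk
footprint; mosaics can be downsampled so the largest dimension is ≤ 2048.
Linear auto-scaling exists for display only and never feeds quantitative
tables.

## Discretization

**Cells.** Nuclear masks come from an external segmenter or the built-in
classical fallback (Gaussian smooth, Otsu threshold, distance-transform
watershed, size filter) — adequate for round, well-separated phantom
nuclei, not a replacement for a learned model on real tissue. Masks are
expanded by a Euclidean distance (default 3 px, configurable; no printed
value generalizes across magnifications). Contested pixels go to the
nearest nucleus; exact ties go to the lower label id, implemented with one
distance transform per label in ascending order — O(K) EDTs, trivially
cheap at phantom scale. Expansion is a partition refinement: original
nuclear pixels never change label.

**Objects.** Threshold segmentation: sum the configured channels, Gaussian
blur, threshold (absolute intensity or a quantile of positive blurred
pixels — both modes exist because either convention is defensible),
8-connected components, retain areas in [min_px, max_px]. 8-connectivity
keeps thin glial processes connected. Foreground area is monotone
nonincreasing in the threshold.

**Morphology.** area, perimeter, eccentricity, axis lengths from image
moments; circularity = 4πA/P² (can slightly exceed 1 on digitized shapes).
An optional area-quantile split (default median) stands in for
morphology-based neuron-vs-glia inference; no absolute cutoff is baked in.

**Integration.** Cell and object layers are never merged; their
relationship is the overlap table of (cell, object) pairs sharing ≥ 1 pixel
with shared-pixel counts, recomputable exactly from the two label images.

## Quantification

Per-object totals are summed over label pixels and divided by area
(`raw = value × area` holds to 1e−6 by construction). Normalization is
`log(1+x)` (natural log; +1 avoids log 0) followed by division by the
per-channel quantile (default q = 0.99, linear interpolation) computed over
all objects of all FOVs jointly — pooling keeps values comparable across
fields — then clipped to [0, 1]. All-zero channels stay zero with a
warning, never NaN. FOV fingerprints are per-marker mean pixel intensities,
z-scored within each marker (hence invariant to per-marker affine
rescaling) and average-linkage clustered with Euclidean distance on both
axes. Fingerprints are computed after background removal; computing them
before would mostly fingerprint slide area.

## Phenotyping

Gating is ordered and exclusive: endothelial (CD31 | MCT1 | CD105), then
microglia (CD45 | Iba1), then astrocytes (GFAP), remainder = neurons.
Positivity thresholds apply to [0, 1]-normalized expression and must be
explicit in config (default 0.5); there is no silent curation step.
Threshold-segmented objects bypass gating — their class is fixed by the
source channel.

Meta-clustering follows the FlowSOM idiom: a seeded online SOM (default
10 × 10 grid, 10 epochs, Gaussian neighborhood with linearly decaying
radius and learning rate, data-range initialization) maps objects to nodes;
node weights are average-linkage clustered and cut at `n_meta` (default 11
for neuronal subsetting). The SOM is implemented in-package
(`mibipipe.som`) and kept deliberately minimal; k-means serves as an
independent cross-check in the test suite. Embeddings delegate to UMAP
with a fixed random state.

## Spatial statistics

**Distances.** Co-proximity uses periphery distances: the minimum Euclidean
distance between boundary-pixel centers (boundary = object minus its
erosion); overlapping or touching objects score 0, and an object is never
its own neighbor. Neighborhood profiles and the voronoi expansion use
centroids — boundary distance is specified only for co-proximity.

**Null model.** expected(t) = n_B · πt² / A_FOV, the chance count under
uniform dispersion; for a class against itself the candidate count is
n_B − 1. There is **no edge correction**: discs truncated by the field
border make the observed count, and hence the ratio, biased low by roughly
the mean truncated-disc fraction (≈ 5–9 % for t ≤ 100 px on a 1024-px
field, growing with t/L). This mirrors the analytic form of the null and is
accepted as a known conservative bias. Observed counts are means per
A-object (not FOV totals), which keeps the ratio placement-scale-free;
ratios are NaN-flagged when no candidate B objects exist.

**Association ratio.** n(cells overlapping ≥ 1 object of the class) /
n(cells with none), per lineage per group; zero denominators are flagged
infinite rather than dropped.

**Region discovery.** Per-object neighborhood profiles (class proportions
within a centroid radius, default 50 px, self included) are pooled across
samples and clustered by SOM + linkage at each k in a range. The chosen k
is the smallest whose mean silhouette (subsampled at 5000 profiles for
large tables) exceeds a floor (default 0.2), comes within 1 % of the best
silhouette over the range, and has every sample represented in every
cluster. The near-best requirement operationalizes "the minimum number of
regions common to all samples": a bare floor would always stop at the first
k that crosses it and never reach the real structure. If nothing qualifies
the best-silhouette k is returned with a warning. The canonical region
names are N, G, M, AP, TT (neuronal, glial, mixed, plaque-dominant,
tangle-dominant). Voronoi expansion then assigns every tissue pixel the
region of its nearest labeled centroid — idempotent, covering exactly the
tissue mask.

**Synaptic coincidence.** Pixel positivity per channel (explicit threshold
or Otsu on the denoised channel). Excitatory synaptic pixels =
SYP ∧ PSD95 ∧ (VGLUT1 ∨ VGLUT2); inhibitory = SYP ∧ VGAT ∧ GAD. The score
per region and proteopathy channel is |synaptic ∧ proteopathy⁺| /
|synaptic|, NaN-flagged where a region holds no synaptic pixels.

## The phantom generator

The generator emulates: round nucleated somata (neurons r = 6 px, glia
r = 4 px at the 1024-px scale), thin ramified process arms for microglia
and astrocytes (intensity only — ground-truth cell labels are somata),
elongated vessel capsules, disk-shaped plaque/tangle aggregates (an
optional lobing parameter adds amorphous boundaries; the default is exact
disks so planted areas are analytic), Poisson count noise on per-class
per-marker mean intensities (Gaussian and noise-free modes exist; the true
MIBI noise spectrum is not asserted), a gold background channel high
exactly off-tissue, a carbon channel high on-tissue, and optional linear
spillover injected between channel pairs. Tangles are planted near neuron
somata with probability 0.7 and plaques only in acellular space, giving the
association statistics real signal. Same-layer structures keep a small
clearance (2 px cells, 4 px objects) so planted counts stay resolvable
under the segmentation blur; requested counts that cannot be placed raise
an explicit placement error. Everything is driven by one seed;
identical seeds give byte-identical outputs.

What the phantom does **not** model: realistic tissue texture and
autocorrelated neuropil, partial-volume and section-thickness effects,
antibody sensitivity differences, TOF detector artifacts, true plaque/NFT
morphology. Passing phantom tests therefore demonstrates correctness of the
computations on known ground truth, not segmentation or clustering accuracy
on real tissue.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances —
128–1024 px fields, tens of structures, hundreds of table rows, 20
replicate FOVs for the null calibration, 50 random instances for the
exhaustive oracles — sizes at which the exact oracles (all-boundary-pixel
brute force, per-pixel nearest centroid, enumerated grid disks) remain
tractable while estimates are statistically stable. The pipeline derives
per-stage seeds as `seed + stage index`; rerunning a config reproduces
deterministic artifacts checksum-identically.

## Known limitations

- The uniform null carries the edge bias described above; permutation
  nulls are out of scope.
- The fallback nuclear segmenter under-splits dense nuclei clusters and is
  only a stand-in for a learned segmenter.
- Sequential subtraction is order-dependent when spillover chains overlap;
  the configured list order is authoritative and echoed to the log.
- Plaque subtyping (neuritic vs diffuse) and batch-effect correction are
  not implemented.
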