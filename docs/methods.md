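# Methods

This note documents the models and estimators implemented in
`spindlemetrics`, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Coordinate conventions

Voxel indices are 0-based `(z, y, x)`; the physical position of a voxel is
`index × voxel_size`, measured at voxel centres, in micrometres.  All
geometry — axes, centroids, widths, distances — is computed in physical μm
coordinates, never in index units, so anisotropic voxels are handled
uniformly.  The default grid is 20 z-slices at 1 μm (a 20 μm axial range,
matching typical live meiocyte acquisition) with 0.2 μm lateral sampling,
shape `(20, 96, 160)`.

## Spindle phantom

A spindle is modelled as a bundle of straight fibers from the metaphase
plate toward each pole.  Fiber anchors are sampled uniformly on the plate
disc (radius `R = plate_width / 2`).  The **divergence** parameter
`d ∈ [0, 1]` sets the residual lateral offset at the pole to `d` times the
anchor offset, so the bundle envelope at axial fraction `f` of the
plate-to-pole distance has radius `R·((1 − f) + f·d)`: a cone for `d = 0`,
a cylinder for `d = 1`.  The closed form for the focus ratio measured at
fraction `f` is therefore `(1 − f) + f·d`, which the recovery tests use as
the oracle.  The chromosome mass is a uniform oblate ellipsoid of diameter
`plate_width` and thickness 2 μm at the plate (uniform rather than tapered
so its half-maximum profile width equals its diameter exactly).

Defaults: plate width 10 μm, half-length 12 μm, 5000 fibers, two poles.
The fiber count matters: a real spindle contains thousands of microtubules
and images as a continuous bundle; with only hundreds of rendered fibers
the cross-section is sparse speckle and any width estimate is dominated by
sampling noise.  5000 fibers keeps the residual speckle below the
measurement tolerances.  Fiber points are deposited with a per-fiber random
sampling phase along the axis; a shared phase would alias into a strong
sawtooth in the per-slab integrated intensity.

Multi-spindle layouts place parallel spindles side by side with a
configurable empty gap; a tripolar layout adds a third pole perpendicular
to the main axis.  Each spindle's plate centre is the centroid of its pole
group.

**Optics**: anisotropic Gaussian PSF (default σ = 0.6 μm axial, 0.25 μm
lateral — widefield-like), Poisson shot noise on `signal × photon_scale +
background` (defaults 80 and 10 counts), and additive Gaussian read noise
(σ = 2).  `Optics.noiseless()` disables background and both noise sources
but keeps the PSF, for geometry-limited tests.  Every generator is a pure
function of its parameters and seed.

## Segmentation

Global histogram thresholding with small-object removal (27-voxel floor,
26-connectivity).  The tubulin channel defaults to **Otsu on
log-transformed intensities**: a focused pole is orders of magnitude
brighter than the mid-spindle, and on that skewed histogram a linear Otsu
cut retains only the poles (in our phantoms, 13% of the true fiber voxels,
with the mask split in two).  The chromosome channel defaults to linear
Otsu: its foreground is under 1% of the voxels, which destabilises the
log-scale criterion, while the compact high-contrast blob is the textbook
bimodal case.  Both choices are per-call options (`otsu`, `otsu-log`,
`triangle`), and the threshold actually used is recorded in the result for
provenance.  Constant images raise a degenerate-input error.

## Axis, plate and half-spindle measurement

The spindle axis is the principal eigenvector of the intensity-weighted
second-moment matrix of the tubulin channel inside its mask; if the two
leading eigenvalues agree within 5% the distribution is effectively
isotropic and an anisotropy error is raised.  The plate centre is the
intensity-weighted centroid of the chromosome channel inside its mask.
The two half-spindles (ids 1 and 2, the positive and negative side of the
axis) are measured independently; cell-level summaries average the two.

* `L`: distance from the plate centre to the farthest masked tubulin voxel
  projected onto the axis on the requested side.  Ties are broken by
  intensity, then lowest `(z, y, x)` index.
* `W_C`: full width at half maximum (FWHM) of the chromosome-channel
  intensity profile along a line through the plate centre perpendicular to
  the axis, maximised over 24 in-plane directions.  A tubulin-channel
  alternative is available via `w_c_channel`.
* `W_S`: the same maximised in-plane FWHM of the tubulin signal, in the
  plane at axial distance `f·L` from the plate (default `f = 0.75`).
  Using the same aggregation for both widths keeps the ratio of a circular
  cross-section to the plate unbiased.
* `focus_ratio = W_S / W_C`, exactly.

FWHM details: profiles are sampled by trilinear interpolation at the
finest voxel pitch, lightly smoothed (σ = 2 samples), and the half level is
taken between a baseline (5th percentile of the profile) and a robust
plateau estimate (median of the values within 25% of the maximum) rather
than the raw maximum — on flat-topped profiles the residual fiber speckle
would otherwise inflate the half level and pull the crossings inward.
Crossings are linearly interpolated.  Widths are FWHM by design (robust to
the segmentation threshold); a mask-extent alternative is available via
`width_mode="mask"`.  Width was measured manually in the original
workflow this package automates, with no operational definition, so the
FWHM convention is a deliberate, configurable choice.

Known estimator biases, measured on noiseless phantoms: the cylinder limit
reads ≈ 1.01–1.03 (direction-maximisation picks up residual speckle) and
the cone limit reads ≈ 0.25 ± 0.003; both are inside the ±0.05 bands the
recovery tests assert.  The axial PSF (σ 0.6 μm against 1 μm slices)
softens edges tangent to the axis and is the main contributor to the
remaining width error (≈ 0.4 μm at default noise).

## Topology

Spindle counting: connected components of the tubulin mask
(26-connectivity), with components whose gap is below `min_gap` μm merged
(the background Euclidean distance transform is thresholded at
`min_gap / 2`, which bridges narrow splits).  Pole counting per component:
voxels at ≥ 55% of the maximal distance from the component centroid are
candidates, and their direction vectors are clustered greedily
(farthest-first) within 45°; each cluster is one pole.  This is equivalent
to finding the peaks of the component's radial-extent function while being
robust to the ring-shaped maxima a flat-ended (high-divergence) component
produces along one direction.  Pole counts are meaningful for focused and
moderately divergent spindles; for a near-perfect cylinder the "pole" is a
face, not a point, and the count is not well defined.

## Kinematics

Objects are labeled per frame (26-connectivity) and linked across frames
by optimal nearest-centroid assignment (Hungarian algorithm on the
centroid distance matrix) with an optional maximum displacement per frame;
unmatched detections open new tracks, and empty frames are flagged rather
than fatal.  Centroids are intensity-weighted, in μm.

Anaphase A distance is the 3D displacement of a chromosome mass's centroid
between `t_start` and `t_end`; the rate is that distance divided by the
elapsed time, reported per mass and as the cell mean.  The measurement
window is configurable; by default `t_start` is the first frame at which
the inter-mass distance exceeds its initial baseline by 2 μm and `t_end`
is the last frame — the acquisition that motivated this pipeline did not
state its window, so it is explicit and overridable here.  Chromosome
offset is the plain Euclidean distance between the chromosome-mass and
spindle centroids, a congression metric.

The anaphase generator starts the two masses 3 μm apart so that they are
resolvable as two objects from the first frame; each moves poleward at
±`speed` from `anaphase_onset`, so the separation grows at twice the
poleward speed.

## Statistics

* **ANOVA letters**: one-way ANOVA (F, p) with a post-hoc pairwise test —
  Tukey HSD by default; Fisher's LSD (the agricolae default) as an option —
  converted to a compact letter display.  Letters are assigned from the
  maximal cliques of the non-significance graph, which guarantees the
  display is valid in both directions: two groups share a letter exactly
  when their pairwise comparison is non-significant at `alpha`.
* **Proportions**: Wilson score intervals, chosen over Wald for stability
  at small counts (the rare-phenotype scoring use case: 3 positives of 434).
* **2^−ΔΔCt**: per sample ΔCt = mean target Ct − mean reference Ct; ΔΔCt is
  taken against the mean calibrator ΔCt (a per-replicate alternative would
  pair wells; the mean-calibrator form is the common default).  Genotype
  summaries are computed on the ΔΔCt scale and exponentiated, so the point
  estimate is the geometric mean of per-sample expressions and noiseless
  generated tables round-trip exactly; CIs are t-based on ΔΔCt.

## Genotyping

Cut positions are 0-based top-strand offsets; a linear molecule with k
sites yields k + 1 fragments whose lengths sum to the amplicon length.
Both bundled enzymes (MseI `T^TAA`, NsiI `ATGCA^T`) recognise palindromic
sites, so single-strand scanning is complete; non-palindromic enzymes are
out of scope.  Allele calls match the observed fragment multiset against
the assay's cut and uncut patterns within a per-fragment size tolerance
(default 5 bp, emulating gel resolution); the union of both patterns is
called heterozygous, as expected when genotyping segregating material.
IUPAC ambiguity codes are rejected rather than expanded: a CAPS call on an
ambiguous template is not meaningful.

The amplicon generator implants recognition sites so cleavage occurs
exactly at the requested positions, then mutates away accidental
occurrences (bounded retries, seeded); impossible placements (overlapping
sites) raise a generation error.

## What the generator does and does not emulate

It emulates: two-channel widefield-like acquisition with anisotropic
voxels and PSF, Poisson + read noise, pole-focus geometry from fully
focused to fully divergent, multi-spindle and tripolar configurations,
constant-velocity anaphase at 5-min sampling, binomial count scoring, Ct
tables with prescribed relative expression, and diagnostic amplicons.

It does not emulate: curved or buckling fibers, astral microtubules,
kinetochore fiber bundling, uneven chromosome arms or lagging chromosomes,
depth-dependent attenuation or scattering, stage drift, photobleaching, or
biological variance structure beyond what the per-cell geometry jitter in
the CLI batch generator adds.  Passing recovery tests therefore
demonstrates that the estimators are correct for bundle-like spindles
under realistic sampling and noise — not that they are robust to every
artefact of real microscopy.

## Problem sizes

Tests and the acceptance script run on the default `(20, 96, 160)` grid
(≈ 0.3 M voxels, ≈ 0.4 s per phantom end to end), 20 phantoms per
divergence level for the recovery sweep, 6-frame movies for kinematics,
and batches of 6–8 cells per genotype for the end-to-end discrimination
check — small enough for a laptop, large enough that every estimator runs
in its realistic regime.
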