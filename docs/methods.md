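# Methods notes

This note records the models behind `punctatrack`, the defaults and their
rationale, the numerical choices, and what the synthetic-data tests do and
do not demonstrate about real recordings.

## Coordinate conventions and units

Image coordinates are 0-based pixels with x = column and y = row; the
apical pole of an upright cell sits at low y. Physical units are explicit
everywhere: positions in nm (1 px = 210 nm by default), time in s (1
frame/s), displacement and speed in nm and nm/s, trajectory in μm, area in
μm². The cell-axis correction applies exactly

    x' = x·cosθ + y·sinθ
    y' = y·cosθ − x·sinθ

with θ the angle between the apico-basal axis and the image vertical; after
rotation y′ is the apico-basal coordinate. θ is a per-cell annotation: the
package does not estimate it from images, because axis determination in
real data is a manual choice (e.g. the line through basal body and
synapse). Synthetic geometries carry their exact θ.

## Tracking model

Segmentation follows the fixed-parameter recipe (blur σ 0.1 px — effectively
no smoothing, retained as the configured default; min-max normalization;
threshold 0.30; 4-connectivity; minimum component size 2 px). The
threshold operates on normalized blurred *intensity*; pixel-classification
front-ends used by interactive tools produce probability maps, which raw
intensity approximates for high-contrast puncta. A constant frame has no
detections by definition (normalization undefined).

Linking solves, independently for each consecutive frame pair, a bipartite
assignment with unmatched-node costs (appearance 9, disappearance 47,
transition weight 3 on the *squared* pixel distance, gate 8 px). Squared
distance is the conventional assignment energy; it implies a break-even
distance of √((9+47)/3) ≈ 4.32 px beyond which ending one track and
starting another is cheaper than linking. Because mergers are capped at one
object and divisions are disabled, the frame-pair factorization is exact —
the implementation is the optimal solution of the full model, verified
against exhaustive enumeration in the tests. Ties (equidistant
alternatives) resolve toward lower detection indices via the solver's scan
order; with continuous coordinates ties have probability zero. There is no
gap closing: a particle undetected for one frame restarts as a new track,
consistent with the appearance/disappearance semantics. The division
weight (10) is stored for completeness but inert.

Registration is translation-only: each frame of the puncta channel is
aligned to frame 0 by phase cross-correlation and both channels receive the
same shift. Integer shifts are exact; sub-pixel refinement is available via
`upsample_factor`. **Caveat:** registration assumes the field of view is
dominated by static structure. On single-cell synthetic videos whose only
channel-1 content is the moving puncta themselves, the correlation locks
onto particle motion and cancels it; the pipeline therefore leaves
registration off by default and enables it explicitly for drifting inputs
(the drift tests inject and recover known stage drift).

## Kinematic definitions and edge cases

- Displacement uses track endpoints only; trajectory sums consecutive
  steps; maximum speed is the largest single step over the frame interval.
- Directionality is the ratio of coordinate *spans* (max − min) after axis
  rotation. Span, not summed excursion, is the implemented reading of
  "maximum distance spanned". Tracks with zero apico-basal span have
  undefined directionality, are excluded from the per-cell mean and
  counted in `n_undefined_directionality`.
- Area is the mean over the track's frames of pixel count × pixel area
  (per-frame aggregation was not further specified; the mean is the
  natural per-track reduction).
- The BB contact radius is 3 px = 630 nm, *inclusive* at the boundary
  ("within" is ambiguous; the closed ball is the documented choice).
- Single-frame tracks have zero displacement/trajectory and undefined
  maximum speed; they cannot occur after the ≥ 10-frame eligibility filter
  but the functions handle them anyway.
- Per-cell summaries are unweighted means over eligible tracks; a cell
  with no eligible tracks is reported with `n_tracks = 0` and NaN means,
  never silently dropped.

## Statistical choices

All p-values are two-sided. Student's t is the classical equal-variance
test (Welch via flag). The Mann-Whitney U is exact by full enumeration of
group labelings for combined n ≤ 16 — correct under ties because U is
recomputed per labeling with midranks — and uses the tie-corrected normal
approximation above that. The two-sided exact p doubles the smaller tail
and caps at 1. Degenerate inputs follow explicit conventions: two constant
equal samples give p = 1; an all-identical ANOVA gives F = 0, p = 1. No
multiple-testing correction is applied, matching per-parameter reporting;
no post-hoc tests follow the ANOVA. The colocalization criterion
(unspecified upstream) is centroid-in-mask, with a centroid-distance
fallback whose default radius reuses the 630 nm contact radius.

## Synthetic-data model

The generator emulates the acquisition the analysis expects: 600 frames at
1 frame/s, 210 nm pixels, channel 1 moving puncta, channel 2 a static BB
blob.

**Geometry.** A rectangular footprint of length 60 px (12.6 μm) and width
16 px (3.4 μm), rotated by θ, with the BB just inside the apical end and
compartment boundaries at fixed length fractions (outer segment 15%, inner
segment 60%, synaptic region 25%). These dimensions are a realistic larval
photoreceptor scale and — together with the default particle count — keep
puncta sparse enough that blob overlap is occasional rather than constant.

**Motion.** Per frame each particle takes independent Gaussian steps in
the cell frame (axial σ 400 nm, lateral σ 150 nm), rotated into image
coordinates, reflected at the inner-segment compartment boundaries
(reflection, not absorption, so confinement does not destroy path length),
with the step norm capped at 1 μm so that maximum per-frame steps approach
the ~1 μm/s maximum-speed scale. With probability 0.002 per frame a
particle starts an excursion: a constant-speed run (800 nm/s) to within
200 nm of the BB and back to its origin, then diffusion resumes. The
excursion speed is deliberately below the linker's 4.32 px break-even
distance (907 nm at 1 frame/s) so that excursions remain trackable, as the
fastest observed particles evidently were. Particles disappear
geometrically (mean lifetime 400 frames) and appear at 0.01/frame; default
count is 5 per cell. Density and signal-to-noise are not published
anywhere, so these defaults are calibrated only against the printed
kinetic scales and the calibration property below.

**Rendering.** Isotropic Gaussian blobs (σ 250 nm ≈ the diffraction limit
at the stated magnification; no PSF is published), peak 1000 over
background 10, optional Poisson shot noise and Gaussian read noise from a
dedicated seeded generator, optional per-frame stage drift applied to true
positions (identical to translating the rendered frame for integer
drifts), and a "mutant" mode that moves a fraction of the signal into a
diffuse cytoplasmic background, reduces the particle count and doubles
lateral σ — a qualitative emulation of the mutant phenotype, with no claim
about the underlying parameter values.

**Calibration property.** With the default anisotropy, ≥ 90% of tracks
measured by the full pipeline on noiseless renders have directionality < 1
(measured ≈ 92% pooled over seeds). The margin is real but modest; most
of the > 1 tail comes from transient blob merging between nearby
particles, which displaces the merged centroid laterally.

## What the generator does *not* emulate

- **Pausing.** Real vesicles alternate pauses with movement; the Gaussian
  walk steps every frame at the observed *maximum-speed* scale. The
  simulated per-track trajectory (~600 × mean step) is therefore several
  times larger than published trajectories (~21 μm over 10 min), while
  displacement (confinement-limited) and maximum speed (cap-limited) are
  on the published scales. Matching all three simultaneously would require
  a multi-state (pause/run) model that the analysis itself does not need.
- 3-D motion and focal-plane exit as anything richer than geometric
  disappearance; photobleaching kinetics; nuclei/outer-segment structure;
  autofluorescence; multiple cells per field.
- Real tracking front-ends: segmentation operates on intensity, not
  learned pixel probabilities.

Consequently, passing synthetic tests demonstrates correctness of the
measurement chain (segmentation, optimal linking, metric arithmetic,
statistics) and its calibration behaviour — not that the motion model is a
faithful generative model of vesicle biology.

## Problem sizes in the automated checks

The acceptance script runs the full five-condition study at 13
photoreceptors per condition and 600 frames per video, the replication
design's scale; oracle-equivalence checks use 200 random instances with up
to 4 detections over up to 5 frames (the largest sizes exhaustive
enumeration handles comfortably); estimator-recovery checks use 50
isotropic walkers of 600 frames. The unit-test suite uses smaller
versions of the same fixtures to stay fast.
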