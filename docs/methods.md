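# Methods

## Internalization scoring

### Model

Receptor internalization is proxied by image texture: a surface-resident
receptor-GFP forms a smooth membrane rim, an internalized one a punctate
vesicular pattern. For each segmented cell the intensities inside the
surface mask are linearly quantized to N gray levels over the mask's own
min..max range, a co-occurrence matrix p(i, j) is accumulated over pixel
pairs at a fixed offset, and the contrast C = Σ |i − j|² p(i, j) is
reported. Quantizing over the mask's own range makes C exactly invariant to
affine intensity transforms (gain and offset), so cells imaged with
different settings are comparable after the stated normalizations.

Assumptions: the analysis is 2D (maximum-intensity projections), the mask
is a faithful cell footprint, and texture at the chosen offset (default:
horizontal neighbor) is representative — texture in these cells is
approximately isotropic, so a single offset suffices.

### Parameters

| parameter | default | rationale |
|---|---|---|
| gray levels N | 8 | coarse enough to be noise-tolerant, fine enough to separate rim from puncta; exposed in config |
| offset (dy, dx) | (0, 1) | right neighbor, the common co-occurrence convention |
| symmetric accumulation | off | direction is irrelevant for \|i−j\|², symmetrization changes nothing material |
| quantization range | mask min..max | affine invariance (above) |
| out-of-mask pairs | excluded | the score should reflect intracellular heterogeneity, not the cell/background edge; a zero-fill variant is available behind a flag for sensitivity analysis |
| quality gates | >1% saturated pixels, or <4 occupied levels | explicit, logged stand-in for the manual exclusion of overly bright/dim cells |

Constant masked regions place all mass at p(0, 0) by convention (C = 0).
Degenerate masks with no valid pixel pair at the offset raise an error
rather than returning a silent zero.

### Normalizations and the gradient profile

Raw contrast is normalized either to the mean contrast of reference cells
(non-mobilized cells in the caudal hematopoietic tissue of the same movie,
mode `cht_mean`) or to the per-movie maximum (mode `movie_max`, used when no
reference population exists). The spatial profile assigns each cell the
minimum Euclidean distance from its centroid to the wound-margin polyline
(component centroids for clustered cells) and bins at 25 µm by default,
reporting mean, SEM across cells (n ≥ 2) and n per bin. A decay length is
read off by least-squares fitting A·exp(−d/L).

## Segmentation

Seeded cells: a square core (half-width 5–15 px) around a manually supplied
seed point is evolved by morphological Chan-Vese active contours on a
contrast-normalized image (hence invariant to uniform intensity scaling),
up to 200 iterations with early stop after 5 unchanged iterations. The
4-connected component containing the seed is kept and interior holes are
filled, since the surface metric must include all pixels inside the
outline. Failure modes (constant image, collapse away from the seed,
flooding the frame) raise explicit errors. Whole-image mode thresholds the
frame, fills holes (so a supra-threshold rim yields the full footprint) and
labels connected components; components may be multi-cell clusters by
design. Objects below 50 px are removed (strictly below — objects exactly
at the threshold are kept; the same convention is used for the 60 µm²
cluster filter), and every exclusion is logged with its reason.

## Trajectory analysis

The occupied wound area (owa) is a polygon; points on its boundary count as
inside, which makes entry/exit detection deterministic. Distances use the
exact point-to-edge minimum, not a sampled vertex set. Per step (consecutive
point pair): v_t = |Δr|/Δt in µm/min; d_t is the distance from the step's
start point to the nearest owa-perimeter point (0 inside); cos θ_t is the
cosine between the step displacement and the start-point→nearest-perimeter
vector, undefined (and excluded from binning) for in-owa starts and
zero-length steps. θ is defined per step from the step origin, matching the
instantaneous usage of speed.

Classification: tracks that intersect the owa get a forward segment (first
point up to the last point before first entry; in-owa points are excluded
from forward statistics) and, if points exist after the final in-owa point,
a reverse segment (last in-owa point to track end). A track can contribute
both. Non-intersecting tracks are split into toward-moving (end strictly
closer to the owa than the start) and away-moving; tracks entirely inside
the owa are reported separately. Net reverse traffic divides reverse
segments by owa-intersecting forward tracks; non-intersecting tracks are in
neither count.

Ingestion drops points outside the fin polygon (movement in the
hematopoietic tissue is excluded) before applying the duration filter
(≥3 time points, boundary inclusive). Straightness restricts each track to
points within 50 µm of the owa (inside counts as distance 0), requires ≥2
zone points and ≥10 µm of restricted path (shorter tracks are reported as
excluded), and returns net displacement over cumulative path length.
Binned profiles default to 25 µm distance bins and 0.25-wide cosine bins;
aggregation is an explicit parameter — `per_step` (error bars across cell
steps) or `per_cell` (first averaged within track per bin) — never
inferred, because different figure-level analyses legitimately use either.
An optional time window (e.g. the 1–2 h post-wound interval) filters steps
before all statistics.

## Cluster statistics

Recruitment counts centroids inside a closed, axis-aligned 200 × 200 µm
square about the wound center. Cluster size drops surfaces below 60 µm² and
averages across object-frame observations in the stated window (a per-frame
mean first is available as an option). A candidate owa can be extracted
from a maximum-intensity time projection (largest supra-threshold
component's outline); the final owa remains user-editable.

## Synthetic scenes: what they emulate, and what they do not

**Cell phantoms.** One cell per frame; total flux is fixed (conserved to
<0.1% across parameter values, so contrast comparisons are texture, not
brightness). A constant cytosol fraction (0.25) forms a diffuse interior
pool; the remaining receptor pool is split by the vesicular fraction vf
between a membrane ring and interior puncta. The ring is shaded with a
radial Gaussian of σ = 2× the membrane thickness — the membranous phenotype
must be genuinely smooth, and a sharp rim would itself be high-contrast
texture. Puncta are Gaussian spots (σ 0.3 µm) whose *number* grows with vf
(round(vf · 12), ≥1 for vf > 0) at roughly constant per-punctum flux,
placed on a jittered golden-angle spiral inside the interior eroded by one
membrane thickness. Both choices are deliberate: internalizing receptor
accumulates in more endosomes rather than brighter ones, and because
quantization is per-cell min..max a fixed set of puncta with scaled
amplitude would give a vf-independent texture (contrast would saturate);
the growing-count design yields a near-affine, monotone contrast–vf
relation. The spiral placement keeps puncta separated, which removes most
seed-to-seed variance of the score. Defaults (0.5 µm/px, cell radius 5 µm,
membrane 0.75 µm, background 100 counts, Poisson noise, 16-bit output with
clipping) emulate confocal time-lapse of larval neutrophils.

**Gradient scenes.** Cells are rejection-sampled (non-overlapping, within
300 µm of the margin) and each carries the ground-truth vesicular fraction
exp(−d/λ) with λ = 200 µm, emulating ligand-driven internalization near a
wound margin. The margin defaults to a straight left-edge polyline; its
real-data counterpart is hand-drawn, and the geometry is a modeling choice,
not a claim about wounds.

**Walkers.** Persistent random walks at a 30 s frame interval (240 frames ≈
2 h, the typical analysis window): outside the owa the heading is von Mises
about the previous heading with κ_p = 2p/(1−p) for persistence p∈[0,1), or
about the direction to the nearest owa-perimeter point with concentration
κ (the bias) when within the bias range. Speeds are truncated-normal
(default 8 ± 2 µm/min) with an optional orientation coupling
v = v₀(1 + a·cos θ) for recovery tests. On entering the owa a walker dwells
(default 10 frames), then with probability `p_reverse` actively exits
through the nearest boundary point and walks unbiased, treating the
occupied cluster as a reflecting obstacle — a dispersing cell does not
re-join the cluster; the rest stay confined inside. The fin boundary
reflects (mirror about the nearest boundary point, stay-in-place fallback).
Ground-truth labels are derived from the realized geometry with the same
closed-polygon inside test the classifier uses.

**Not modeled:** photobleaching, stage drift, the z dimension, cell shape
irregularity and deformation, cell–cell contact artifacts within clusters,
receptor biochemistry, and spot detection/linking (trajectories are
consumed as tables, as from tracking software). Passing tests therefore
demonstrate correctness of the measurement chain on controlled input, not
robustness to segmentation or tracking errors in real movies.

## Numerical choices

- Quantized level of intensity v: floor((v − min)/(max − min) · N), clipped
  to N − 1; min == max maps to level 0.
- SEM uses the n−1 denominator and is reported only for n ≥ 2.
- cos θ is clipped to [−1, 1] against floating-point overshoot.
- Decay fits are bounded (A ≥ 0, L > 0) Levenberg–Marquardt via
  `scipy.optimize.curve_fit`.
- Seeds: every generator takes an explicit integer seed; derived seeds are
  drawn below 2³¹. Identical seeds give bit-identical images, tracks and
  pipeline outputs (TIFF writes omit timestamps).
- Problem sizes in the test and acceptance runs — 50 phantom pairs for the
  phenotype ordering, 20 scenes × 40 cells for gradient recovery, 520-track
  cohorts for classification and reverse-traffic recovery — were chosen so
  that sampling error is comfortably below the effect sizes under study.

## Known limitations

- Absolute contrast values depend on N, offset and mask quality; only
  orderings, normalized values and monotone relations are meaningful across
  datasets.
- The exponential-decay fit has no offset term; profiles with a nonzero
  far-field plateau will bias the fitted length upward.
- Threshold segmentation merges touching cells by design; the gradient
  profile treats such components as single clustered observations.
- The walker model is phenomenological: it reproduces the geometry and
  event structure of recruitment/dispersal (entry, dwell, egress) but not
  signaling dynamics, cell interactions, or speed distributions of real
  neutrophils beyond their first two moments.
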