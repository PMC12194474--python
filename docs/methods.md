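# Methods

This note documents the models, conventions and numerical choices behind
`cxraug`, in the spirit of a package's methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Coordinate and image conventions

Images are 2-D grayscale arrays with an explicit scale tag — `eight_bit`
([0, 255]) straight off disk, `unit` ([0, 1]) after min–max normalization.
Coordinates put the origin at the top-left corner, x rightward, y downward,
and are continuous with pixel centers at integer coordinates (no half-pixel
offset). Polygon labels store vertices normalized by image width and height;
the serialized form is one region per line, `class_id x1 y1 x2 y2 …`,
space-separated, 6-decimal fixed point. Round-tripping a label file
preserves class ids exactly and coordinates to 1e-6 (the formatting
precision); coordinate (de)normalization round-trips to 1e-9. Normalized
inputs may overshoot [0, 1] by up to 1e-6 (float dust from upstream tools)
and are clamped; larger overshoot is rejected as malformed. Images labeled
"No Finding" carry an empty label file rather than a whole-image region.

Preprocessing follows the standard recipe for this data: resize to 800×800
with bilinear interpolation, then min–max normalize intensities to [0, 1].
A constant image has no range; it normalizes to all zeros with a warning
rather than dividing by zero.

## The shared affine map

An augmentation is one homogeneous 3×3 affine `T = [R(θ)|t] · S(s_x, s_y)`
— scaling first, then rotation and translation. The plain form rotates
about the origin; rotating an 800×800 radiograph about its corner would
evict the anatomy from the frame, so the pipeline conjugates with center
translations, `T_c · ([R|t]·S) · T_{−c}`, making the image center the pivot.
The pivot is a parameter, so origin-centered behavior remains available and
testable. Angles are user-facing degrees.

The same matrix is applied two ways:

- **pixels** — inverse-mapped resampling (scikit-image `warp`), bilinear
  for intensity images and nearest-neighbor for rasterized masks (averaging
  would smear labels); regions mapped from outside the frame are filled
  with 0, the radiograph background;
- **vertices** — exact matrix multiplication, then clipping to the image
  rectangle. Clipping uses shapely's exact polygon intersection with the
  frame box; if the result splits, the largest piece is kept, and pieces
  with fewer than 3 vertices or area below `min_area` (default 10 px²) are
  dropped — a result, not an error. When nothing is cut away the mapped
  vertices are returned unchanged (same order), so an identity transform is
  exactly the identity on labels.

Alignment is the testable core claim: for lesions of rasterized area
≥ 500 px², the IoU between (a) the rasterization of the transformed polygon
and (b) the nearest-neighbor warp of the original rasterized mask is ≥ 0.95
under every scenario transform. The residual disagreement is boundary
discretization, which shrinks with lesion size.

The spatial-distortion diagnostic `L = Σᵢ‖P̂ᵢ − T(Pᵢ)‖² + λ‖T‖_F` (λ default
0.01; Frobenius norm unsquared) scores how well a transform maps source
landmarks onto targets. It is exposed as a validation metric only — no
optimizer is attached, since the pipeline's transforms are constructed, not
fitted.

## Sampling and clinical bounds

Augmentation parameters are sampled uniformly and independently per output:
the rotation angle from the scenario's *discrete* set (continuous angles are
deliberately not used), translation within ±2% of width/height, isotropic
scale in [0.95, 1.05] (anisotropy would distort anatomy, contradicting the
framework's premise), brightness and contrast within ±10%, noise variance
within [10, 50] on the 8-bit scale. Exceeding these bounds requires an
explicit `non_clinical` flag. Geometric augmentation is applied first,
photometric second, so noise is never warped.

Brightness/contrast use `out = clip((in − 0.5)(1 + c) + 0.5 + b, 0, 1)`:
mid-grey is the contrast pivot and a fixed point, and `b = c = 0` is the
identity. The choice of an additive brightness and multiplicative contrast
about 0.5 is a declared convention, not a derived one. Gaussian noise
variance is specified on the 8-bit scale because values of 10–50 only make
sense there (σ ≈ 3.2–7.1 grey levels); unit-scale images receive σ/255.
Outputs are clipped to [0, 1] after noise; the small clipping bias near the
intensity extremes is accepted.

Determinism: every sampled quantity comes from a seeded integer-state
generator. Each source image gets its own substream seeded by
`(run_seed, crc32(stem))`, so re-running — in any order, or on a subset —
reproduces label files byte-identically. The per-output manifest (CSV of
all sampled parameters) exists because reproducibility is otherwise
untestable.

The class-balance planner is plain arithmetic — per folder,
`augmented = original × multiplier`, `final = original + augmented`, plus a
totals row — shipped because rebalancing rare-abnormality folders with
higher multipliers is how the augmentation budget is allocated in practice.

## Evaluation metrics

Metrics are instance-level (detection style): a prediction is a polygon
with a confidence, and overlap is mask IoU — both polygons rasterized at
image resolution, intersection over union of pixel counts. Matching is
class-wise greedy in descending confidence; a detection is a true positive
iff its best-IoU still-unmatched same-class ground truth reaches the
threshold, and each ground truth matches at most once. Precision, recall
and F1 = 2PR/(P+R) follow from the counts, with conventions: P := 0 when
there are no predictions but ground truth exists, R := 0 with ground truth
and no true positives, and a class absent from both sides is excluded from
class means. (Published tables in this area sometimes report P = 1 with
R = 0 for a class with no predictions — an artifact of training-tool
threshold selection that this package does not replicate.) AP uses
101-point interpolation of the precision–recall curve (COCO style, declared
so numbers are reproducible); mAP@0.5:0.95 averages AP over IoU thresholds
0.50–0.95 in 0.05 steps and then over classes present in ground truth. The
aggregate `all` row is the macro average over classes.

## Statistical comparison

Model configurations are compared per metric with the tie-corrected
Kruskal–Wallis test: pool all N values, average-rank with ties, and

    H = [ 12/(N(N+1)) Σ Rᵢ²/nᵢ − 3(N+1) ] / C,
    C = 1 − Σ(t³−t)/(N³−N),

with p from the χ² survival function at k−1 df. Each model contributes one
value per table row — the eight abnormality classes *plus* the aggregate
`all` row, nine observations per model. That observation unit was
established by exact reproduction of the published omnibus statistics
(H = 14.874111 for precision, 2.231198 for recall): an eight-row
computation yields ≈ 11.88 and does not match. A fully degenerate input
(every value identical, C = 0) returns H = 0, p = 1 with a warning.

The post hoc is the *block-rank* Nemenyi: rank the k models within each row
(average ranks on ties), take mean ranks R̄ⱼ, and for each pair refer
q = |R̄ᵢ − R̄ⱼ| / √(k(k+1)/(6n)) to the studentized-range distribution,
p = P(Q_{k,∞} > q·√2), computed numerically via scipy. This Friedman-aligned
variant — not the rank-sum Nemenyi that "post hoc after Kruskal–Wallis"
would literally suggest — is the one that reproduces all six published
pairwise p-values for the precision grid (0.005602, 0.013806, 0.992827,
0.635254, 0.797991, 0.153177); the rank-sum variant (pooled global ranks,
tie-corrected variance) is available behind a flag for comparison. Both the
inclusion of the `all` row and the block-rank choice are inferences
recovered by matching the printed statistics; the code paths to verify them
are the package's own tests.

One caveat the tests surface honestly: the published F1 grid does not
reproduce the published F1 omnibus statistic. The bundled F1 table yields
H = 0.811856 (p = 0.846629), while the published value is 0.932251
(p = 0.817639 — internally consistent with each other, so the original
computation evidently used an F1 grid differing slightly from the printed
one; exhaustive single- and two-cell perturbation searches, including
harmonic-mean recomputations, find no printed-table variant that matches).
The package reports the value computed from the table it ships. Precision,
recall and both mAP grids reproduce their published statistics exactly, and
the F1 values for the three internally consistent model columns are exactly
the harmonic means of the printed precision and recall.

## Phantom generator

Phantoms emulate the structural features the pipeline assumes: an 800×800
8-bit frame; a bright soft-tissue background (185 grey levels) with mild
smoothed Gaussian texture; two darker elliptical lung fields (−70 grey
levels, semi-axes 0.16 × 0.28 of the frame, centered at 0.32/0.68 × 0.45);
and 0–4 lesions per image. Each lesion is a convex-ish star polygon (8–16
vertices, radial perturbation ±30%) rescaled so its shoelace area hits a
target drawn from 500–20 000 px², centered at most 60% of the way from a
lung center to its border so lesions stay inside plausible anatomy and the
frame. Lesions are rendered as soft additive intensity perturbations (±35
grey levels, Gaussian-feathered) rather than replacements, so photometric
augmentation remains meaningful on them. Annotations are the exact
generating polygons — ground truth is known by construction, which is what
makes phantoms usable for alignment and metric tests.

Class frequencies default to an imbalanced preset proportional to a curated
clinical training distribution (common classes ≈ 20–26% of labels —
Fibrosis, Nodule; rare ones ≈ 1–5% — Atelectasis, Pneumothorax).

What phantoms do *not* model: ribs, heart shadow, devices, acquisition
physics, inter-annotator variability, or co-occurrence structure between
classes. Tests passing on phantoms therefore demonstrate geometric and
statistical correctness of the pipeline, not segmentation difficulty or
model performance on real radiographs.

## Problem sizes and tolerances in the test suite

The suite exercises the alignment contract on 100 seeded phantoms (one
scenario transform each), label round-trips on 1000 random annotations,
sampling bounds on 10⁴ draws, and noise statistics on 10⁶ pixels; the
statistical reproductions run on the 9×4 reference grids. Numeric
tolerances: 1e-12 for closed-form linear algebra, 1e-9 for point
transforms, 1e-6 for serialized coordinates and shoelace-vs-determinant
area identities, 1e-4/1e-3 for the reproduced H and p statistics, 0.02 mean
absolute intensity error for four composed quarter-turn warps, and 0.95
IoU for mask–polygon alignment.

## Known limitations

- Mask–polygon alignment degrades for very small regions (area ≲ 500 px²),
  where boundary discretization dominates; the 0.95 IoU contract is stated
  for regions above that size.
- The rasterization-based IoU is resolution-dependent by design; polygon
  (vector) IoU would differ in the third decimal for small regions.
- The rank-sum Nemenyi variant is provided for completeness but has no
  published reference values here to validate against.
- The pipeline handles single polygons per region; donut-shaped (holed)
  regions are out of scope, as are elastic or perspective transforms.
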