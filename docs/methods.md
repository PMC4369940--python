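# Methods

This note documents what `colonseg` computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the synthetic
phantom does and does not establish about clinical data.

## Scope and assumptions

The pipeline targets axial abdominal CT stacks, nominally 512 × 512 pixels
per slice at 16-bit unsigned depth. All intensity logic is defined on that
16-bit scale; DICOM rescale slope/intercept are applied on read and the
result is shifted and clipped into [0, 65535] with the transform recorded
on the volume. Coordinates are 0-based (row, col) internally; the 1-based
border-row convention of the row-stripping stage is converted at that one
call site.

Core assumptions, in pipeline order:

* air is the dark intensity class and is well separated from soft tissue,
  so a per-slice Otsu threshold isolates it;
* lungs appear only on the early slices, where the number of connected air
  regions *L* is small and the lung components are the largest by area;
* the colon lumen is continuous from slice to slice, while small-bowel air
  is not — the basis of XOR slice-difference removal (SLDR);
* opacified fluid and bone share the high-intensity band, and only fluid
  sits under a partial-volume (P/M) boundary band that is itself under
  air — the basis of fluid extraction.

## Intensity categories and window labeling

Per-pixel categories on the 16-bit scale: A = [0, 10000), P/M =
[30000, 55000), M = [10000, 55000), HI = [55000, 63000). `categorize`
returns every category containing a value (the M and P/M ranges overlap by
construction), and HI is extended above 63000 so saturated bone still
reads as high intensity.

Because M is a superset of P/M, a literal union of per-pixel category sets
can never present P/M without M, which would make the enumerated window
rules unsatisfiable. Window labeling therefore uses disjoint per-pixel
classes: a pixel is *M-evidence* only when nothing but muscle can explain
it (10000–30000); 30000–55000 is P/M evidence; ≥ 55000 is HI. A window is
an active region for extraction iff its presence set is exactly {A},
{A, P/M} or {A, P/M, HI}; all other combinations (muscle evidence, HI
alone, P/M alone, air with muscle, …) are inactive. A configuration switch
(`pm_with_air_active=False`) selects the stricter variant in which air
with P/M but no high intensity is also inactive.

## The cascade network

Architecture: input → one hidden layer of 64 logistic units → one logistic
output, plus a direct input → output connection (each layer receives the
input as well as the preceding layer) and biases everywhere. Features per
8 × 8 window: the four presence indicators, min/max/mean/sd of intensity
normalized to [0, 1], and the window center as (row, col) fractions — ten
inputs. The window size matches the 8 × 8 block geometry of the cleanup
stage. The decision threshold on the output is 0.5, the midpoint of the
logistic.

Training minimizes MSE + λ·mean(w²) over the weights (biases are not
penalized), the fixed-hyperparameter form of Bayesian regularization, by
full-batch backpropagation with adaptive-moment gradient steps
(β₁ = 0.9, β₂ = 0.999). Defaults: λ = 10⁻³, learning rate 0.02, at most
1500 epochs (600 in the test/acceptance workloads, which converge well
before that), stopping at MSE < 10⁻⁴. Weights initialize uniformly in
[−0.5, 0.5] from the seed; training is deterministic given the seed.
Quality is tracked by the final MSE and the regression coefficient R
between outputs and targets.

Two supervision routes exist:

* **Rule targets** (default of `build_training_set`): windows labeled by
  the category rules above. The rules are a deterministic function of the
  indicator features, so a trained network reproduces them almost exactly
  (held-out accuracy > 99%, R ≈ 1.0).
* **Ground-truth correlation** (`truth=` argument): windows labeled active
  iff they overlap a supplied mask — here, the union of air-filled
  anatomy, fluid and boundary band; training windows restricted to the
  body. This is the supervision the segmentation demo and end-to-end tests
  use, because the enumerated rules classify every window that mixes air
  and muscle — i.e. every lumen-edge window — as inactive, which quantizes
  lumen boundaries away at window resolution. Ground-truth correlation
  labels edge windows active and lets the D₀ ∧ D₁ conjunction recover the
  boundary at pixel resolution.

## Stage-level choices

* **Otsu**: full 65536-bin histogram by default (the scan is exact);
  ties in the between-class variance break toward the lowest threshold;
  one threshold per slice, not per volume. A constant slice is degenerate:
  the threshold equals the single value and the air mask is empty.
* **Lung removal**: gate at *L* ≤ 18 regions; area cutoff `lung_area_min`
  is configurable with default 2000 px at 512 × 512 — large enough that
  distended-lumen cross-sections survive, small enough that lung sections
  are always removed. The cutoff is absolute area, not relative to body
  area. A slice "contains lungs" downstream iff this stage removed at
  least one component — the only lung signal available later.
* **Boundary tracing**: Moore-Neighbor walks over the 8-neighborhood,
  clockwise from the backtrack, starting at the first raster-order pixel
  of each component with an initial backtrack to its west. The walk is a
  deterministic map on (pixel, backtrack) states; it stops when a state
  repeats (Jacob's criterion — a pixel re-entered from the direction it
  was first entered) and the returned contour is the detected cycle, which
  is always closed. Holes are the 4-connected background regions enclosed
  by a component; each is traced as its own region.
* **D₁**: the paper trail for this branch describes an Otsu binarization
  of the morphologically opened image, with the opening acting on the
  grayscale slice; D₁ is therefore the Otsu-dark class of the
  grayscale-opened slice. (Restricting the histogram to the opened air
  support produces a unimodal air histogram that Otsu would split
  arbitrarily; that variant is not usable.) D₁ may include external air —
  the later AND with the lung-free interior air mask removes it.
* **Tiny-hole removal (threshold 10)**: literal block semantics — any
  8 × 8 block whose total foreground area is below the threshold
  (strictly, by default) is cleared; blocks clip at image edges for
  non-divisible shapes.
* **Post-SLDR cleanup (threshold 35)**: applied to whole 8-connected
  segments rather than to block-local foreground. A block-local area test
  at 35 would erase every boundary block of a genuine colon segment
  (roughly a quarter of a typical lumen cross-section); the stage's
  purpose is to strip small free-standing non-colon remnants, which is an
  area test on segments.
* **SLDR**: compares against the previous slice's *final* mask, giving
  causal forward propagation; threshold 0.5 on the XOR fraction
  (the boundary between "mostly persistent" and "mostly new"); the first
  slice has no reference and passes through, so bowels on slice 0 are not
  removed. A consequence of forward propagation is that losing a segment
  on one slice suppresses it on all later slices.
* **Fluid extraction**: within the network's active region, P/M pixels
  vertically connected to an air-adjacent P/M pixel form boundary-band
  candidates; HI pixels directly beneath a candidate seed the pool, which
  is grown through the 8-connected HI intensity class (the pool interior
  is reached even where its windows were classified as bone-like); band
  pixels connected to the pool are included. Bone is never seeded because
  it does not sit under an air → P/M layering. The final mask is the union
  of colon segments and extracted fluid, hole-filled.

## The phantom

The generator emulates the slice content the pipeline must cope with, not
CT physics: an elliptical soft-tissue body in external air, a bright spine,
two lungs on a configurable early-slice range, `n_colon_segments` elliptical
lumens whose centers drift by a clamped random walk (continuity across
slices is guaranteed), single-slice bowel blobs rejected against the
previous slice's bowels (discontinuity is guaranteed), and, in a
configurable fraction of lumens, a fluid pool below a flat horizontal
air–fluid interface with a partial-volume band of configurable width.

Intensity draws per class (before additive Gaussian noise, default
σ = 600, clipped to the 16-bit range): air-like classes uniform
[2000, 7000]; soft tissue uniform [22000, 40000] — a bounded band
straddling the M/P-M split, whose hard lower edge keeps the air/tissue
histogram cleanly bimodal the way well-separated clinical air/tissue
attenuations are; bone and fluid uniform [57000, 61500]; the band a
vertical ramp across [33000, 52000] ± 800, inside the P/M range. Margins
are ≥ 3.3σ from every class boundary, so at default noise ≥ 99% of each
class stays in its nominal range (100% at σ = 0).

Geometry is expressed as fractions of the slice shape. Lumen semi-axes are
drawn from [0.030, 0.048] of the image size (15–25 px at 512, i.e.
2–4 cm diameter at typical abdominal pixel spacing), which also keeps every
cross-section below the lung-area cutoff. Lumens are clamped inside the
body and kept clear of the spine and lungs — colonic air touching lung air
would merge the regions into one component, which anatomy precludes and
the lung-removal stage cannot undo. Defaults: 20 slices, 3 lumens, lungs
on slices 0–3, fluid fraction 0.5, band width 3 px, one bowel blob per
slice on average.

What passing phantom tests shows: that every stage implements its stated
rule, that the stages compose, and that the pipeline recovers known ground
truth under the phantom's assumptions (clean bimodal histograms, strict
inter-slice colon continuity, strictly discontinuous bowels, flat fluid
interfaces, no collapsed segments). What it does not show: performance on
clinical data — haustral folds, collapsed segments, stool, scanner noise,
metal artifacts and genuinely ambiguous partial-volume mixtures are all
absent.

## Problem sizes

The test suite and the acceptance script run at the sizes the method
defines: full 512 × 512 slices, 8 × 8 windows (4096 per slice), 7 training
slices (28672 window patterns, 20% held out), a 20-slice evaluation
phantom, and 20 speckle masks of 200 components each. Network training is
the dominant cost (tens of seconds on one CPU); everything else is
seconds.

## Known limitations

* The two supervision routes disagree at lumen edges by design; the rule
  route is the specification of the category logic, the correlation route
  is the one that yields full-resolution segmentations.
* SLDR's forward propagation cannot recover a segment once lost, and the
  first slice is never filtered.
* Fluid pools whose interface is not roughly horizontal (patient not
  supine/prone) would defeat the column-layering extraction.
* Segment-granularity specificity requires a population of known
  non-colon segments (the phantom provides bowels and lungs); without it
  true negatives are undefined and reported as not-applicable.
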