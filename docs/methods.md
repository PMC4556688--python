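# Methods

This note documents the models behind `fibrilquant`, the parameter defaults and
why they hold their values, what the synthetic generators do and do not emulate,
and the numerical conventions a user re-analyzing real micrographs or thermograms
should know.

## The measurement problem

A transverse TEM section through corneal stroma shows collagen fibrils as
quasi-circular bright or dark spots. Three numbers summarize the ultrastructure:
the equivalent diameter of the spots, the center-to-center distance from each spot
to its nearest neighbor (interfibrillar spacing), and the areal packing density.
A DSC scan of the same tissue shows a single broad endotherm at the collagen
helix–coil transition; its peak temperature tracks crosslink density and matrix
integrity. Enzyme digestion (collagenase, chondroitinase ABC) degrades all of
these; riboflavin/UVA crosslinking restores some. The package quantifies each
readout and runs the planned group comparisons.

## Segmentation chain

`adaptive_binarize → morphological_open → label_components → filter_by_area →
filter_by_eccentricity`

* **Adaptive threshold.** Foreground iff `intensity − local_mean > offset`, local
  mean over an odd `block_size` square with reflective padding (sign flipped for
  dark-fibril contrast via the `polarity` flag). The local-mean statistic was
  chosen for transparency: it admits an exact brute-force oracle, which the test
  suite exercises pixel-for-pixel.
* **Opening** with a disk structuring element (radius 1 by default) removes
  speckle; it is anti-extensive, so it can only remove foreground.
* **Components** are 8-connected (diagonal contact counts as one cross-section).
  Eccentricity comes from the ellipse with the component's second central moments:
  0 for a disk, →1 for a line. Border-touching components are flagged: their area
  is censored by the frame, so they are excluded from diameter statistics but kept
  for density counting (density counts spots; diameters must be unbiased).
* **Filters.** Area ≥ 50 px² and eccentricity ≤ 0.90 by default.

### Default calibration — and why block 35 / offset 0.10 / opening 1

The defaults were set by a one-off calibration against the synthetic generator at
the nine group settings (diameter 36.4–42.4 nm, density 13.1–25.7 per window,
noise sd 0.05, blur 1 px): the frozen combination gives a mean equivalent-diameter
bias of +0.03 nm with per-setting spread within ±0.6 nm, and exact fibril-count
recovery. Two interactions found during calibration are worth knowing:

* A small offset (e.g. 0.01) puts the threshold far below the blurred edge
  half-level, inflating every diameter by several nm; the offset must sit roughly
  at `(half-level − local background)`, which depends on block size and local
  packing. Recalibrate `offset` if your contrast differs from the renderer's
  0.25/0.75 background/foreground.
* An opening radius of 2 px erodes noisy boundaries erratically (opening removes
  protrusions but cannot refill indentations), producing scene-to-scene diameter
  scatter; radius 1 is stable at the default noise level.
* The area guard (50 px²) is about a quarter of the smallest plausible fibril
  cross-section (~30 nm → ~170 px² at 2 nm/px). Its job is to reject noise blobs
  and the compact fragments left when opening shatters an artifact thinner than
  the structuring element — such fragments otherwise pass the eccentricity filter.
  Rescale it with the calibration.

### Pixel calibration 2.0 nm/px

No calibration can be recovered from a micrograph alone, so it is a required
input for real data. The default used throughout the synthetic world is
2.0 nm/px, chosen for internal consistency of the published summary values: at
that scale a 300×300 px window is 0.36 µm², so 18 spots per window ≈ 50
fibrils/µm², whose expected nearest-neighbor distance (≈ 0.5/√λ ≈ 71 nm) matches
the published ~72 nm spacing at a ~41 nm diameter. At 1 nm/px the same numbers
would force spacings near contact, which the published tables contradict.

## Morphometry conventions

* **Nearest-neighbor distance** is center-to-center (an edge-to-edge variant —
  subtracting both equivalent radii — is available as `nn_mode="edge"`). Output
  order matches input order; two points are required.
* **Window density**: 200 axis-aligned 300×300 px windows drawn uniformly with
  the window fully inside the image; centroid containment on half-open intervals
  `[r, r+w)×[c, c+w)`; the median of the integer counts uses the midpoint
  convention for even window counts. The window is read as 300×300 *pixels*: a
  print-resolution unit (dpi) cannot define an image region. Density is reported
  both as the unitless per-window median (the convention of the published tables)
  and as spots/µm².
* **Sampling caveat**: one 1K image holds only ~11 independent 300 px windows, so
  the median of a single realized pattern fluctuates ~5–10% around
  `density × window area` even with perfect segmentation. Validation therefore
  compares the recovered median against the true-center median under the identical
  window protocol per image, and against the analytic value only in aggregate.

## Thermal analysis

`heat_flow(T)` is corrected by a least-squares line fitted to the first and last
`fit_fraction` (default 10%) of points — with a single transition in mid-scan both
tails are baseline — then smoothed with a 5-point moving average. The transition
is the vertex of a parabola through the global extremum of the *magnitude* of the
corrected signal and its two neighbors, so endotherm-up and endotherm-down file
conventions behave identically; exact ties resolve to the lowest temperature, and
peak maximum (not onset) is the reported statistic. A no-peak error is raised
when the extremum magnitude is under 3× the tail noise of the *unsmoothed*
corrected curve (smoothing shrinks noise by √window and would otherwise defeat
the rule).

The extractor is shift-equivariant in temperature and scale-invariant in heat
flow. Single-curve precision is limited: a 3-point parabola on a ~3 °C-wide peak
sampled at 0.1 °C with 2% noise scatters by ~0.3–0.5 °C per curve, while the
replicate mean is unbiased to < 0.1 °C — matching how transition temperatures are
actually reported (mean ± SD over samples).

## Group statistics

Pooled-variance (Student) two-sided t-tests, as the study design names — Welch is
a flag, not the default. The planned comparison families are: each enzyme-treated
group vs untreated control, and each crosslinked arm vs the non-crosslinked group
with the same enzyme. No multiple-testing correction is applied, as a faithful
reproduction of the original analysis; p-values should be read accordingly.
Swelling reduction is `100·(mean_ref − mean_cmp)/mean_ref` with the conventional
CXL arm as reference; for the control family the same CXL-referenced convention
is used (the alternative — referencing the untreated control — would give ~5%
instead of ~1%; both stay under the published "less than 4%" bound's intent, but
the CXL-referenced reading parallels the enzyme families). Percentages are
rounded half-up only when quoted as integers; raw values are kept in outputs.

## Synthetic world

* **Scenes**: fibril count = round(density × area); diameters from a normal
  truncated at zero (summary tables report mean ± SD only — the minimal faithful
  model); placement by random sequential adsorption under the hard-disk condition
  `‖x_i − x_j‖ ≥ r_i + r_j + gap` (default gap 4 nm), with a 10⁴
  consecutive-rejection cap raising an infeasible-density error. Centers are
  uniform over the whole frame, so disks may clip at the border — exactly the
  censoring real micrographs have, and the only placement rule that leaves the
  point density unbiased for window counting. Artifacts are thick line segments
  ≥ 5 mean diameters long, placed with hard clearance from every fibril so
  ground-truth identity stays unambiguous (their eccentricity ≈ 1 exercises the
  exclusion rule).
* **Rendering**: per-pixel center-distance rasterization at 0.25/0.75 contrast,
  optional Gaussian blur, linear illumination gradient, additive Gaussian noise,
  clipped to [0,1]; default scene size 1024² (the study's cameras were 1K×1K).
  The default validation condition is noise sd 0.05, blur 1 px.
* **Thermograms**: Gaussian peak (default width 3 °C, amplitude 1) on a sloped
  line over 10–95 °C at 0.1 °C steps (a 5 °C/min scan at a typical ~1 s sampling
  period), plus white noise (default 2% of amplitude).
* **Group tables**: per-eye values i.i.d. normal(mean, sd) at the published group
  settings, n = 3 per OCT sub-group.
* All randomness flows from one integer seed per call; equal seeds give
  bit-identical outputs. The pipeline expands its single config seed into
  per-stage sub-seeds via `SeedSequence([seed, stage_index])`.

**Not emulated** — and therefore not established by green tests: D-banding
texture, lamellar organization, keratocytes and tears, spatially correlated
(shot/CCD) noise, fibril ellipticity from oblique sectioning, partial-volume
edge profiles beyond Gaussian blur, multi-peak or asymmetric DSC endotherms, and
any OCT image content (thickness enters only as tables). Recovery results on the
synthetic world bound method error under its stated assumptions, not under every
property of real micrographs.

## Known limitations

* The adaptive-threshold offset is contrast-dependent; real micrographs need a
  short recalibration against manual annotations or the synthetic renderer tuned
  to their histogram.
* Equivalent diameter from thresholded area inherits a rasterization floor of
  ~0.1–0.3 nm at 2 nm/px; sub-pixel accuracy would need edge-model fitting, which
  is out of scope.
* Touching fibrils merge under 8-connectivity (the hard-disk generator never
  produces them; dense real tissue can).
* The t-test layer reproduces the original two-family plan without multiplicity
  control; with 8 planned tests per measure, family-wise error is ~1/3 under the
  global null.
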