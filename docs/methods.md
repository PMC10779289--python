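# Methods

`mitoscreen` quantifies mitochondrial superoxide (mROS), a mitochondrial
membrane-potential proxy, and mitochondrial area per cell from 3-channel
fluorescence images of 96-well plates, and layers plate-level normalization
and screening statistics on top. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The measurement model

Each imaged field carries three co-registered 2-D rasters: a nuclear dye
(405 nm excitation), a mitochondrial dye (640 nm), and a superoxide reporter
(561 nm). The per-cell readouts are

* **mROS signal** — the background-corrected reporter intensity summed over
  the cell's mitochondrial mask (RFU). Summing over the mask and excluding
  everything else is the point of the method: reporter fluorescence that
  does not colocalize with mitochondria (cytosolic oxidation products,
  plate autofluorescence) is excluded by construction.
* **Membrane-potential proxy** — the *mean* mitochondrial-dye intensity over
  the mask (RFU). A mean rather than a sum, so the readout is independent
  of mask area and the two readouts cannot trivially co-vary.
* **Mitochondrial area** — mask pixel count × `pixel_size_um²` (μm²),
  default 0.6 μm/px.

A well's value is the per-cell mean over all its fields (total signal
across cells divided by cells analysed), conditions average replicate
wells, and condition means are reported as percent of a designated control:
`(ratio − 1) × 100` for increases and `(1 − ratio) × 100` for reductions.
Plate-reader mode normalizes raw well fluorescence as
`(raw − mean blank)/protein μg`; viability mode reports luminescence as
percent of the vehicle control.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling →
distance-transform watershed to split touching nuclei → size filter
(≥ 30 px) → exclusion of border-touching nuclei (their mitochondria may be
clipped; configurable). Cell regions: the field foreground (nuclei plus
above-threshold mitochondrial signal, morphologically closed) is partitioned
by a watershed seeded at the nuclei and flooding distance-to-nucleus, so
every foreground pixel joins its nearest cell and the regions exactly
partition the foreground. Mitochondrial masks: thresholding within each
cell region, objects under 4 px removed.

Two numerical choices matter. First, all intensity thresholds are computed
on *log* intensities (with an offset proportional to the value range, which
keeps the label maps exactly invariant under multiplication by a positive
constant). Fluorescence histograms are heavily right-skewed; linear-domain
Otsu inside a cell region lands far above the granule/floor boundary and
erodes the mask, while log-domain Otsu tracks it. Second, the per-cell Otsu
falls back to a global quantile threshold when a region's histogram is
degenerate (flat or nearly empty), so cells with no mitochondrial signal
are retained with an empty mask and measure zero.

## Background correction

Two strategies are implemented because their disagreement is itself a
result the pipeline must reproduce:

* **Sliding parabola** — subtract the grayscale morphological opening with
  a paraboloid structuring element `z(dx,dy) = −c(dx² + dy²)`. The opening
  is computed exactly by the lower-envelope algorithm for parabolic
  min-convolutions, applied separably (rows then columns); because the
  paraboloid is additively separable, the 1-D passes equal the full 2-D
  opening, which the test suite verifies against a brute-force oracle.
  The curvature `c` (intensity/px²) is the single tunable. A paraboloid
  reproduces any quadratic surface exactly in the field interior — but only
  if `c` is at least the curvature of that surface; a flatter element
  undershoots near the borders of a finite field. Larger `c` in turn eats
  roughly `c` intensity units per pixel of narrow structures. The default
  `c = 0.05` covers illumination bowls several times steeper than the
  simulator's default while costing well under 1% of a typical punctum.
  Because a morphological opening rides the *lower* envelope of noise, the
  raw residual retains a positive floor of roughly one noise amplitude
  inside every mask; the pipeline therefore estimates the opening on a
  Gaussian-smoothed copy (σ = 2 px) and subtracts it from the original —
  the same device rolling-ball background subtracters use. The raw
  (unsmoothed) residual remains available (`presmooth_sigma = 0`).
* **Background well** — subtract the mean pixel intensity of empty,
  cell-free wells as a single scalar, clamped at zero. This removes the
  mean illumination level but none of its spatial structure; cells sample
  the field interior (border nuclei are excluded), so a bowl-shaped
  illumination profile leaves a systematic residual in every masked sum and
  biases fold-changes. The acceptance suite demonstrates exactly this
  failure mode against the sliding parabola on identical images.

Correction is applied to the superoxide channel before measurement; the
mitochondrial channel is left uncorrected by default (its readout is a raw
RFU proxy), switchable by flag.

## Synthetic plates

No imaging dataset accompanies the assay, so the generator is the test
bed: it renders fields with known per-pixel ground truth. Nuclei are
super-Gaussian discs (radius 6 ± 0.8 px) rejection-sampled with ≥ 20 px
separation and a 14 px border margin; the mitochondrial network is a sum of
small anisotropic Gaussian kernels (σ 2.2 × 0.9 px, amplitude ~250 RFU,
28 per cell) scattered in an annulus 1.3–2.8 nucleus radii from the
center — granular and perinuclear without modelling true morphology. The
true mitochondrial mask is the texture above a fixed cutoff (40 RFU);
overlapping textures are owned by the stronger cell. The reporter channel
is exactly `s ×` texture on that mask, where `s` is the condition-level
superoxide scale; a nonspecific fraction `f` adds a uniform cytoplasmic
component totalling `f/(1−f)` of each cell's masked signal over a
perinuclear disc excluding the mask, so `f` is the fraction of total
cellular reporter signal outside mitochondria. A parabolic illumination
bowl (base 50, amplitude 150 RFU over the field) plus Poisson shot noise
and Gaussian read noise (σ = 3 RFU) complete the camera model. Channels are
rendered in fixed order before noise, so conditions differing only in `s`
or `f` share identical nuclei and mitochondria channels at the same seed —
which is what makes the null-readout tests exact.

Per-well seeds are spawned deterministically from the master seed;
replicate wells share condition parameters but realize independent noise.
Cell counts per field are Poisson around `n_cells × viability`. Dose series
map dose to `s` through the same 4PL curve the fitting layer estimates.

A deliberate generator choice: with a single condition-independent `f`, the
whole-field (plate-reader emulation) and mitochondria-masked fold-changes
are algebraically equal — both scale with `s`. The observed plate-reader
vs confocal contrast (a large unmasked fold alongside a modest masked one)
requires the stimulated condition to raise cytosolic reporter oxidation
disproportionately, so the effect spec allows a per-condition `f`; the
specificity scenarios use f = 0.5 (basal) vs 0.7 (stimulated).

What the generator does **not** emulate: real mitochondrial morphology and
its remodelling, cell shape heterogeneity and confluency, focus drift,
photobleaching, channel cross-talk, or spatial plate-position effects.
Passing tests show the pipeline recovers known effects under this idealized
but structurally faithful model — not that it is robust to every artifact
of real plates.

## Statistics

Two-group comparisons use the classical pooled-variance Student t-test
(Welch by flag; paired mode available) with the 95% CI of the mean
difference. Dose screens use one-way ANOVA followed by Dunnett's
many-to-one comparisons via the equal-correlation multivariate-t
distribution (scipy's implementation; a seeded generator makes the
numerical integration reproducible). Cohort tables use Pearson's
chi-squared *without* Yates continuity correction — the uncorrected
statistic reproduces the published p-value on the reference 2×2 table, the
corrected one does not. Dose-response curves are fitted as
`y = bottom + (top − bottom)/(1 + (x/IC50)^h)` by least squares in
log10-dose space; standard errors come from the Jacobian at the optimum,
and the IC50's SE from the log-IC50 SE by the delta method. Fits that fail
to converge, or whose Hill-slope sign contradicts the expected direction,
are flagged explicitly. Degenerate inputs are resolved rather than left to
propagate NaNs: identical groups give t = 0, p = 1; a constant paired
shift gives p → 0 with a degenerate CI.

The calibration suite checks the type-I error of the t-test (5000 null
replicates, n = 7/group), the family-wise error of Dunnett's procedure
(2000 replicates, 4 groups), and IC50 recovery under 5% proportional
response noise in triplicate (bias under 5% across 50 replicates). "5%
noise" is modelled as a 5% coefficient of variation on the response, the
usual plate-assay noise scale.

## Problem sizes and determinism

The synthetic recovery scenarios run two conditions × duplicate wells ×
10 fields × ~30 cells per field on 256×256 px fields — large enough that
replicate-well means are stable, small enough that the full suite runs in
minutes on one CPU. Every stochastic element (simulation, Monte-Carlo
calibration, Dunnett integration) is driven by explicit seeds, and
re-running the pipeline on the same inputs reproduces its output tables
byte for byte.

## Known limitations

* Mask-level ground-truth agreement is bounded by geometric ambiguity:
  where perinuclear networks of neighbouring cells interleave, truth
  assigns pixels to the stronger texture while the watershed assigns them
  to the nearer nucleus. Fold-change estimates are insensitive to this,
  per-cell IoU is not.
* The sliding-parabola residual slightly over-subtracts beneath broad
  elevated plateaus (e.g. a strong diffuse cytoplasmic component), since
  the opening climbs onto the plateau; fold-changes remain within the
  tested bounds because the effect is similar across conditions.
* The background-well model subtracts a scalar; it is implemented as the
  comparison baseline it is, not as a recommended correction.
* 4PL standard errors are asymptotic (Jacobian-based); with 7 doses in
  triplicate they are indicative, not exact.
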