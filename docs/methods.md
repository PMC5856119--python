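# Methods

## Problem setting

A VNIR pushbroom camera captures an intraoperative scene as a hypercube:
rows × cols pixels, each carrying a reflectance spectrum over 400–1000 nm.
The system must label every pixel as normal tissue, tumor tissue, blood
vessel / hypervascularized tissue, or background (instruments, drapes,
serum), and present the result as a single RGB map a surgeon can read
during resection. Missing tumor is the costly error; false tumor inside
healthy parenchyma destroys trust in the map. Both concerns shape the
design: a conservative tumor-first tie-break in the voting stage, and a
negative-control test suite on tumor-free scenes.

## Calibration

Raw digital numbers are converted to percent reflectance by
β = 100·(α−δ)/(γ−δ) with white reference γ and dark reference δ. The
references may be a single line (1 × cols × bands) replicated along the
scan axis, matching a pushbroom geometry in which the white tile is
captured where the patient's head will lie. Design choices where the
published chain is silent:

* α < δ (sensor noise) is clipped to 0: downstream normalization assumes
  non-negative spectra.
* β > 100 (specular highlights) is **kept** and flagged, because bright
  pixels must remain classifiable as background rather than being deleted.
* γ = δ (dead reference samples) yields 0 and a per-pixel flag; calibration
  aborts only if the references are degenerate everywhere.

Gain invariance — multiplying the dark-subtracted signal and reference by
any common positive factor leaves β unchanged — is the property that makes
the pipeline robust to illumination amplitude, and is tested exactly.

## Pre-processing chain

The chain is fixed in order: clip → smooth → downsample → normalize.
Defaults (all configurable, never hard-coded into the stages):

| step | default | rationale |
|---|---|---|
| clip | keep 450–900 nm | sensor extremes of a 400–1000 nm axis are noise-dominated |
| smooth | moving average, window 5 bands | removes band-to-band sensor noise without distorting broad tissue features |
| downsample | 128 bands, contiguous means | controls dimensionality; group wavelengths are averaged so the axis stays strictly increasing |
| normalize | per-pixel unit-max | removes illumination amplitude; leaves spectral-angle values unchanged, so SAM labeling commutes with it |

Degenerate spectra (all-zero) pass through normalization unchanged and are
flagged rather than producing NaNs.

## SAM labeling

The spectral angle arccos of the cosine similarity is scale-invariant, so a
single trusted reference pixel grows a class region that tolerates
illumination variation but not shape changes. Selection is monotone in the
threshold (nested masks), the reference pixel is always included, and
all-zero pixels are never selectable. Overwriting a previously assigned
label requires an explicit flag — gold standards are meant to be small sets
of very reliable pixels, and silent overwrites would corrupt them.
Labeling operates on pre-processed spectra by default (a config flag allows
raw-reflectance SAM); the tolerance is an explicit argument, standing in
for the slider of an interactive tool.

## Supervised stage

The pixel classifier is a four-class SVM, linear kernel, C = 1, one-vs-one
with pairwise-coupled Platt probabilities. Linear is the defensible default
for high-dimensional spectra (hundreds of bands, modest training sets);
kernel, C and seed are config. Training rows are canonically sorted (by
label, then lexicographically by spectrum) before fitting so that the model
— including its internal probability-calibration folds — is invariant to
the order training pixels happened to arrive in.

Spatial–spectral homogenization embeds each pixel as
(λ·row/s, λ·col/s, g), where s = max(rows, cols), g is the per-image first
principal component min–max scaled to [0, 1], and λ (default 1) weighs
space against the guide. Each pixel's probability vector becomes the mean
over its K (default 40) nearest neighbours in that space, renormalized.
Limits: λ → ∞ degenerates to a purely spatial mean filter, λ = 0 to a
guide-value-only filter; K = 1 is the identity. PCA is fitted per image,
not on the training set, because the one-band guide must reflect the
incoming scene's own contrast. The sign of the loading vector is fixed
(largest-magnitude entry positive) for reproducibility.

## Unsupervised stage and fusion

Hierarchical K-means is implemented as bisecting K-means: greedily split
the cluster with the largest within-cluster sum of squares using 2-means
with 10 seeded restarts, until K clusters (default 24). This reading gives
a deterministic, testable hierarchy whose total WCSS is non-increasing in
K; clusters of exactly duplicated spectra are split by pixel order only
when nothing with spread remains, keeping all K clusters non-empty.

Fusion counts, per cluster, the filtered argmax labels of its pixels
(hard labels; a config switch averages soft probabilities instead — the
default follows the view that a classification *map* is being fused).
Majority voting breaks exact ties by tumor > vessel > normal > background,
the clinically conservative order. The TMD rendering keeps each cluster's
three largest densities, renormalizes them to sum 1, and paints the cluster
with the corresponding convex combination of class colours; rendered
colours therefore always lie in the convex hull of the palette.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes, in
the raw domain (inverting the calibration relation) so that calibration is
genuinely exercised:

* **Endmembers**: four smooth sum-of-Gaussian reflectance spectra, redrawn
  until all pairs are ≥ 0.15 rad apart in spectral angle — comparable to
  the separation visible between tissue-class signatures after
  pre-processing, while leaving genuine overlap under jitter.
* **Variability**: per-pixel smooth spectral jitter (sd 0.02) for
  intra-subject variation; subject-level smooth multiplicative offsets
  (sd 0.04) for inter-subject variation; both low-dimensional in a smooth
  spectral basis so realizations remain physically smooth.
* **Sensor model**: white level ≈ 3000 DN with a gently curved tile
  spectrum, dark level 96 DN, additive Gaussian noise (sd 8 DN) on the
  scene, 12-bit saturation at 4095 DN; a smooth multiplicative illumination
  field is folded into the white reference, exactly as a flat-field capture
  would see it. Specular pixels (fraction 0.002) saturate all bands and
  calibrate to > 100 % reflectance; dead reference pixels (γ = δ) are
  injectable.
* **Layout**: background ring, normal parenchyma, one elliptical tumor
  blob, two sinuous vessel curves. Truth maps label only region interiors
  (2-pixel erosion; 1 pixel for the thin vessels), mirroring gold standards
  built from a few very reliable pixels; specular pixels are left
  unlabeled.

Default scene size is 128 × 128 pixels with 200 raw bands (128 after the
default chain) — a desk-scale analogue of a clinical capture, chosen so the
full multi-seed experiments run on one CPU in minutes. What the phantom
does **not** model: real tissue optics (absorption/scattering), spatial
texture within a class beyond smooth jitter, shadows, extravasated blood,
or tumor heterogeneity. Passing the end-to-end tests therefore shows the
chain is correct and self-consistent under its stated assumptions, not that
clinical-grade accuracy is guaranteed on real captures — phantom class
structure is cleaner than surgical scenes, and measured agreements near
100 % should be read in that light.

## Experiments the suite runs

* **End-to-end recovery**: over 3 seeds, fused maps agree with phantom
  truth on ≥ 90 % of labeled pixels at default conditions.
* **Negative control**: over 10 tumor-free held-out scenes, no cluster is
  voted tumor.
* **Training-fraction curve**: stratified subsampling at fractions of the
  training set followed by 10-fold CV; the accuracy plateaus, with the
  plateau mean within CV noise of the full-data mean (no overfitting from
  using all samples).
* **Noise monotonicity**: mean pipeline accuracy decreases across three
  increasing sensor-noise levels (5 seeds each).
* **Oracle equivalences**: k-NN filtering vs exhaustive neighbour search;
  bisecting K-means vs the exhaustive 2-partition WCSS optimum; PCA vs the
  closed-form 2 × 2 eigen-decomposition — all to 1e-9. The bisecting
  implementation is additionally cross-checked against an independent
  library implementation on well-separated blobs.

## Numerical conventions and limitations

Indices are 0-based, row-major (row, col, band), origin top-left. ENVI is
the interchange dialect (BSQ default on write; BIL/BIP and both byte orders
on read); the physical-extent helper rounds half-up to whole millimetres.
Band lookup by wavelength takes the nearest band, ties to the lower index.
All stochastic elements (endmember draws, jitter, fold assignment, 2-means
restarts) flow from explicit integer seeds; same seed, same input → byte-
identical outputs. The pipeline runs single-process; the supervised and
unsupervised branches are a logical fork joined at fusion, and per-stage
wall times are logged for each run. Known limitations: no radiometric
calibration to physical units, no NIR-range support, no interactive
labeling GUI, and clustering cost grows with K · pixels — for much larger
scenes the 2-means restart count and K are the knobs to lower.
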