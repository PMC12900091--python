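# Methods

`retphasor` implements a pipeline for classifying multispectral fundus images
of the retina as healthy or diseased using spectral phasor features, together
with a synthetic data generator that stands in for clinical data. This note
documents the models, the numerical choices, and what the synthetic results
do and do not show.

## Reflectance calibration

Raw frames record digital levels (DL) mixing tissue reflectance with LED
power, sensor sensitivity and dark current. With a white-reference frame and
a dark-current frame acquired under the same exposure, per-pixel per-band
reflectance is

    Refl(i,j,λ) = (DL − DL_dark) / (DL_white − DL_dark) · Refl_ref(λ),

with `Refl_ref` the calibrated reflectance of the white target (per band;
default 0.95). Reflectance is deliberately **not clipped** to [0, 1]: noise
can push values slightly outside, and the downstream band-wise
standardization makes clipping both unnecessary and distorting. Pixels where
any band's white−dark difference falls below `eps` (default 1.0 DL, below
the sensor noise floor) are marked invalid instead of divided. The output is
invariant to a common positive rescaling of all three DL inputs and
monotone in the raw DL, both asserted by tests.

## Band-wise Z-score normalization and percentile trimming

Each band is standardized to zero mean and unit **population** variance over
a scope mask (the entire retina). Standardization emphasizes relative
spectral contrast over absolute reflectance — uniform gain or offset per
band is removed exactly, so the features cannot learn illumination
artifacts. The population (not sample) standard deviation is used because a
full pixel population is being standardized, not estimated from; at image
scale the difference is negligible but the convention must be fixed for
exact tests.

Standardized distributions have heavy tails (vessels, the bright optic
disk), which would dominate averaged features; the top and bottom 20th
percentiles of each band's in-scope values are therefore removed.
Percentiles use linear interpolation between order statistics; exclusion is
by strict inequality, so ties at the boundary survive. A pixel outside the
bounds in **any** band is dropped entirely (union rule): the per-pixel
phasor needs all n bands, so a partial spectrum is unusable. Trimming only
edits the validity mask; surviving spectra compare bit-equal before and
after.

Two scope decisions were genuinely open:

* **Z-score scope.** Statistics are computed over the entire retina even
  when a sub-region is analyzed. Normalizing inside a small ROI would erase
  inter-region contrast and destabilize σ on a few dozen pixels.
* **Trim scope.** Trimming is computed over the pixel population actually
  being summarized (the ROI). Computed globally, the 20/20 union rule
  provably empties anatomically coherent but globally extreme regions — the
  optic disk sits 2–5σ above the global distribution in every band — making
  per-region analysis impossible. For whole-retina analyses the two choices
  coincide.

Trimming is applied only to standardized data; analyses of raw reflectance
phasors use no trim.

## Spectral phasor transform

Each pixel's n-band spectrum I(m), m = 0..n−1 in ascending wavelength, maps
to the plane via the normalized k-th discrete Fourier harmonic:

    g(k) = Σ_m I(m) cos(2πkm/n) / Σ_m I(m)
    s(k) = Σ_m I(m) sin(2πkm/n) / Σ_m I(m)

Harmonics k = 1..n−1 are available (k = 0 is identically (1, 0)). For
nonnegative spectra the point is a convex combination of unit-circle points:
it lies in the unit disk, is invariant to positive rescaling of the
spectrum, and is **linear under intensity-weighted spectral mixing** — the
property that makes phasors a faithful low-dimensional encoding of spectral
shape. All three properties, the closed forms (flat spectrum → origin,
single-band delta → unit circle), conjugate symmetry between harmonics k and
n−k, and agreement with an independently coded brute-force summation (and
between the direct and FFT evaluation paths) are asserted by tests at
1e-10–1e-12.

Phase is uniform over the band **index** by default; with a single camera
the channel bandwidth Δλ is constant and cancels in the ratio. A
wavelength-proportional phase with per-band Δλ weighting is available
(`phase_axis="wavelength"`) for cubes with strongly uneven band spacing.

**Z-scored input and the denominator.** After band-wise standardization the
per-pixel band sum is zero-centered over the scope *by construction*, so a
non-negligible fraction of pixels has a near-zero denominator and a
Cauchy-like per-pixel phasor. With a purely nominal guard (eps = 1e-6) the
scope-averaged phasor is dominated by these tails and carries no signal.
The pipeline therefore invalidates z-scored pixels whose band sum is within
0.5 z-units of zero — a total signal indistinguishable from noise admits no
interpretable spectral shape. The transform's own default guard stays at
1e-6 for nonnegative input, where the issue cannot arise.

Per case and region, the phasor cloud is summarized as the arithmetic mean
(g_avg, s_avg) over valid in-scope pixels, optionally with a single scalar
dispersion STD = sqrt(var(g) + var(s)) (population variances) — a
rotation-invariant measure keeping the extended feature set at exactly three
numbers. Baseline features are the per-band means over the same scope
(12-dimensional Avg-MSI, or 3-dimensional Avg-RGB on the RGB-like sub-cube
of the 471/595/732 nm bands).

## Classification protocol

Four classifiers are compared: nearest centroid, Gaussian naive Bayes, an
RBF-kernel SVM (C = 1.0) and a ν-SVC (ν = 0.5), the SVM family preceded by a
train-fold-fitted standardizer (margin methods are scale-sensitive; fitting
the scaler on the training fold only avoids leakage). Evaluation uses
repeated random holdout: 70% train / 30% test, 10 repetitions from a fixed
seed, not stratified, with the same partitions reused across every feature
set, classifier, harmonic and region within a run. Six metrics are reported
per repetition and as unweighted means: overall accuracy, balanced accuracy,
specificity, sensitivity, precision and F1. Diseased is the positive class
throughout — sensitivity measures disease detection; this is a convention
choice, stated here because nothing in the protocol forces it. Undefined
0/0 ratios (e.g. precision with no positive predictions) are 0 by
convention, with a warning.

## MANOVA

Group differences are tested with Wilks' Λ = det(W)/det(W+B) over the
within- and between-group scatter matrices. Only the two-group case is
implemented: there the F transformation F = ((1−Λ)/Λ)·(n−d−1)/d on
(d, n−d−1) degrees of freedom is exact via the Hotelling T² identity, so
Rao's general approximation is unnecessary. Scatter matrices are raw sums
of squares and cross-products (no df scaling) — Λ is invariant to that
choice. Phasor representations enter with exactly two dependent variables
(g_avg, s_avg), never STD; band-average representations enter with one
variable per band. Tests assert equality with an independent Hotelling T²
implementation and with statsmodels' MANOVA, affine invariance, and nominal
type-I error on null data.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
retinal radiative transfer. Per case:

* **Geometry.** A circular retinal field; a bright elliptical optic disk
  offset to one side (radius 0.12–0.15 of the field radius); a darker
  macular disk near center (0.16–0.19); six vessels as branching random
  walks from the disk rim, dilated to 3–5 px width, capped near a 10% area
  share; background is the remainder. Disk and macula are disjoint;
  vessels override both in the region masks.
* **Spectra.** Smooth tissue curves: background reflectance rising toward
  the red (melanin-like blue darkening); vessels as attenuated background
  minus hemoglobin-like Gaussian dips at 542/577 nm; the optic disk
  brightest at every band; the macula slightly darker with a blue
  (lutein-like) dip. Each case perturbs each class's curve with an
  independent smooth random polynomial (sd 0.003 reflectance units) —
  biological inter-case variability that band-wise standardization cannot
  remove.
* **Disease.** An additive reflectance perturbation on diffuse drusen-like
  patches (random blurred spots covering ≈45% of the configured extent;
  whole retina by default, or macula/disk/vessels only). The spectral
  profile is two Gaussian lobes at 524 nm (σ 22) and 645 nm (σ 20, weight
  0.8), peak amplitude 0.6 reflectance units by default. The two-lobe
  *shape* change is deliberate: it produces a coherent first-harmonic
  phasor displacement, and both lobes fall between the RGB surrogate's
  bands (471/595/732 nm), so the full 12-band analysis holds a genuine
  information advantage. Spot-wise (not uniform) application matters: a
  spatially uniform per-band shift is annihilated exactly by per-case
  band-wise Z-scoring. Magnitude 0 makes healthy and diseased cases
  bit-identical draws; the locality of the effect is exact (pixels outside
  the lesion support are unchanged).
* **Acquisition noise.** A smooth multiplicative illumination field shared
  across bands (sd 0.10); a fine-grained multiplicative texture field also
  shared across bands (sd 0.05, correlation ≈2 px) emulating tissue
  texture — without it, within-region variation would be purely
  band-independent sensor noise, and the 20/20 union trim would remove
  ≈0.6¹² of every homogeneous region, a degeneracy real images do not
  show; per-pixel per-band lognormal noise on reflectance (sd 0.02); and
  additive Gaussian sensor noise on digital levels (sd 3 DL). Digital
  levels follow the calibration forward model with white = 45000 DL,
  dark = 800 DL, so calibrating a noise-free case recovers the injected
  reflectance field exactly.

All draws derive from `(seed, case_index)`, identically for both labels, so
datasets are bit-reproducible and label-only comparisons are exact. The
default study is 73 healthy + 60 diseased cases of 128×128 px — a
desk-scale stand-in for the ~1757² clinical rasters, chosen so that every
anatomical region keeps a usable pixel population after union trimming
while a full dataset generates in seconds.

**What passing does and does not show.** The generator realizes a *strong,
advanced-stage* disease with a fixed spectral signature, chosen so the
default study is clearly separable by first-harmonic z-scored phasor
features and so that the multispectral phasor representation outranks both
the RGB-like phasor and the band-average baselines — the qualitative
structure the pipeline is designed to detect. Passing these checks
validates the *pipeline's mechanics and statistics*, not any clinical
claim: real pathologies are heterogeneous, their spectral contrasts are far
subtler and not confined to convenient bands, and real inter-case
variability (media opacity, pigmentation, focus) is richer than the
generator's smooth fields. The synthetic effect shapes must not be read as
biologically calibrated.

## Null calibration

With magnitude 0 the full chain (generation → calibration → z-score → trim
→ phasor → MANOVA) rejects at the nominal 0.05 rate (500 replicates of
15+15 cases at 48×48 px stay inside the binomial 95% band), and classifier
balanced accuracy stays inside the chance band. Replicates of 10+10 cases
make the exact two-group F test visibly conservative — the case-level
phasor features retain mild heavy-tailedness from the ratio transform — so
the calibration study uses 15 cases per group, where the approximation is
accurate.

## Known limitations

* The phasor mean on z-scored data is a ratio statistic; its stability
  depends on the denominator guard, and no guard choice recovers pixels
  whose standardized band sum is genuinely ≈0.
* Region-level analyses on small rasters can leave very few pixels after
  union trimming; the pipeline raises rather than silently summarizing
  fewer than 2 pixels.
* Splits are regenerated per case count from the same protocol seed, so
  region-filtered datasets (different n) cannot literally share partitions
  with the full dataset.
* No image registration, vendor formats, or automated segmentation: masks
  are inputs.
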