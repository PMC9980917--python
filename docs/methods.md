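# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the validation experiments do and do not demonstrate.

## Image-analysis chain

**Registration.** The two staining rounds of one core differ by a planar
translation (same scanner, restained slide); rotation and scale are not
modelled. The shift is estimated by spectral cross-correlation of the shared
DAPI channels with 1/20-px subpixel refinement. The *unnormalized*
cross-correlation variant is used deliberately: spectral whitening ("phase"
normalization) is unreliable on smooth, low-texture images. The quality
score is the Pearson correlation of the two DAPI images after alignment; a
core scoring below `min_score` (default 0.5 — a package decision, chosen so
that unrelated textures fail and correctly aligned cores pass with a wide
margin) keeps its round-1 measurements but has its SMA fraction recorded as
missing. Out-of-view pixels after alignment are filled with the channel
median and flagged in a validity mask.

**Otsu primitive.** Thresholds are computed on the sample's exact discrete
values (256-bin compression only for continuous data with more than 256
distinct values) by maximizing between-class variance with cumulative
moments; ties resolve to the lowest cut, and the returned threshold is the
midpoint between the optimal level and the next distinct level, making the
operator exactly shift-equivariant on integer data. Tests compare it against
an explicit exhaustive-search oracle.

**Adaptive Otsu.** Per-block thresholds (block 128 px at the 1024-px
reference size, scaled proportionally for smaller renders) bilinearly
interpolated to a full-resolution threshold map. A block threshold is
accepted only if its between-class/total variance ratio is at least 0.8 —
blocks lying entirely inside one compartment are unimodal (ratio ≈ 0.64 for
a Gaussian, 0.75 for a uniform), and a local Otsu there would split the
signal itself; such blocks fall back to the global threshold. Accepted
block thresholds are clamped to [0.7, 1.5]× the global threshold so a block
whose two modes are both background (glass vs unstained tissue) cannot drag
the map below the stain level.

**Tissue.** Channels are scaled by their 99.9th percentile, clipped to
[0, 1], summed, log-compressed (`log1p(5·sum)`), smoothed (σ = 2 px) and
globally Otsu-thresholded. The log compression is essential on realistic
trimodal sums: without it the dominant variance gap is bright-stain versus
everything, and Otsu would return only the stained pixels as "tissue".
Holes smaller than the minimum lumen area are filled; larger holes (gland
lumens, which are optically empty) are retained, so tissue = epithelium ∪
stroma exactly and lumen area is reported relative to tissue area.

**Epithelium, stroma, lumen.** Epithelium is the adaptive-Otsu level set of
PanEpi inside tissue, converted to connected gland objects with area ≥ 500 px
(≈ 31 µm² at 0.25 µm/px; scaled quadratically for smaller renders); stroma
is tissue minus epithelium (disjoint by construction); lumens are the
enclosed holes of the epithelial mask (`fill_holes(epi) ∧ ¬epi`) with area
≥ 100 px.

**Nuclei.** Adaptive Otsu of DAPI, guarded by the same effectiveness
criterion at the image level (a blank-plus-noise DAPI image yields zero
nuclei instead of a half-split of the noise), distance-transform watershed
with peaks ≥ 5 px apart to split touching nuclei, and an equivalent-diameter
filter of 5–30 px. Whether the original interactive pipelines declumped
touching nuclei is typically unstated; watershed splitting is this package's
choice.

**Marker positivity.** Otsu computed per core on the stroma-restricted
intensities (per-core rather than per-slide thresholds — a package choice).
The threshold is floored at `p25 + 4·(p25 − p5)` of the stromal intensities,
a robust upper bound on the background spread valid whenever at least a
quarter of the stroma is unstained (true for all markers here; SMA, the most
abundant, peaks near 60%). Without the floor, a marker channel containing
only background noise would be Otsu-split in half and read as ~50% positive;
with it, a pure-background channel reports < 0.5% positivity while a genuine
0.3% FAP signal (the benign-tissue level) is still detected, because its
Otsu threshold sits far above the floor.

## Brightfield path

The chromogenic FAP/SMA classifier is a random forest (60 trees,
seed-deterministic) over per-pixel features: raw RGB, the three
color-deconvolution channels (hematoxylin / red / DAB optical densities),
and Gaussian-smoothed intensity plus gradient magnitude at σ = 1, 2, 4 px.
Classes are fixed: empty, FAP⁺, SMA⁺, other tissue — the last absorbing
hematoxylin and faint background without sub-segmentation. FAP and SMA
fractions are normalized by total tissue pixels (everything not "empty"):
this modality has no epithelial costain, so no epithelium/stroma split
exists and its FAP fraction is systematically smaller than the
stroma-normalized fluorescence fraction; the two are compared by
correlation, never by identity. A quarter of the scribble pixels are held
out for the reported training accuracy.

## Synthetic data

**Cores.** A circular tissue disk (radius 0.47 × image side) at
0.25 µm/px. Epithelial glands are upper level sets of a smoothed Gaussian
random field (σ = side/16); holes of the raw level set are filled and the
level rank re-found by bisection so the only enclosed holes are the lumens
carved deliberately (from a finer field, inside a 3-px erosion of the
glands, so every lumen is a genuinely enclosed hole that fill-and-subtract
can find). Level sets are taken by exact pixel rank, so rendered masks hit
the requested area fractions to within a pixel and the stored ground truth
is an exact recount of the emitted masks. Nuclei are non-touching 8-px
disks placed by rejection sampling; markers are level sets of per-marker
fields (fine-grained for CD8/CD163, coarser for FAP patches, large smooth
regions for SMA) restricted to stroma. Intensities: glass 4, tissue
autofluorescence 30, stain median 150 with lognormal spread (log-SD 0.15),
additive Gaussian noise (SD 5 by default), all on the 8-bit scale. Round 2
is rendered in the round-1 frame and translated by the true shift before
noise is added.

Class-conditional defaults encode the published medians where printed
(SMA 59.7 / 55.9 / 41.3%, FAP 0.3 / 1.4 / 3.1%, CD163 1.4 / 2.5 / 3.1%,
CD8 0.8 / 1.4 / 1.5% of stroma for benign / MRI-negative / MRI-positive;
lumen 9.7 / 8.4 / 7.6% of tissue) and the published ordering at plausible
levels where only the ordering is known (epithelium 0.35 / 0.37 / 0.48,
nuclei 0.14 / 0.15 / 0.20). Dispersions are not published and are free
parameters of the generator, not calibrated claims.

**Cohorts.** Marker fractions follow a Gaussian copula whose latent
correlations are back-transformed from the target Spearman values
(r = 2 sin(πρ/6); defaults ρ = 0.44 FAP–CD8, 0.43 FAP–CD163, −0.30
FAP–SMA), with lognormal marginals around the class medians (log-SD 1.4 for
FAP — heavy-tailed so that roughly the top decile of patients exceeds a 20%
fraction while the median sits near 3%, matching the published patient
histogram shape — and 0.8 for CD8/CD163) and a logit-normal marginal for
SMA. Event times are exponential proportional hazards with linear predictor
β_FAP·FAP + β_SMA·SMA on the MRI-positive lesion values (continuous, or
median / top-decile indicators via `hazard_form`); the default per-unit
log-hazards 100·ln(1.04) and 100·ln(0.96) restate the published continuous
per-percentage-point hazard ratios. The exponential (constant-hazard)
baseline is the simplest PH-consistent choice; no published claim
identifies the hazard shape. Censoring is independent exponential truncated
at 60 months. PTEN loss and ERG positivity are drawn with the
FAP-/SMA-linked prevalences implied by the published 2×2 counts, so the
cross-tabulation machinery sees realistic dependence. A `time_varying`
switch generates crossing hazards (effect reverses a quarter into
follow-up) to give the Schoenfeld test something to detect.

**What the generator does not emulate:** optics (PSF, chromatic shifts),
autofluorescence spectra, 9-tile stitching, staining-batch effects,
nonrigid tissue deformation between rounds, and spatial covariance between
markers beyond class-level correlation. Passing tests therefore demonstrate
the correctness and calibration of the computational chain, not the
field performance of the thresholds on real tissue.

## Statistics layer

Normality gating uses the Lilliefors form of the KS test (mean and SD are
estimated); samples under 10 observations go to the rank test directly since
the normality test has no power there. Fisher's exact test is applied to
2×2 tables (per config or when an expected cell is below 5; the published
association table is reproduced with Fisher forced for its 2×2 strata, χ²
for the 5-level grade table). Dichotomization cuts are strict (>); decile
rules mark exactly round(n/10) patients with stable tie order. The
univariable screen uses a vectorized Newton fit of the single-covariate Cox
partial likelihood (Breslow ties — the screen operates on continuous
simulated times where ties are absent and Breslow coincides with Efron),
cross-checked against the reference implementation in tests; multivariable
fits, Kaplan–Meier, log-rank and the Schoenfeld test (rank time transform)
are backed by lifelines with Efron ties. Bonferroni correction uses a
family size of 53 by default — the full clinical + image-variable screen
run as one family. The DeLong test is implemented from placement values
(midranks), with the AUC = U/(n₁n₀) identity as its test oracle;
zero-variance ΔAUC (identical scores) returns p = 1.

## Validation experiment sizes

Synthetic cores for tests and validation are rendered at 256 px (192 px for
the pipeline demo) with thresholds scaled from the 1024-px reference
geometry; the 50-core segmentation sweep spans all three lesion classes
with random inter-round shifts up to ±12 px. Survival operating
characteristics use 200 replicates (CI coverage at HR 2.75, n = 300;
log-rank power at HR 4.48, 10% prevalence, n = 280; 53-variable null
screen) or 500 replicates (Schoenfeld and DeLong type-I error), with the
calibration cohorts using a baseline hazard of 0.006/month and censoring at
0.004/month over 60 months (≈ 25% events). The modality-concordance
experiment renders 50 paired cores spanning FAP fractions 0–0.25.

## Known limitations

* Per-core marker thresholds assume each core contains enough unstained
  stroma to estimate background; a core saturated with one marker (> ~75%
  positive) would bias its own threshold.
* The brightfield classifier is validated only on synthetic stain colors;
  real chromogen spectra vary and would require retraining from scribbles.
* The registration model is translation-only; real restaining occasionally
  introduces small rotations that would degrade the correlation score and
  be (correctly) flagged as failures rather than corrected.
* Replicate-core aggregation averages fractions rather than re-pooling
  pixel counts; with unequal core areas the two differ slightly.
* The Cox screen's fast path flags separation by a step-size guard rather
  than a formal monotone-likelihood diagnostic.
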