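# Methods

## Problem and data model

The package analyzes MALDI mass spectrometry imaging (MSI) of on-slide
tryptic digests: one profile spectrum per 50 µm pixel over the tryptic
peptide window m/z 800–3200, acquired from 1–7 tissue-microarray cores per
patient.  Regions of interest (ROIs, tumor-cell-rich areas) carry binary
prognostic labels per patient: lymphatic vessel invasion (pL), nodal
metastasis (pN), angioinvasion (pV).  The goal is a per-feature *peptide
signature*: aligned m/z values whose pixel intensities discriminate
feature-positive from feature-negative tissue, cross-annotated to proteins
through an LC-MS/MS reference peptide list.

## Pipeline stages and parameters

**Baseline removal** (`preprocess.remove_baseline`, `width=20` points).
"Convolution baseline removal" as shipped in commercial MSI software is
unpublished; we use the standard construction that matches its behavior on
TOF profiles: a running-minimum filter of half-width `width` data points
followed by convolution with a Gaussian kernel (σ = width/2 points), reflect
padding, result clipped at zero.  `width` is in data points, not Da: at the
generator's 0.05 Da axis step the filter window spans ~2 Da, an order of
magnitude wider than a peptide peak (σ ≈ 0.1 Da), so peaks survive while
drift is removed.  The estimator is idempotent to within 1% of the maximum.

**TIC normalization** (`preprocess.tic_normalize`).  Unit-sum scaling.  Any
common rescaling (e.g. mean-TIC) gives identical downstream results because
AUC and the rank-sum test depend only on within-feature ranks; unit sum is
the simplest canonical choice.  All-zero pixels raise rather than silently
propagating NaNs.

**Peak selection** (`peakalign.pick_peaks_omp`).  Greedy orthogonal matching
pursuit on the dataset mean spectrum over a dictionary of Gaussian atoms
(σ configurable, default 0.1 Da — the simulated instrument width) centered
on axis points.  Each step selects the atom most correlated with the
residual, jointly refits all selected amplitudes by least squares, and
subtracts; the residual norm is therefore non-increasing, which the tests
assert.  Stopping: `max_peaks`, or fitted height < `min_rel_height` × global
maximum (pipeline default 0.02).  A minimum centroid separation (default
0.32 Da, i.e. twice the binning half-width plus ε) keeps the subsequent
intervals disjoint; only the ranked-centroid *interface* of the commercial
OMP implementation is reproduced, its exact kernel being unpublished.

**Interval alignment** (`peakalign.align_to_intervals`).  Feature value =
mean (or max) of a pixel's intensities within centroid ± half-width; empty
intervals are 0.  Two half-width settings mirror the two analysis paths:
0.156 Da / mean for segmentation and ROC screening, 0.3 Da / max for the PCA
path.  Intervals are closed on both sides; under explicitly allowed overlap
a datapoint on a shared boundary belongs to the lower centroid.  The PCA
path always allows overlap because 0.3 Da half-widths can exceed half the
centroid spacing.

**Multivariate diagnostics** (`multivariate`).  Level scaling ((x − m)/m),
then ordinary PCA (5 components) on the labeled-pixel subset; "supervised"
refers to computing on group-labeled ROI pixels and carrying labels into the
score output for separation display, not to a label-regularized
decomposition.  Bisecting k-means repeatedly 2-means-splits the leaf with
the largest within-cluster sum of squares; splits are initialized by
deterministic farthest-point seeding (first center: point farthest from the
leaf mean; second: point farthest from the first), so segmentations are
reproducible.  "Medium" spatial smoothing is mapped to a Gaussian of
σ = 1 pixel applied to each feature image (missing pixels handled by
mask-normalized smoothing); the commercial scale is unpublished.

**Screening** (`discrim`).  Groups whose sizes differ by more than 10%
("approximately the same" quantified; no published number exists) are
subsampled without replacement to at most 1500 spectra per group, seeded.
AUC is computed in the Mann–Whitney rank form with midrank tie handling —
exactly equal to pair counting, which the tests verify on random instances.
Only AUC-gate passers (AUC < 0.4 or > 0.6) receive a Wilcoxon rank-sum test,
matching the screen's two-stage published design; p < 0.001 two-sided keeps
a feature.  The exact branch (pooled n ≤ 20) enumerates all label splits of
the midranked pooled sample and counts deviations of the rank sum from its
permutation mean at least as large as observed — valid under ties; the
asymptotic branch is the tie- and continuity-corrected normal approximation
(scipy).  Exhaustive enumeration at 10+10 shows the two branches agree
within 0.005 wherever the exact p ≤ 0.2 (and within 0.009 globally; the
discrepancy near p ≈ 0.5 is a property of the normal approximation and is
irrelevant at the 0.001 decision threshold).  No multiple-testing
correction by default, in fidelity to the emulated screen (raw p < 0.001
over a few hundred features); Benjamini–Hochberg is available via
`ScreenConfig(bh_correction=True)`.

**Annotation** (`annotate`).  Nearest-reference matching with signed
deviation Δ = m/z(MSI) − m(ref), accepted iff |Δ| < 0.2 Da; ties broken by
protein name for determinism.  One MSI m/z consumes one reference peptide
per feature, but a reference peptide may be nearest for several MSI m/z,
and an m/z may recur across features (real signatures share peptides across
features).  Protein inference requires ≥ 2 distinct matched m/z per protein
with one shared direction ("similar spatial differential intensity" is
operationalized as same AUC side of 0.5, there being no published
quantitative similarity measure).  Reference rows are treated as
protein-specific; shared tryptic peptides between proteins are not modeled.

## Synthetic data

`synthio` generates the study conditions with full ground truth:

- **Cohort**: default 18 patients; binary features assigned by the
  largest-remainder rule at the published prevalences (pN+ 12/18 = 67%,
  pL+ 8/18 = 44%, pV+ 5/18 = 27%), then permuted across patients
  independently per feature (marginals are all that is published; an
  optional joint-probability table models correlations).  Stage and grade
  follow the published margins; cores per patient uniform on 1–7.
- **Spectra**: sum of Gaussian peaks (σ = 0.1 Da) at centroids drawn on a
  1 Da slot lattice with ±0.25 Da jitter (minimum spacing 0.5 Da keeps
  0.156 Da intervals disjoint and planted peaks unambiguous), per-pixel
  log-normal amplitudes (σ_log = 0.5, a realistic ~55% CV; base heights
  log-uniform 50–500 a.u.), a deterministic slowly varying baseline
  (sinusoid + descending ramp, amplitude 30 a.u. — something for
  `remove_baseline` to remove), additive Gaussian noise (sd 2 a.u.),
  clipped at zero.  Detection range fixed to 800–3200 Da; default 557 peaks
  echo the emulated study's aligned-feature count.
- **Planted effects**: per feature, a configurable number of synthetic
  proteins × 2 peptides (default 8 pL / 1 pN / 2 pV, the published
  signature structure); their amplitudes are multiplied (pL, pV: "up") or
  divided (pN: "down") by `effect_size` in feature-positive patients'
  pixels.  With σ_log = 0.5, effect size 2 gives a theoretical per-pixel
  AUC of Φ(ln 2 / (0.5·√2)) ≈ 0.84, comfortably outside the 0.6 gate.
- **Reference list**: one peptide per planted m/z at planted + N(0, σ_jit)
  (default σ_jit = 0.05 Da, placing ~99.9% of deviations under the 0.2 Da
  tolerance, as in the published deviation column), plus uniquely named
  decoy peptides farther than 0.2 Da from every planted m/z.
- **Per-core random intercepts** exist (`core_intercept_sd`) but default to
  0: within-patient core variability is unpublished.

What the generator does *not* emulate: isotope patterns and adducts,
detector physics (saturation, mass drift), spatial autocorrelation of
biological signal within a core, and patient-level random effects under the
default intercept of 0.  Consequently the screening tests certify the
*statistical machinery* (calibration, recovery, exactness), not robustness
to pseudo-replication: like the emulated screen, tests are spectrum-level,
and correlated pixels within patients would inflate significance on real
data.  This is a deliberate fidelity choice, flagged as a limitation.

## Problem sizes used by the test suite

Simulation-backed tests run on scaled problems chosen to exercise every
stage at full fidelity: 8 patients at 50% prevalence (4 + 4 per group), one
12×12-pixel core each (576 pixels per group), m/z 800–1000 at 0.05 Da
steps, 40 peaks.  Null calibration averages the combined-filter pass
fraction over 20 seeds; planted recovery (3 pL proteins × 2 peptides,
effect size 2.5, reference jitter 0.05 Da, 10×10 cores) requires 3/3
recovery with no decoy assignment in ≥ 19 of 20 seeds.  `SimConfig`
defaults, by contrast, mirror the full study design (18 patients, 1–7
cores, 557 peaks over 800–3200 Da) and are intended for library use.

## Numerical conventions

- Pixel coordinates are 1-based (imzML convention) everywhere in
  containers; 0-based indexing appears only where images are rasterized.
- imzML I/O is processed-mode, float64 for both axes: round-trips are
  bit-exact.
- Reported tables: m/z to 3 decimals, masses and Δ to 4, AUC to 4; numeric
  parsing accepts decimal commas and unicode minus signs as found in
  published tables.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the reference-list generator derives its
  stream as `seed + 1` so list regeneration does not depend on dataset
  generation order.  Pipeline screens offset the balancing seed per feature
  (pL +0, pN +1, pV +2) so feature screens are mutually independent.
- Report bundles avoid timestamps and use fixed float formats; identical
  configuration + seed reproduces byte-identical output, which the tests
  assert.

## Known limitations

- Spectrum-level inference (no per-patient aggregation or mixed models) —
  faithful to the emulated screen but anticonservative under within-patient
  correlation.
- The OMP dictionary assumes a single Gaussian peak width across the mass
  range; TOF resolution actually degrades with m/z.
- Nearest-mass annotation at 0.2 Da cannot distinguish isobaric peptides;
  the two-peptide rule mitigates but does not eliminate misassignment.
- TIC normalization couples features: strong planted effects slightly
  depress the normalized intensity of all other peaks in positive pixels
  (closure effect), which can surface as weak opposite-direction
  discriminative features.  This is physical, not an artifact of the
  implementation.
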