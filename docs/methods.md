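# Methods

This note documents the models, numerical choices and limitations behind
`perfstrat`. It is written for a reader who wants to know exactly what the
code computes and what a passing test suite does — and does not — establish.

## 1. Signal model and concentration conversion

DSC-MRI records a T2\*-weighted signal S(t) at repetition interval Δt while
a gadolinium bolus transits the vasculature. The package uses the standard
single-exponential relation S(t) = S₀·exp(−TE·ΔR2\*(t)) with a linear
ΔR2\*–concentration relationship, so

    ΔR2*(t) = −ln(S(t)/S₀) / TE,   S₀ = mean of the pre-bolus baseline.

The baseline window is the first `baseline_points` samples (≥ 3; default 8).
Absolute proportionality constants between ΔR2\* and gadolinium
concentration are never needed because every reported map is normalized to
a reference region (below). Nonpositive signal samples abort the conversion
with the offending voxel/time index; the pipeline driver converts such
failures into categorized exclusions rather than crashing a cohort run.

## 2. Bolus model, QC gate

The first-pass bolus is modeled as a gamma-variate
K·(t−t₀)^α·e^{−(t−t₀)/β} (zero before arrival t₀; analytic maximum at
t₀ + αβ). The fit is nonlinear least squares with a deterministic
initialization: t₀ from the last pre-peak sample below 5% of the peak,
α₀ = 3, β₀ solved from the time-to-peak, K₀ from the peak height. After
convergence the first-pass window is re-derived from the fitted curve
(fitted t₀ to the post-peak sample where the fit drops below 20% of its
peak) and R² = 1 − SSres/SStot is evaluated there. The window is never
shorter than 8 samples: with 4 free parameters, goodness of fit on fewer
points is meaningless and was observed to let pure noise pass the gate.
Non-convergence is a flag (R² = 0), not an exception.

The quality gate excludes a study when R² < 0.95, strictly: a fit exactly
at the threshold passes. The threshold is configurable
(`PipelineConfig.qc_threshold`).

## 3. AIF detection

Arterial voxels are found by scoring every brain-mask voxel on three
first-pass features — peak height (z), time-to-peak (−z) and FWHM (−z),
z-scored over the candidate population — followed by a divide-and-conquer
pass that repeatedly halves the candidate list (keeping the better-scoring
half) until ≤ 50 remain; the AIF is the mean concentration curve of the top
10 voxels. Ties are broken by lowest linear voxel index, so detection is
fully deterministic. FWHM uses linear interpolation at the half-maximum
crossings. This scorer is a deliberately simple, reproducible stand-in for
more elaborate arterial-shape classifiers; it honors the three features
that make a curve "arterial" (tall, early, narrow) and is exercised against
phantoms whose arterial voxels are tall/early/narrow by construction.

## 4. Deconvolution and the quadrature trade-off

Tissue curves follow the convolution model C(t) = CBF·(AIF ⊛ R)(t) with a
single-exponential residue R(t) = e^{−t/MTT} (a standard, analytically
tractable choice; the true residue family of tissue is unknown). CBF is
recovered by the block-circulant truncated-SVD method: the zero-padded AIF
forms a circulant convolution operator on the doubled (2N) grid, singular
values below `truncation_fraction` × the largest are zeroed
(default 0.10; 0 disables truncation), and CBF is the maximum of the
recovered residue. Because the operator is exactly circulant, a bulk delay
of the tissue curve only rotates the residue and leaves CBF unchanged.

Discretization choice: the forward model and the operator share the
rectangle-rule sum over the pointwise-sampled residue. This makes the CBF
round-trip exact at zero truncation and exactly delay-insensitive, at the
cost of a known quadrature inflation of the discrete curve area:
Δt·ΣR exceeds ∫R = MTT by ≈ Δt/2 (about 13% at Δt = 1 s, MTT = 4 s). Two
alternatives were evaluated and rejected: a time-averaged residue fixes the
area but biases CBF by ≈ −11%, and a trapezoidal endpoint weight fixes both
only by breaking circulant shift-equivariance (−22% CBF under a shifted
bolus). The inflation factor is common to all voxels with similar MTT, so
it cancels in the **relative** maps the analysis uses; absolute CBV in
physical units is out of scope. Consequences users should know:

* rCBV and rCBF (white-matter-normalized) round-trip essentially exactly on
  noiseless phantoms;
* raw CBF at the default 10% truncation is accurate to ~5–9% for
  physiologic MTTs when the AIF is sharp (see §7);
* the MTT map equals the CBV/CBF ratio by construction and inherits the
  area factor (~+15–25% absolute at Δt = 1 s); only MTT contrasts between
  regions are meaningful.

`truncation_fraction` accepts [0, 1): the zero value is deliberately legal
because consistency checks and impulse-input identities require an
untruncated inverse.

## 5. Leakage correction

Where the blood-brain barrier is disrupted, extravasating contrast adds a
T1-dominant term that depresses the measured ΔR2\*. The forward model adds
−k₂·∫₀ᵗ C_intravascular dτ to the voxel's leak-free curve (K₁ = 1); the
correction regresses each tumor-voxel curve on the mean reference-tissue
curve and its running integral,

    C_meas(t) ≈ k₁·C_ref(t) − k₂·∫C_ref dτ,

and restores C_corr = C_meas + k₂·∫C_ref. The recovery is exact when the
voxel's leak-free curve is proportional to the reference curve (equal MTT)
and degrades smoothly with residue-shape mismatch: at the phantom defaults
(tumor MTT 4.2 s vs white-matter reference 4.0 s) the corrected CBV carries
a residual ≈ 2%, versus a 10–15% uncorrected bias at the default leakage
rates (k₂ = 0.003/0.002 s⁻¹ for the HAT/LAT habitats). A reference curve
with zero variance is rejected.

## 6. Habitat delineation and the vascular marker

Within the enhancing tumor, voxels are split into two classes by k-means on
z-scored (rCBV, rCBF) features, initialized at the 10th/90th-percentile
feature vectors with a single pass (no random restarts): deterministic,
permutation-invariant, and invariant to common positive rescaling of the
maps. The cluster with the higher mean rCBV is the high-angiogenic habitat
(HAT). A region with zero feature variance is flagged degenerate and
treated entirely as HAT. This two-class partition is a declared simplified
substitute for full multi-habitat segmentation methods, which are beyond
the scope of this package; it is validated against phantoms where the true
HAT/LAT labels are known.

The vascular marker rCBV_HAT is the 90th percentile of rCBV over HAT
voxels (linear-interpolation percentile convention, NumPy default) — a
robust surrogate for the region's maximum perfusion. The cohort threshold
rCBVth is the sample median of the markers (mean of central order
statistics for even n); classification is `marker < rCBVth → moderate`,
`≥ → high`, so n distinct markers always split ⌊n/2⌋ / ⌈n/2⌉.

## 7. Synthetic phantoms: what they emulate and what they do not

The default phantom is a 32×32×8 block volume with arterial, white-matter,
gray-matter, tumor-HAT, tumor-LAT and edema regions. Defaults (chosen once
as a consistent, physiologically plausible operating point):

| class        | CBV (fraction) | MTT (s) | k₂ (1/s) |
|--------------|----------------|---------|----------|
| white matter | 0.020          | 4.0     | 0        |
| gray matter  | 0.035          | 4.0     | 0        |
| tumor HAT    | 0.214          | 4.2     | 0.003    |
| tumor LAT    | 0.100          | 4.2     | 0.002    |
| edema        | 0.015          | 4.0     | 0        |

CBF = CBV/MTT everywhere, so the central-volume identity holds exactly in
the ground truth. The HAT/white-matter CBV ratio (10.7) puts the measured
marker in the range reported for highly vascularized glioblastoma. The AIF
is a gamma-variate with α = 2, β = 1 s, arrival 12 s, peak ΔR2\* 40 s⁻¹
(FWHM ≈ 3.4 s): a sharp arterial first pass, which also keeps the
deconvolution operator's spectrum broad enough that 10% singular-value
truncation costs < 10% CBF. Timing defaults: TE 30 ms, Δt 1 s, 70 frames,
8 baseline frames. Noise is additive Gaussian on the signal at baseline
SNR 50 (configurable; acceptance round-trips use zero noise).

Not emulated: anatomy, partial-volume mixtures, bolus dispersion and
recirculation, motion and susceptibility artifacts, scanner- or
protocol-dependent calibration. Passing round-trip tests therefore
establish algorithmic correctness under the stated forward model, not
clinical accuracy on real acquisitions.

## 8. Cohort simulation

Each simulated patient carries age ~ N(59, 10²) (clipped 25–90), gender
(31% female), an ordered extent-of-resection code (gross total 0,
subtotal 0.5, biopsy 1; ~2% missing), MGMT methylation (44.8%), IDH1
status (34% unknown; 8% mutated among known), and a continuous marker
rCBV_HAT ~ N(10.73, 3²) truncated at 0.5. Survival is exponential with

    h_i = h₀ · exp(β_MGMT(v_i)·unmeth_i + β_rCBV·(marker_i − 10.73)
                   + β_age·(age−59) + β_gender·female + β_res·code),

where β_MGMT equals log 2.73 when the patient's marker lies below the
empirical cohort median ("moderate" vascularity) and log 1.72 otherwise,
β_rCBV = log 1.06 per marker unit, β_gender = log 0.88, β_res = log 1.84,
and h₀ = ln2/402 d⁻¹ (median survival ≈ 400 days for a reference patient).
Censoring is administrative: C ~ Uniform(0, c) independent of T, with the
horizon c solved analytically (bisection on
E[(1−e^{−hc})/(hc)] = target) to hit the requested expected censoring
fraction (default 15%). All draws flow through one seeded generator;
identical configs give byte-identical tables.

Note on marginal vs conditional effects: the subgroup hazard ratios
recovered by *univariable* Cox fits are mildly attenuated relative to the
generating conditional log-HRs (≈ 2.65 vs 2.73 at n = 5000) because of the
non-collapsibility of the hazard ratio in the presence of the independent
marker/covariate effects. This is a property of the estimand, not an
estimation error, and stays well inside the 10% recovery tolerance.

## 9. Survival statistics

Cox models are partial-likelihood fits (lifelines), reporting
exp(coefficient) with Wald 95% intervals and p-values, and Harrell's
concordance over all comparable pairs (cross-checked against an exhaustive
pair-enumeration oracle in the tests; with a binary covariate the
concordance ceiling is below 1 because within-group pairs are risk-tied and
credited ½). The resection covariate enters as the ordered numeric code
with mean imputation of missing values (imputation count logged). MGMT
enters as an unmethylated indicator, so hazard ratios above 1 mean
methylation is protective.

Kaplan-Meier medians use the product-limit convention in which the median
is the first time the curve falls strictly below 0.5; a curve that never
reaches 0.5 yields a flagged undefined median (NaN). Log-rank tests use the
standard hypergeometric variance; survival times are continuous in the
generator, so event-time ties arise only from user data.

The per-subgroup AUC is a landmark classification AUC: the ability of the
unmethylated indicator to predict death before the subgroup's combined KM
median survival, excluding patients censored before that landmark
(their status is unknown), computed by the rank/Mann-Whitney identity.
This is one reasonable operationalization of a subgroup discrimination
summary; other time-dependent ROC definitions exist and would give
different numbers.

Group tests: two-sided Mann-Whitney U (reported for the methylated group:
pairs where the methylated value is larger, ties half) and the two-sided
Fisher exact test on the IDH1 × MGMT 2×2 table restricted to known-IDH1
patients (exclusions counted; degenerate tables flagged, not tested).
P-values are two-sided throughout; no multiplicity correction is applied.

## 10. Pipeline and reproducibility

`run_case` converts every failure mode into one of five CONSORT-style
categories (included / processing_error / qc_gamma_fail / fov_incomplete /
other) with a free-text reason; counts always sum to the number of input
cases. The field-of-view check flags enhancing tumor touching the volume
boundary. `run_cohort` aborts — with the exclusion log already written — if
fewer than 4 cases survive. Reports (measured cohort CSV, Cox table,
stratified KM table, exclusion log, manifest with the seed) are written
with fixed float formatting and sorted keys, so reruns on identical inputs
are byte-identical. In the simulation step, each patient's phantom scales
its tumor-HAT blood volume to the patient's drawn marker (markers below 1.5
are floored at 1.5× white matter so HAT remains a high-perfusion region),
closing the imaging→outcome loop.

## 11. Problem sizes used in validation

The shipped validation suite uses: 32×32×8×70 phantoms (≈ 3,500 in-mask
voxels); 200 replicates for the QC noise gate; 100 replicate cohorts of
n = 5000 for subgroup hazard-ratio recovery; 1000 replicate cohorts of
n = 60 for null p-value calibration; and 300 randomized datasets of ≤ 12
records for the enumeration-oracle equivalence checks. These sizes give
Monte-Carlo standard errors comfortably below the tolerances they are
checked against while keeping a full run fast on a single CPU.

## 12. Known limitations

* The residue function, signal model and leakage model are the simplest
  members of their families; real tissue violates all three to some degree.
* Relative (not absolute) perfusion quantification only; no dispersion
  correction of the AIF.
* The two-class habitat partition cannot represent necrosis or multi-level
  vascular heterogeneity inside the enhancing tumor.
* The landmark AUC definition is one of several possible; compare numbers
  across software with care.
* Exponential survival with administrative censoring is a deliberately
  minimal outcome model: adequate for testing estimator correctness, not a
  model of real glioblastoma survival curves.
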