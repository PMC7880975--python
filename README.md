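# perfstrat

Perfusion-based survival stratification for glioblastoma: a tested,
reproducible implementation of the analysis chain that links tumor
vascularity measured by dynamic susceptibility contrast (DSC) MRI with MGMT
promoter methylation status and overall survival.

## Who this is for

Researchers who want to exercise, validate or extend the quantitative steps
behind imaging-biomarker survival studies in neuro-oncology without access
to patient data: every stage runs end-to-end on synthetic DSC phantoms with
known hemodynamic ground truth and on simulated cohorts with a known
proportional-hazards structure, so each algorithm can be checked against the
values that generated its input.

## The analysis chain

1. **DSC quantification** (`perfstrat.dsc`). The T2\*-weighted signal is
   converted to a concentration-time curve, ΔR2\*(t) = −ln(S/S₀)/TE with S₀
   the pre-bolus baseline mean. The arterial input function (AIF) is
   detected automatically from peak height, time-to-peak and
   full-width-at-half-maximum features. Tumor curves are corrected for
   contrast extravasation with the Boxerman linear model
   (ΔR2\*ₘₑₐₛ ≈ K₁·ΔR2\*ᵣₑ𝒻 − K₂·∫ΔR2\*ᵣₑ𝒻). Cerebral blood volume is the
   trapezoidal area under the curve; cerebral blood flow comes from
   delay-insensitive block-circulant truncated-SVD deconvolution of
   C(t) = CBF·(AIF ⊛ R)(t); mean transit time is MTT = CBV/CBF. rCBV and
   rCBF are normalized so normal-appearing white matter averages 1.0. A
   gamma-variate fit K·(t−t₀)^α·e^(−(t−t₀)/β) of the first pass provides
   the quality gate: studies with R² < 0.95 are excluded.
2. **Habitat marker** (`perfstrat.habitat`). The enhancing tumor is
   partitioned into high- and low-angiogenic habitats (HAT/LAT) in
   (rCBV, rCBF) feature space; the patient's vascular marker **rCBV_HAT**
   is the 90th percentile of rCBV over the HAT habitat. The cohort
   threshold **rCBVth** is the median marker: below it a tumor is
   "moderately", at or above it "highly" vascularized.
3. **Survival analysis** (`perfstrat.survival`). Three Cox
   proportional-hazards models (clinical covariates + MGMT, + rCBV_HAT,
   + both) with Harrell's concordance; Kaplan-Meier curves, log-rank tests
   and univariable hazard ratios for methylated vs unmethylated MGMT within
   the vascularity subgroups; Mann-Whitney and Fisher tests for
   marker/molecular associations. MGMT is coded so HR > 1 means an
   unmethylated promoter increases hazard.
4. **Synthetic test-bed** (`perfstrat.phantom`, `perfstrat.cohort`).
   Block phantoms with per-class CBF/CBV/MTT and leakage rates (the
   forward model of everything stage 1 inverts), and cohort simulation
   from an exponential proportional-hazards model in which the MGMT effect
   depends on vascularity (default log-HR log 2.73 below the cohort-median
   marker, log 1.72 above) with calibrated administrative censoring.
5. **Pipeline** (`perfstrat.pipeline`, CLI `perfstrat`). simulate →
   quantify → marker → analyze with CONSORT-style per-case exclusion
   accounting and byte-reproducible reports.

## Worked example

`examples/03_cohort_survival.py` simulates a 96-patient cohort and runs the
full statistical battery:

```
n = 96, methylated = 45, censored = 10
cohort median rCBV_HAT (threshold) = 10.35

MGMT-methylation effect by vascularity subgroup:
  all       n = 45+51  HR  1.97 [1.26, 3.08]  log-rank p = 0.0024  AUC = 0.63
  moderate  n = 25+23  HR  3.46 [1.74, 6.89]  log-rank p = 0.0002  AUC = 0.75
  high      n = 20+28  HR  1.04 [0.57, 1.91]  log-rank p = 0.8961  AUC = 0.53

Mann-Whitney U (rCBV_HAT by MGMT): U = 1039, p = 0.428 (n = 45 vs 51)
```

The moderate-vascularity subgroup shows a markedly stronger methylation
effect than the high-vascularity subgroup — the generating structure of the
simulation, recovered by the analysis (with the sampling noise a single
96-patient draw implies). `examples/01_phantom_roundtrip.py` and
`02_habitat_marker.py` show the imaging half: a phantom whose tumor-HAT
blood volume is 10.7× white matter yields a measured median rCBV ≈ 10.4 and
a HAT-habitat Dice of 1.0 at zero noise. `04_full_pipeline.py` runs the
disk-based pipeline; the same run is available from the shell as

```bash
perfstrat run-all --work-dir demo_run --seed 7
```

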