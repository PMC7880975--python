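"""Simulate a 96-patient cohort and run the survival analysis battery.

Draws a cohort with a vascularity-dependent MGMT methylation effect
(hazard ratio 2.73 for unmethylated status in moderately vascularized
tumors, 1.72 in highly vascularized ones), then runs the three Cox models,
the median-threshold stratification with Kaplan-Meier/log-rank comparisons,
and the marker/molecular group tests.
"""

import numpy as np

from perfstrat.cohort import CohortConfig, generate_cohort
from perfstrat.habitat import compute_threshold
from perfstrat.survival import (
    compare_rcbv_by_mgmt,
    stratified_analysis,
    test_idh_associations,
    three_cox_models,
)

cohort = generate_cohort(CohortConfig(seed=1))
print(f"n = {len(cohort)}, methylated = {cohort['mgmt_methylated'].sum()}, "
      f"censored = {(1 - cohort['event']).sum()}")

th = compute_threshold(cohort["rcbv_hat"].to_numpy())
print(f"cohort median rCBV_HAT (threshold) = {th.rcbv_th:.2f}\n")

print("Cox proportional-hazards models (HR [95% CI], p; C = concordance):")
for name, model in three_cox_models(cohort).items():
    print(f"  {name} (C = {model.concordance:.2f})")
    for cov, eff in model.effects.items():
        print(f"    {cov:<18} HR {eff.hr:5.2f} [{eff.ci95[0]:.2f}, "
              f"{eff.ci95[1]:.2f}]  p = {eff.p:.3f}")

print("\nMGMT-methylation effect by vascularity subgroup:")
strat = stratified_analysis(cohort, th)
for name, row in strat.rows.items():
    print(f"  {name:<9} n = {row.n_meth}+{row.n_unmeth:<3} "
          f"HR {row.hr:5.2f} [{row.ci95[0]:.2f}, {row.ci95[1]:.2f}]  "
          f"log-rank p = {row.logrank_p:.4f}  AUC = {row.auc:.2f}")

mw = compare_rcbv_by_mgmt(cohort)
print(f"\nMann-Whitney U (rCBV_HAT by MGMT): U = {mw.statistic:.0f}, "
      f"p = {mw.p:.3f} (n = {mw.n_per_group[0]} vs {mw.n_per_group[1]})")
idh = test_idh_associations(cohort)
print(f"Fisher IDH1×MGMT p = {idh['fisher'].p:.3f} "
      f"({idh['fisher'].n_excluded} unknown-IDH1 patients excluded)")

# A larger HR in the 'moderate' row than in the 'high' row reproduces the
# generating structure: methylation is most protective when tumor
# vascularity is below the cohort median.
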