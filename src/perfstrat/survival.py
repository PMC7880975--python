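"""Survival analyses: Cox regressions, KM/log-rank stratification, group tests.

Reproduces the statistical battery of an imaging-biomarker survival study:

* mean imputation of missing extent-of-resection codes;
* three Cox proportional-hazards models (clinical covariates plus MGMT,
  plus rCBV_HAT, plus both), each reporting per-covariate hazard ratios,
  Wald 95% CIs, p-values, and Harrell's concordance;
* Kaplan-Meier / log-rank comparison of methylated vs unmethylated MGMT
  arms within vascularity subgroups (all / moderate / high, split at the
  cohort-median rCBV_HAT threshold);
* Mann-Whitney U comparison of rCBV_HAT by MGMT status, and Fisher /
  Mann-Whitney tests of IDH1 associations.

MGMT is coded so that *unmethylated = 1*: hazard ratios above 1 mean that an
unmethylated promoter increases hazard, i.e. methylation is protective.
P-values are two-sided throughout and no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from scipy.stats import fisher_exact, mannwhitneyu

from .cohort import RESECTION_CODES
from .errors import AnalysisError, FitError, ImputationError
from .habitat import VascularThreshold

__all__ = [
    "CovariateEffect",
    "CoxResult",
    "StratifiedRow",
    "StratifiedResult",
    "GroupComparisonResult",
    "impute_resection",
    "fit_cox",
    "three_cox_models",
    "km_logrank",
    "stratified_analysis",
    "compare_rcbv_by_mgmt",
    "test_idh_associations",
    "km_curve_coordinates",
]


@dataclass(frozen=True)
class CovariateEffect:
    hr: float
    ci95: Tuple[float, float]
    p: float


@dataclass
class CoxResult:
    """Per-covariate hazard ratios and Harrell's concordance of one model."""

    effects: Dict[str, CovariateEffect]
    concordance: float
    n: int
    n_events: int


@dataclass
class StratifiedRow:
    """One subgroup's KM/log-rank summary (methylated vs unmethylated arms)."""

    subgroup: str
    n_meth: int
    n_unmeth: int
    median_os_meth: float
    median_os_unmeth: float
    delta_os: float
    hr: float
    ci95: Tuple[float, float]
    logrank_p: float
    auc: float


@dataclass
class StratifiedResult:
    rows: Dict[str, StratifiedRow]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for name, r in self.rows.items():
            recs.append(
                {
                    "subgroup": name,
                    "n_meth": r.n_meth,
                    "n_unmeth": r.n_unmeth,
                    "median_os_meth": r.median_os_meth,
                    "median_os_unmeth": r.median_os_unmeth,
                    "delta_os": r.delta_os,
                    "hr": r.hr,
                    "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1],
                    "logrank_p": r.logrank_p,
                    "auc": r.auc,
                }
            )
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p: float
    n_per_group: Tuple[int, int]
    degenerate: bool = False
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# imputation and design matrix
# ---------------------------------------------------------------------------

def impute_resection(cohort: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Mean-impute the numeric resection code for records missing it.

    The extent of resection is encoded on an ordered numeric scale
    (gross_total = 0, subtotal = 0.5, biopsy = 1); missing entries receive
    the mean of the observed codes.  Returns the cohort with a
    ``resection_code`` column plus the number of imputed records.
    """
    out = cohort.copy()
    if "resection_code" in out.columns:
        codes = out["resection_code"].astype(float)
    else:
        codes = out["resection"].map(RESECTION_CODES).astype(float)  # NaN if missing
    observed = codes.dropna()
    n_missing = int(codes.isna().sum())
    if len(observed) == 0:
        raise ImputationError("all resection values are missing")
    codes = codes.fillna(observed.mean())
    out["resection_code"] = codes
    return out, n_missing


_COVARIATE_LABELS = {
    "age": "age",
    "gender": "gender_f",
    "resection": "resection_code",
    "mgmt": "mgmt_unmethylated",
    "rcbv_hat": "rcbv_hat",
}


def _design(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    df, _ = impute_resection(cohort) if "resection" in covariates else (cohort.copy(), 0)
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov == "age":
            X["age"] = df["age"].astype(float)
        elif cov == "gender":
            X["gender_f"] = (df["gender"] == "f").astype(float)
        elif cov == "resection":
            X["resection_code"] = df["resection_code"].astype(float)
        elif cov == "mgmt":
            X["mgmt_unmethylated"] = 1.0 - df["mgmt_methylated"].astype(float)
        elif cov == "rcbv_hat":
            X["rcbv_hat"] = df["rcbv_hat"].astype(float)
        else:
            raise AnalysisError(f"unknown covariate {cov!r}")
    X["os_days"] = df["os_days"].astype(float)
    X["event"] = df["event"].astype(int)
    return X


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def fit_cox(cohort: pd.DataFrame, covariates: Sequence[str]) -> CoxResult:
    """Cox proportional-hazards fit by partial likelihood.

    ``covariates`` is a subset of {"age", "gender", "resection", "mgmt",
    "rcbv_hat"}.  Reports exp(coefficient) hazard ratios with Wald 95%
    intervals and p-values, and Harrell's concordance over all comparable
    pairs.  MGMT enters as an unmethylated indicator so HR > 1 means
    methylation is protective.
    """
    X = _design(cohort, covariates)
    if int(X["event"].sum()) < 2:
        raise FitError("need at least 2 observed events for a Cox fit")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="os_days", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise FitError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    effects = {}
    for cov in covariates:
        label = _COVARIATE_LABELS[cov]
        row = summ.loc[label]
        effects[label] = CovariateEffect(
            hr=float(row["exp(coef)"]),
            ci95=(
                float(row["exp(coef) lower 95%"]),
                float(row["exp(coef) upper 95%"]),
            ),
            p=float(row["p"]),
        )
    return CoxResult(
        effects=effects,
        concordance=float(cph.concordance_index_),
        n=len(X),
        n_events=int(X["event"].sum()),
    )


def three_cox_models(cohort: pd.DataFrame) -> Dict[str, CoxResult]:
    """The three standard models: clinical + MGMT, clinical + rCBV_HAT, all."""
    clinical = ["age", "gender", "resection"]
    return {
        "excluding_rcbv_hat": fit_cox(cohort, clinical + ["mgmt"]),
        "excluding_mgmt": fit_cox(cohort, clinical + ["rcbv_hat"]),
        "all_clinical_variables": fit_cox(cohort, clinical + ["mgmt", "rcbv_hat"]),
    }


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def _km_median(os_days: np.ndarray, event: np.ndarray) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(os_days, event_observed=event)
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")


def _landmark_auc(sub: pd.DataFrame, landmark: float) -> float:
    """AUC of the unmethylated indicator for death before the landmark time.

    Patients censored before the landmark are excluded (their status at the
    landmark is unknown); among the rest, the positive class is death before
    the landmark.  With a binary predictor this reduces to the balanced
    accuracy of "unmethylated predicts early death".
    """
    if not np.isfinite(landmark):
        return float("nan")
    os_days = sub["os_days"].to_numpy(float)
    event = sub["event"].to_numpy(bool)
    known = ~((os_days < landmark) & ~event)
    died_early = (os_days < landmark) & event
    y = died_early[known]
    score = (1 - sub["mgmt_methylated"].to_numpy(float))[known]
    if y.sum() == 0 or y.sum() == len(y):
        return float("nan")
    # rank-based AUC (Mann-Whitney identity), ties get half credit
    pos, neg = score[y], score[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def km_logrank(
    cohort_subset: pd.DataFrame, subgroup: str = "all"
) -> StratifiedRow:
    """KM medians, log-rank test, and univariable Cox HR for MGMT arms.

    The hazard ratio comes from a univariable Cox fit on the unmethylated
    indicator, so HR > 1 means unmethylated patients fare worse; its sign
    always agrees with the direction of the KM separation.
    """
    meth = cohort_subset[cohort_subset["mgmt_methylated"] == 1]
    unmeth = cohort_subset[cohort_subset["mgmt_methylated"] == 0]
    if len(meth) == 0 or len(unmeth) == 0:
        raise AnalysisError(f"subgroup {subgroup!r} has an empty MGMT arm")

    med_m = _km_median(meth["os_days"].to_numpy(float), meth["event"].to_numpy(int))
    med_u = _km_median(unmeth["os_days"].to_numpy(float), unmeth["event"].to_numpy(int))

    lr = logrank_test(
        meth["os_days"], unmeth["os_days"],
        event_observed_A=meth["event"], event_observed_B=unmeth["event"],
    )
    try:
        cox = fit_cox(cohort_subset, ["mgmt"])
        eff = cox.effects["mgmt_unmethylated"]
        hr, ci = eff.hr, eff.ci95
    except FitError:
        hr, ci = float("nan"), (float("nan"), float("nan"))

    landmark = _km_median(
        cohort_subset["os_days"].to_numpy(float), cohort_subset["event"].to_numpy(int)
    )
    auc = _landmark_auc(cohort_subset, landmark)

    return StratifiedRow(
        subgroup=subgroup,
        n_meth=len(meth),
        n_unmeth=len(unmeth),
        median_os_meth=med_m,
        median_os_unmeth=med_u,
        delta_os=med_m - med_u,
        hr=hr,
        ci95=ci,
        logrank_p=float(lr.p_value),
        auc=auc,
    )


def stratified_analysis(
    cohort: pd.DataFrame, threshold: VascularThreshold
) -> StratifiedResult:
    """MGMT survival comparison in all / moderate / high vascularity subgroups.

    The moderate subgroup holds patients with ``rcbv_hat < rcbv_th``, the
    high subgroup the rest; the threshold is the cohort-median marker, so
    subgroup sizes partition the cohort.
    """
    marker = cohort["rcbv_hat"].astype(float)
    subsets = {
        "all": cohort,
        "moderate": cohort[marker < threshold.rcbv_th],
        "high": cohort[marker >= threshold.rcbv_th],
    }
    rows = {}
    for name, sub in subsets.items():
        if len(sub) == 0:
            raise AnalysisError(f"subgroup {name!r} is empty")
        rows[name] = km_logrank(sub, subgroup=name)
    return StratifiedResult(rows=rows, threshold=threshold.rcbv_th)


def km_curve_coordinates(cohort_subset: pd.DataFrame) -> pd.DataFrame:
    """Product-limit curve coordinates per MGMT arm, exportable as CSV."""
    frames = []
    for label, code in (("methylated", 1), ("unmethylated", 0)):
        arm = cohort_subset[cohort_subset["mgmt_methylated"] == code]
        if len(arm) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(arm["os_days"], event_observed=arm["event"], label=label)
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"arm": label, "time": sf.index.to_numpy(float),
                 "survival": sf[label].to_numpy(float)}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_rcbv_by_mgmt(cohort: pd.DataFrame) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U on rCBV_HAT by MGMT methylation.

    The U statistic is reported for the methylated group: the number of
    (methylated, unmethylated) pairs in which the methylated value is larger
    (ties counted half).
    """
    meth = cohort.loc[cohort["mgmt_methylated"] == 1, "rcbv_hat"].to_numpy(float)
    unmeth = cohort.loc[cohort["mgmt_methylated"] == 0, "rcbv_hat"].to_numpy(float)
    if len(meth) == 0 or len(unmeth) == 0:
        raise AnalysisError("both MGMT groups must be non-empty")
    res = mannwhitneyu(meth, unmeth, alternative="two-sided")
    return GroupComparisonResult(
        statistic=float(res.statistic), p=float(res.pvalue),
        n_per_group=(len(meth), len(unmeth)),
    )


def test_idh_associations(cohort: pd.DataFrame) -> Dict[str, GroupComparisonResult]:
    """Fisher test of IDH1 × MGMT plus Mann-Whitney of rCBV_HAT by IDH1.

    Records with unknown IDH1 are excluded; the exclusion count is carried on
    both results.  A contingency table with an empty row or column is flagged
    degenerate rather than tested.
    """
    known = cohort[cohort["idh1"] != "unknown"]
    n_excluded = len(cohort) - len(known)
    if len(known) == 0:
        raise AnalysisError("no records with known IDH1 status")
    mutated = known["idh1"] == "mutated"
    meth = known["mgmt_methylated"] == 1

    table = np.array(
        [
            [int((mutated & meth).sum()), int((mutated & ~meth).sum())],
            [int((~mutated & meth).sum()), int((~mutated & ~meth).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        fisher = GroupComparisonResult(
            statistic=float("nan"), p=float("nan"),
            n_per_group=(int(mutated.sum()), int((~mutated).sum())),
            degenerate=True, n_excluded=n_excluded,
        )
    else:
        odds, p = fisher_exact(table, alternative="two-sided")
        fisher = GroupComparisonResult(
            statistic=float(odds), p=float(p),
            n_per_group=(int(mutated.sum()), int((~mutated).sum())),
            n_excluded=n_excluded,
        )

    mut_vals = known.loc[mutated, "rcbv_hat"].to_numpy(float)
    wt_vals = known.loc[~mutated, "rcbv_hat"].to_numpy(float)
    if len(mut_vals) == 0 or len(wt_vals) == 0:
        mw = GroupComparisonResult(
            statistic=float("nan"), p=float("nan"),
            n_per_group=(len(mut_vals), len(wt_vals)),
            degenerate=True, n_excluded=n_excluded,
        )
    else:
        res = mannwhitneyu(mut_vals, wt_vals, alternative="two-sided")
        mw = GroupComparisonResult(
            statistic=float(res.statistic), p=float(res.pvalue),
            n_per_group=(len(mut_vals), len(wt_vals)), n_excluded=n_excluded,
        )
    return {"fisher": fisher, "mannwhitney": mw}
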