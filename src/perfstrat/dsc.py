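"""Voxelwise DSC perfusion quantification: rCBV, rCBF and MTT maps.

Pipeline per study:

1. convert the T2* signal to ΔR2*(t) concentration curves
   (``ΔR2* = −ln(S/S0)/TE``, S0 = pre-bolus baseline mean);
2. automatically detect the arterial input function from peak height,
   time-to-peak and full-width-at-half-maximum features;
3. leakage-correct tumor voxels with the Boxerman linear model;
4. rCBV by trapezoidal integration of the curve, rCBF by block-circulant
   (delay-insensitive) truncated-SVD deconvolution, MTT = CBV/CBF by the
   central-volume theorem;
5. normalize CBV/CBF to the mean over a normal-appearing white-matter
   reference mask so that reference tissue averages exactly 1.0.

A gamma-variate fit of the first-pass bolus provides the quality-control
statistic: studies whose R² falls below 0.95 are excluded from analysis
(strict "<"; equality passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .curves import AcquisitionTiming, ConcentrationCurve, gamma_variate
from .errors import (
    AnalysisError,
    ConversionError,
    CorrectionError,
    DetectionError,
    NormalizationError,
    ParameterError,
)

__all__ = [
    "DscStudy",
    "GammaFit",
    "QcResult",
    "Aif",
    "BoxermanResult",
    "BsvdResult",
    "PerfusionMaps",
    "signal_to_concentration",
    "fit_gamma_variate",
    "qc_first_pass",
    "detect_aif",
    "boxerman_correct",
    "compute_cbv",
    "deconvolve_bsvd",
    "compute_mtt",
    "compute_maps",
]


@dataclass
class DscStudy:
    """One patient's 4-D DSC signal with masks and acquisition timing."""

    signal: np.ndarray  # (x, y, z, t)
    timing: AcquisitionTiming
    masks: Dict[str, np.ndarray]  # named 3-D boolean masks on the study grid

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ParameterError("signal must be 4-D (x, y, z, t)")
        if self.signal.shape[3] != self.timing.n_timepoints:
            raise ParameterError(
                "signal time axis does not match timing.n_timepoints"
            )
        for name, m in self.masks.items():
            if m.shape != self.signal.shape[:3]:
                raise ParameterError(f"mask {name!r} is not on the study grid")


# ---------------------------------------------------------------------------
# signal conversion
# ---------------------------------------------------------------------------

def signal_to_concentration(
    signal: np.ndarray, timing: AcquisitionTiming
) -> ConcentrationCurve:
    """Convert a signal-time series to a ΔR2*(t) concentration curve.

    ``ΔR2*(t) = −ln(S(t)/S0)/TE`` with S0 the mean over the pre-bolus
    baseline window.  Pre-bolus samples therefore map to ≈ 0.

    Raises
    ------
    ConversionError
        If any sample (or the baseline mean) is nonpositive; the message
        names the offending time index.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or len(s) != timing.n_timepoints:
        raise ParameterError("signal must be 1-D on the acquisition grid")
    bad = np.nonzero(s <= 0)[0]
    if bad.size:
        raise ConversionError(
            f"nonpositive signal at time index {int(bad[0])}; cannot take log"
        )
    s0 = s[: timing.baseline_points].mean()
    if s0 <= 0:
        raise ConversionError("nonpositive baseline mean")
    values = -np.log(s / s0) / timing.echo_time
    return ConcentrationCurve(
        values=values, time=timing.time, baseline_points=timing.baseline_points
    )


def _concentration_volume(
    signal4d: np.ndarray, timing: AcquisitionTiming, mask: np.ndarray
) -> np.ndarray:
    """Vectorized ΔR2* conversion for all voxels in ``mask`` → (V, T) array."""
    s = signal4d[mask].astype(float)  # (V, T)
    if np.any(s <= 0):
        v, t = np.argwhere(s <= 0)[0]
        raise ConversionError(
            f"nonpositive signal at in-mask voxel {int(v)}, time index {int(t)}"
        )
    s0 = s[:, : timing.baseline_points].mean(axis=1, keepdims=True)
    return -np.log(s / s0) / timing.echo_time


# ---------------------------------------------------------------------------
# gamma-variate fit and QC
# ---------------------------------------------------------------------------

@dataclass
class GammaFit:
    """Gamma-variate first-pass fit and its goodness of fit."""

    K: float
    t0: float
    alpha: float
    beta: float
    r_squared: float
    converged: bool
    window: Tuple[int, int] = (0, 0)  # [start, stop) sample indices of the window

    @classmethod
    def failure(cls) -> "GammaFit":
        return cls(K=0.0, t0=0.0, alpha=1.0, beta=1.0, r_squared=0.0, converged=False)


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str
    r_squared: float


def _first_pass_window(values: np.ndarray, peak_idx: int) -> Tuple[int, int]:
    """Data-driven first-pass window: bolus onset to post-peak 20% decay."""
    peak = values[peak_idx]
    start = 0
    for i in range(peak_idx, -1, -1):
        if values[i] < 0.05 * peak:
            start = i
            break
    stop = len(values)
    for i in range(peak_idx, len(values)):
        if values[i] < 0.20 * peak:
            stop = i + 1
            break
    return start, stop


def fit_gamma_variate(curve: ConcentrationCurve) -> GammaFit:
    """Least-squares gamma-variate fit over the first-pass window.

    Initialization is deterministic: bolus arrival from the last pre-peak
    sample below 5% of the peak, shape fixed at α₀ = 3 with β₀ solved from
    the time-to-peak, amplitude from the peak height.  After convergence the
    window is re-derived from the fitted curve (fitted t0 to the post-peak
    sample where the fit drops below 20% of its peak) and R² is evaluated
    there.  Non-convergence returns a failure flag with ``r_squared = 0``
    rather than raising.
    """
    v = curve.values
    t = curve.time
    peak_idx = int(np.argmax(v))
    peak = v[peak_idx]
    if peak <= 0:
        return GammaFit.failure()

    start, stop = _first_pass_window(v, peak_idx)
    if stop - start < 5:
        return GammaFit.failure()

    t0_init = max(t[start], 0.0)
    tp = t[peak_idx]
    if tp <= t0_init:
        return GammaFit.failure()
    alpha0 = 3.0
    beta0 = max((tp - t0_init) / alpha0, curve.dt / 10)
    K0 = peak / ((alpha0 * beta0) ** alpha0 * np.exp(-alpha0))

    tw, vw = t[start:stop], v[start:stop]
    try:
        popt, _ = curve_fit(
            gamma_variate,
            tw,
            vw,
            p0=[K0, t0_init, alpha0, beta0],
            bounds=([0.0, 0.0, 0.05, 1e-3], [np.inf, tp, 30.0, 100.0]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return GammaFit.failure()
    K, t0, alpha, beta = (float(x) for x in popt)

    # re-derive the window from the fitted curve: t0 to post-peak 20% decay
    fitted = gamma_variate(t, K, t0, alpha, beta)
    fpeak_idx = int(np.argmax(fitted))
    fpeak = fitted[fpeak_idx]
    if fpeak <= 0:
        return GammaFit.failure()
    w_start = int(np.searchsorted(t, t0))
    w_stop = len(t)
    for i in range(fpeak_idx, len(t)):
        if fitted[i] < 0.20 * fpeak:
            w_stop = i + 1
            break
    # R^2 on fewer samples than ~2x the parameter count is meaningless
    # (4 free parameters can track noise); enforce a minimum window
    w_stop = min(max(w_stop, w_start + 8), len(t))
    if w_stop - w_start < 3:
        return GammaFit.failure()
    resid = v[w_start:w_stop] - fitted[w_start:w_stop]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v[w_start:w_stop] - v[w_start:w_stop].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GammaFit(
        K=K, t0=t0, alpha=alpha, beta=beta,
        r_squared=min(r2, 1.0), converged=True, window=(w_start, w_stop),
    )


def qc_first_pass(fit: GammaFit, threshold: float = 0.95) -> QcResult:
    """Quality-control gate on the first-pass gamma-variate fit.

    Exclusion is strictly ``r_squared < threshold``: a fit exactly at the
    threshold passes (the boundary belongs to the included side).
    """
    if not fit.converged:
        return QcResult(passed=False, reason="gamma_fit_failed", r_squared=0.0)
    if fit.r_squared < threshold:
        return QcResult(
            passed=False, reason="gamma_r2_below_threshold", r_squared=fit.r_squared
        )
    return QcResult(passed=True, reason="", r_squared=fit.r_squared)


# ---------------------------------------------------------------------------
# AIF detection
# ---------------------------------------------------------------------------

@dataclass
class Aif:
    """Arterial input function: mean curve of the selected voxel cluster."""

    curve: ConcentrationCurve
    voxel_indices: list  # list of (x, y, z) tuples
    features: Dict[str, float]  # peak_height, time_to_peak, fwhm


def _fwhm(values: np.ndarray, time: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation at the crossings."""
    peak_idx = int(np.argmax(values))
    half = values[peak_idx] / 2.0
    if half <= 0:
        return np.inf
    left = time[0]
    for i in range(peak_idx, 0, -1):
        if values[i - 1] < half <= values[i]:
            frac = (half - values[i - 1]) / (values[i] - values[i - 1])
            left = time[i - 1] + frac * (time[i] - time[i - 1])
            break
    right = time[-1]
    for i in range(peak_idx, len(values) - 1):
        if values[i] >= half > values[i + 1]:
            frac = (values[i] - half) / (values[i] - values[i + 1])
            right = time[i] + frac * (time[i + 1] - time[i])
            break
    return float(right - left)


def detect_aif(
    study: DscStudy,
    brain_mask: np.ndarray,
    n_select: int = 10,
    min_candidates: int = 100,
) -> Aif:
    """Automatic AIF detection from arterial-shape features.

    Every in-mask voxel is scored on three first-pass features — peak height
    (higher is more arterial), time-to-peak (earlier) and FWHM (narrower) —
    as ``score = z(peak) − z(ttp) − z(fwhm)`` with z-scores over the
    candidate population.  A divide-and-conquer pass repeatedly halves the
    candidate set, keeping the better-scoring half, until ≤ 50 remain; the
    final AIF is the mean curve of the ``n_select`` top voxels.  Ties are
    broken by lowest linear voxel index, making the selection deterministic.

    Raises
    ------
    DetectionError
        Fewer than ``min_candidates`` candidate voxels, or no candidate has
        a positive bolus peak.
    """
    idx = np.argwhere(brain_mask)
    if len(idx) < min_candidates:
        raise DetectionError(
            f"need >= {min_candidates} candidate voxels, got {len(idx)}"
        )
    conc = _concentration_volume(study.signal, study.timing, brain_mask)  # (V, T)
    time = study.timing.time

    peak_idx = np.argmax(conc, axis=1)
    peak = conc[np.arange(len(conc)), peak_idx]
    ttp = time[peak_idx]
    valid = peak > 0
    if not valid.any():
        raise DetectionError("no candidate voxel has a positive bolus peak")
    fwhm = np.full(len(conc), np.inf)
    for i in np.nonzero(valid)[0]:
        fwhm[i] = _fwhm(conc[i], time)
    valid &= np.isfinite(fwhm)
    if not valid.any():
        raise DetectionError("no candidate satisfies minimal arterial criteria")

    cand = np.nonzero(valid)[0]

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    score = z(peak[cand]) - z(ttp[cand]) - z(fwhm[cand])
    # deterministic ordering: score descending, then lowest linear voxel index
    shape3 = study.signal.shape[:3]
    linear = np.ravel_multi_index(idx[cand].T, shape3)
    order = np.lexsort((linear, -score))
    ranked = cand[order]

    # divide and conquer: halve the candidate set until <= 50 remain
    while len(ranked) > 50:
        ranked = ranked[: (len(ranked) + 1) // 2]
    selected = ranked[:n_select]

    mean_curve = conc[selected].mean(axis=0)
    curve = ConcentrationCurve(
        values=mean_curve, time=time, baseline_points=study.timing.baseline_points
    )
    p_idx = int(np.argmax(mean_curve))
    features = {
        "peak_height": float(mean_curve[p_idx]),
        "time_to_peak": float(time[p_idx]),
        "fwhm": _fwhm(mean_curve, time),
    }
    if features["peak_height"] <= 0:
        raise DetectionError("selected cluster has a nonpositive peak")
    voxels = [tuple(int(c) for c in idx[i]) for i in selected]
    return Aif(curve=curve, voxel_indices=voxels, features=features)


# ---------------------------------------------------------------------------
# Boxerman leakage correction
# ---------------------------------------------------------------------------

@dataclass
class BoxermanResult:
    corrected: ConcentrationCurve
    k1: float
    k2: float
    cbv_correction: float


def boxerman_correct(
    curve: ConcentrationCurve, reference: ConcentrationCurve
) -> BoxermanResult:
    """First-order leakage correction of a tumor voxel curve.

    The measured curve is regressed on the leak-free reference curve (mean
    over non-enhancing tissue) and its running integral:

        measured(t) ≈ k1·ref(t) − k2·∫₀ᵗ ref dτ

    ``k2 > 0`` indicates T1-dominant extravasation depressing the measured
    curve.  The corrected curve adds the leakage term back:
    ``corrected = measured + k2·∫ref``; ``cbv_correction`` is that term's
    contribution to the trapezoidal CBV integral.
    """
    if len(curve) != len(reference) or not np.allclose(curve.time, reference.time):
        raise ParameterError("curve and reference must share the time grid")
    ref = reference.values
    if ref.std() <= 1e-15:
        raise CorrectionError("reference curve has zero variance")
    ref_int = cumulative_trapezoid(ref, reference.time, initial=0.0)
    X = np.column_stack([ref, ref_int])
    coef, *_ = np.linalg.lstsq(X, curve.values, rcond=None)
    k1, k2 = float(coef[0]), float(-coef[1])
    corrected_values = curve.values + k2 * ref_int
    corrected = curve.copy_with(corrected_values)
    cbv_correction = float(np.trapezoid(k2 * ref_int, curve.time))
    return BoxermanResult(corrected=corrected, k1=k1, k2=k2, cbv_correction=cbv_correction)


# ---------------------------------------------------------------------------
# CBV, bSVD deconvolution, MTT
# ---------------------------------------------------------------------------

def compute_cbv(curve: ConcentrationCurve) -> float:
    """CBV as the trapezoidal area under the ΔR2* curve (unnormalized)."""
    return float(np.trapezoid(curve.values, curve.time))


@dataclass
class BsvdResult:
    residue_function: np.ndarray  # scaled residue, length 2N (zero-padded grid)
    cbf: float


def _bsvd_operator(aif_values: np.ndarray, dt: float) -> np.ndarray:
    """Block-circulant convolution operator on the zero-padded (2N) grid.

    The rectangle-rule circulant built from the zero-padded AIF; because it
    is exactly circulant, circular shifts of the tissue curve only rotate
    the recovered residue, leaving its maximum (the CBF estimate) unchanged.
    """
    n = len(aif_values)
    L = 2 * n
    padded = np.zeros(L)
    padded[:n] = aif_values
    j = np.arange(L)
    return dt * padded[(j[:, None] - j[None, :]) % L]


def _bsvd_pseudo_inverse(A: np.ndarray, truncation_fraction: float) -> np.ndarray:
    U, s, Vt = np.linalg.svd(A)
    cutoff = truncation_fraction * s[0]
    s_inv = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    return (Vt.T * s_inv) @ U.T


def deconvolve_bsvd(
    tissue: ConcentrationCurve,
    aif: "Aif | ConcentrationCurve",
    truncation_fraction: float = 0.1,
) -> BsvdResult:
    """Delay-insensitive deconvolution by block-circulant truncated SVD.

    Singular values below ``truncation_fraction`` × the largest are zeroed
    (0 disables truncation).  Returns the scaled residue function
    CBF·R(t) on the zero-padded grid; CBF is its maximum, which is
    insensitive to bulk delays because circular shifts only rotate the
    residue.
    """
    if not 0 <= truncation_fraction < 1:
        raise ParameterError(
            f"truncation_fraction must be in [0, 1), got {truncation_fraction}"
        )
    aif_curve = aif.curve if isinstance(aif, Aif) else aif
    if len(tissue) != len(aif_curve):
        raise ParameterError("tissue and AIF must share the time grid")
    if np.allclose(aif_curve.values, 0.0):
        raise ParameterError("AIF is identically zero")
    A = _bsvd_operator(aif_curve.values, tissue.dt)
    M = _bsvd_pseudo_inverse(A, truncation_fraction)
    c = np.zeros(A.shape[0])
    c[: len(tissue)] = tissue.values
    residue = M @ c
    cbf = float(residue.max())
    if cbf < 0:
        cbf = 0.0
    return BsvdResult(residue_function=residue, cbf=cbf)


def compute_mtt(cbv: float, cbf: float) -> float:
    """Mean transit time by the central-volume theorem, MTT = CBV/CBF.

    Returns NaN (undefined-MTT flag) when ``cbf <= 0``.
    """
    if cbf <= 0:
        return float("nan")
    return cbv / cbf


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

@dataclass
class PerfusionMaps:
    """Voxelwise rCBV/rCBF (reference-normalized) and MTT (seconds) maps."""

    rcbv: np.ndarray
    rcbf: np.ndarray
    mtt: np.ndarray
    reference_region_mean: float  # mean unnormalized CBV over the reference mask
    reference_region_mean_cbf: float = field(default=float("nan"))


def compute_maps(
    study: DscStudy,
    aif: Aif,
    reference_mask: np.ndarray,
    tumor_mask: Optional[np.ndarray] = None,
    analysis_mask: Optional[np.ndarray] = None,
    truncation_fraction: float = 0.1,
) -> PerfusionMaps:
    """Assemble rCBV, rCBF and MTT maps for one study.

    Voxels in ``analysis_mask`` (default: union of all study masks except
    background) are converted to ΔR2*; voxels in ``tumor_mask`` are
    leakage-corrected against the mean reference-mask curve before
    integration.  CBV is the trapezoidal curve area divided by the AIF area
    (dimensionless); CBF comes from bSVD deconvolution (1/s); MTT = CBV/CBF
    in seconds.  rCBV and rCBF are normalized by their means over
    ``reference_mask`` (normal-appearing white matter), so reference tissue
    averages exactly 1.0.
    """
    if reference_mask is None or not reference_mask.any():
        raise NormalizationError("reference mask is empty")
    shape3 = study.signal.shape[:3]
    if analysis_mask is None:
        analysis_mask = np.zeros(shape3, dtype=bool)
        for name, m in study.masks.items():
            if name != "background":
                analysis_mask |= m
    if not analysis_mask.any():
        raise AnalysisError("analysis mask is empty")

    conc = _concentration_volume(study.signal, study.timing, analysis_mask)  # (V, T)
    time = study.timing.time
    flat_idx = np.ravel_multi_index(np.argwhere(analysis_mask).T, shape3)
    pos_of = {f: i for i, f in enumerate(flat_idx)}

    ref_flat = np.ravel_multi_index(np.argwhere(reference_mask & analysis_mask).T, shape3)
    if len(ref_flat) == 0:
        raise NormalizationError("reference mask lies outside the analysis mask")
    ref_rows = np.array([pos_of[f] for f in ref_flat])
    ref_curve_values = conc[ref_rows].mean(axis=0)
    ref_curve = ConcentrationCurve(
        values=ref_curve_values, time=time, baseline_points=study.timing.baseline_points
    )

    if tumor_mask is not None and tumor_mask.any():
        tum_flat = np.ravel_multi_index(np.argwhere(tumor_mask & analysis_mask).T, shape3)
        tum_rows = np.array([pos_of[f] for f in tum_flat])
        ref_int = cumulative_trapezoid(ref_curve_values, time, initial=0.0)
        X = np.column_stack([ref_curve_values, ref_int])
        coef, *_ = np.linalg.lstsq(X, conc[tum_rows].T, rcond=None)  # (2, V_t)
        k2 = -coef[1]
        conc[tum_rows] = conc[tum_rows] + k2[:, None] * ref_int[None, :]

    aif_area = float(np.trapezoid(aif.curve.values, time))
    if aif_area <= 0:
        raise ParameterError("AIF area must be positive")
    cbv_raw = np.trapezoid(conc, time, axis=1) / aif_area

    A = _bsvd_operator(aif.curve.values, study.timing.repetition_time)
    M = _bsvd_pseudo_inverse(A, truncation_fraction)
    padded = np.zeros((conc.shape[0], A.shape[0]))
    padded[:, : conc.shape[1]] = conc
    residues = padded @ M.T  # (V, 2T)
    cbf_raw = residues.max(axis=1)
    cbf_raw = np.maximum(cbf_raw, 0.0)

    # central-volume theorem on the unnormalized quantities: cbv_raw is the
    # AIF-normalized curve area (dimensionless blood-volume fraction) and
    # cbf_raw is in 1/s, so their ratio is the transit time in seconds
    nan = float("nan")
    mtt_vals = np.where(cbf_raw > 0, cbv_raw / np.where(cbf_raw > 0, cbf_raw, 1.0), nan)

    ref_cbv_mean = float(cbv_raw[ref_rows].mean())
    ref_cbf_mean = float(cbf_raw[ref_rows].mean())
    if ref_cbv_mean <= 0 or ref_cbf_mean <= 0:
        raise NormalizationError("reference region has nonpositive mean perfusion")

    rcbv = np.zeros(shape3)
    rcbf = np.zeros(shape3)
    mtt = np.full(shape3, nan)
    coords = np.argwhere(analysis_mask)
    rcbv[tuple(coords.T)] = cbv_raw / ref_cbv_mean
    rcbf[tuple(coords.T)] = cbf_raw / ref_cbf_mean
    mtt[tuple(coords.T)] = mtt_vals
    rcbv = np.maximum(rcbv, 0.0)
    return PerfusionMaps(
        rcbv=rcbv,
        rcbf=rcbf,
        mtt=mtt,
        reference_region_mean=ref_cbv_mean,
        reference_region_mean_cbf=ref_cbf_mean,
    )
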