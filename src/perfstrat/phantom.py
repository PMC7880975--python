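"""Digital DSC phantoms with known ground-truth hemodynamics.

The phantom is a small labeled block volume (not anatomically realistic): each
tissue class carries a known CBF/CBV/MTT triple and an optional
blood-brain-barrier leakage rate, and the 4-D signal is built through the full
forward model

    AIF (gamma-variate bolus)
      → tissue ΔR2*: cbf · Δt · (AIF ⊛ R),  R(t) = exp(−t/MTT)
      → optional leakage term  −k2 · ∫ ΔR2*_intravascular dt   (T1-dominant)
      → signal  S(t) = S0 · exp(−TE · ΔR2*(t))  (+ Gaussian noise)

so that every quantification stage downstream can be checked against the
generating truth.  The discrete convolution is the rectangle-rule sum over
the pointwise-sampled residue — the same discretization the block-circulant
SVD deconvolution inverts — so CBF round-trips exactly at zero truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .curves import AcquisitionTiming, ConcentrationCurve, gamma_variate
from .errors import ConfigurationError, ParameterError

__all__ = [
    "TISSUE_CLASSES",
    "GroundTruthVoxel",
    "PhantomLayout",
    "DscPhantom",
    "generate_aif_curve",
    "residue_convolve",
    "synthesize_tissue_curve",
    "generate_phantom",
    "default_layout",
    "default_timing",
]

TISSUE_CLASSES = (
    "arterial",
    "white_matter",
    "gray_matter",
    "tumor_HAT",
    "tumor_LAT",
    "edema",
    "background",
)

#: classes with an intact blood-brain barrier (leakage_k2 must be 0)
_NON_LEAKY = {"arterial", "white_matter", "gray_matter", "edema", "background"}


@dataclass(frozen=True)
class GroundTruthVoxel:
    """Known hemodynamics of one voxel (or one homogeneous tissue class).

    Units are internally consistent rather than absolute: ``cbv`` is a
    dimensionless blood-volume fraction, ``mtt`` is in seconds, and
    ``cbf = cbv / mtt`` (1/s) so the central-volume relation
    ``cbv = cbf × mtt`` holds exactly by construction.  ``leakage_k2`` (1/s)
    is the first-order contrast extravasation rate; 0 means intact barrier.
    """

    cbf: float
    cbv: float
    mtt: float
    leakage_k2: float
    tissue_class: str

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ConfigurationError(f"unknown tissue class {self.tissue_class!r}")
        if self.mtt <= 0 and self.tissue_class != "background":
            raise ParameterError(f"mtt must be > 0, got {self.mtt}")
        if self.leakage_k2 < 0:
            raise ParameterError(f"leakage_k2 must be >= 0, got {self.leakage_k2}")
        if self.leakage_k2 > 0 and self.tissue_class in _NON_LEAKY:
            raise ConfigurationError(
                f"{self.tissue_class} has an intact barrier; leakage_k2 must be 0"
            )
        if self.mtt > 0 and abs(self.cbv - self.cbf * self.mtt) > 1e-9 * max(
            1.0, abs(self.cbv)
        ):
            raise ConfigurationError(
                f"cbv must equal cbf*mtt ({self.cbv} != {self.cbf}*{self.mtt})"
            )

    @classmethod
    def from_cbv_mtt(
        cls, cbv: float, mtt: float, tissue_class: str, leakage_k2: float = 0.0
    ) -> "GroundTruthVoxel":
        """Construct from (cbv, mtt) with cbf derived as cbv/mtt."""
        return cls(
            cbf=cbv / mtt,
            cbv=cbv,
            mtt=mtt,
            leakage_k2=leakage_k2,
            tissue_class=tissue_class,
        )


def _default_tissue_truth() -> Dict[str, GroundTruthVoxel]:
    # CBV fractions chosen so tumor_HAT / white_matter = 10.7, matching the
    # magnitude of reference-normalized rCBV values seen in high-grade glioma.
    return {
        "white_matter": GroundTruthVoxel.from_cbv_mtt(0.020, 4.0, "white_matter"),
        "gray_matter": GroundTruthVoxel.from_cbv_mtt(0.035, 4.0, "gray_matter"),
        # k2 chosen to depress the uncorrected tumor CBV integral by ~10-20%,
        # the magnitude the leakage correction is meant to undo
        "tumor_HAT": GroundTruthVoxel.from_cbv_mtt(0.214, 4.2, "tumor_HAT", 0.003),
        "tumor_LAT": GroundTruthVoxel.from_cbv_mtt(0.100, 4.2, "tumor_LAT", 0.002),
        "edema": GroundTruthVoxel.from_cbv_mtt(0.015, 4.0, "edema"),
    }


@dataclass
class PhantomLayout:
    """Block geometry and per-class hemodynamics of a phantom.

    ``regions`` maps a tissue class to an ``(x, y, z)`` slice triple inside
    ``shape``.  Later entries do not overwrite earlier ones; regions must be
    disjoint by construction (validated at generation time).
    """

    shape: Tuple[int, int, int] = (32, 32, 8)
    regions: Dict[str, Tuple[slice, slice, slice]] = field(default_factory=dict)
    tissue_truth: Dict[str, GroundTruthVoxel] = field(default_factory=_default_tissue_truth)
    # sharp arterial bolus (FWHM ~3.4 s): arteries see a narrower first pass
    # than tissue, and the deconvolution operator must retain enough spectral
    # content for flow recovery under singular-value truncation
    aif_params: Dict[str, float] = field(
        default_factory=lambda: {"peak": 40.0, "t0": 12.0, "alpha": 2.0, "beta": 1.0}
    )
    s0: float = 600.0
    baseline_snr: Optional[float] = 50.0  # None or 0 -> noiseless

    def with_noise(self, snr: Optional[float]) -> "PhantomLayout":
        return replace(self, baseline_snr=snr)


def default_layout(**kwargs) -> PhantomLayout:
    """The default 32×32×8 block phantom used throughout the test-bed.

    Regions: a small arterial block, large white/gray matter slabs, a tumor
    block split into high- (HAT) and low-angiogenic (LAT) subregions, and an
    edema block.  Everything else is background (no signal dynamics).
    """
    regions = {
        "arterial": (slice(2, 6), slice(2, 6), slice(2, 6)),
        "white_matter": (slice(8, 22), slice(2, 14), slice(0, 8)),
        "gray_matter": (slice(8, 22), slice(16, 30), slice(0, 8)),
        "tumor_HAT": (slice(25, 30), slice(3, 9), slice(1, 7)),
        "tumor_LAT": (slice(25, 30), slice(9, 15), slice(1, 7)),
        "edema": (slice(25, 30), slice(17, 23), slice(1, 7)),
    }
    return PhantomLayout(regions=regions, **kwargs)


def default_timing() -> AcquisitionTiming:
    """Conventional DSC timing: TE 30 ms, one volume per second, 70 dynamics."""
    return AcquisitionTiming(
        echo_time=0.030, repetition_time=1.0, n_timepoints=70, baseline_points=8
    )


@dataclass
class DscPhantom:
    """A synthetic DSC study: 4-D signal, tissue masks, timing and truth."""

    signal: np.ndarray  # (x, y, z, t)
    masks: Dict[str, np.ndarray]  # tissue_class -> 3-D bool
    timing: AcquisitionTiming
    truth: Dict[str, GroundTruthVoxel]  # per tissue class
    aif_truth: ConcentrationCurve
    concentration_truth: Dict[str, ConcentrationCurve]  # leak-free, per class
    seed: int

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.signal.shape[:3]

    def brain_mask(self) -> np.ndarray:
        """Union of all non-background tissue masks."""
        out = np.zeros(self.shape, dtype=bool)
        for name, mask in self.masks.items():
            if name != "background":
                out |= mask
        return out

    def labels(self) -> np.ndarray:
        """Integer label volume (index into TISSUE_CLASSES, background = 0)."""
        out = np.zeros(self.shape, dtype=np.int16)
        for i, name in enumerate(TISSUE_CLASSES):
            if name in self.masks and name != "background":
                out[self.masks[name]] = i + 1
        return out

    def truth_for(self, voxel: Tuple[int, int, int]) -> GroundTruthVoxel:
        for name, mask in self.masks.items():
            if mask[voxel]:
                return self.truth[name]
        raise KeyError(f"voxel {voxel} is not inside any mask")


def generate_aif_curve(
    timing: AcquisitionTiming, params: Mapping[str, float]
) -> ConcentrationCurve:
    """Gamma-variate arterial bolus on the acquisition grid.

    ``params`` holds ``K`` (amplitude), ``t0`` (bolus arrival, s), ``alpha``
    (shape) and ``beta`` (scale, s); alternatively ``peak`` may replace ``K``
    to request a given maximum ΔR2* (the amplitude is then solved from the
    analytic maximum at ``t0 + alpha·beta``).
    """
    alpha = float(params["alpha"])
    beta = float(params["beta"])
    t0 = float(params["t0"])
    if alpha <= 0 or beta <= 0:
        raise ParameterError(f"alpha and beta must be > 0, got {alpha}, {beta}")
    t_max = timing.time[-1]
    if t0 < 0 or t0 >= t_max:
        raise ParameterError(f"t0 must lie within [0, {t_max}), got {t0}")
    if "K" in params:
        K = float(params["K"])
    else:
        peak_val = (alpha * beta) ** alpha * np.exp(-alpha)
        K = float(params["peak"]) / peak_val
    values = gamma_variate(timing.time, K, t0, alpha, beta)
    if not np.all(np.isfinite(values)):
        raise ParameterError("gamma-variate parameters produced non-finite values")
    return ConcentrationCurve(
        values=values, time=timing.time, baseline_points=timing.baseline_points
    )


def residue_weights(mtt: float, n: int, dt: float) -> np.ndarray:
    """Pointwise-sampled exponential residue ``R(kΔt) = exp(−kΔt/mtt)``.

    The forward model and the block-circulant deconvolution operator share
    this rectangle-rule discretization, which keeps CBF = max(residue) exact
    and fully delay-insensitive; the discrete curve area then exceeds the
    continuous ``cbv·area(AIF)`` by an O(Δt/MTT) quadrature factor that is
    common to all voxels and cancels in the relative (reference-normalized)
    maps the pipeline reports.
    """
    if mtt <= 0:
        raise ParameterError(f"mtt must be > 0, got {mtt}")
    return np.exp(-np.arange(n) * dt / mtt)


def residue_convolve(aif_values: np.ndarray, residue: np.ndarray, dt: float) -> np.ndarray:
    """Discrete convolution ``Δt·(aif ⊛ residue)`` truncated to the grid."""
    n = len(aif_values)
    return dt * np.convolve(aif_values, residue)[:n]


def synthesize_tissue_curve(
    aif: ConcentrationCurve,
    truth: GroundTruthVoxel,
    timing: AcquisitionTiming,
) -> ConcentrationCurve:
    """Forward-model the ΔR2* curve of a voxel with the given hemodynamics.

    The leak-free curve is ``cbf · Δt · (AIF ⊛ R)`` with exponential residue
    ``R(t) = exp(−t/mtt)``.  If ``leakage_k2 > 0``, a T1-dominant leakage term
    ``−k2 · cumulative-integral(leak-free curve)`` is added, the first-order
    extravasation forward model that the leakage correction inverts.
    """
    if truth.mtt <= 0:
        raise ParameterError(f"mtt must be > 0, got {truth.mtt}")
    if len(aif) != timing.n_timepoints:
        raise ParameterError("AIF must be sampled on the acquisition grid")
    dt = timing.repetition_time
    residue = residue_weights(truth.mtt, timing.n_timepoints, dt)
    clean = truth.cbf * residue_convolve(aif.values, residue, dt)
    if truth.leakage_k2 > 0:
        from scipy.integrate import cumulative_trapezoid

        leak = cumulative_trapezoid(clean, aif.time, initial=0.0)
        values = clean - truth.leakage_k2 * leak
    else:
        values = clean
    return ConcentrationCurve(
        values=values, time=timing.time, baseline_points=timing.baseline_points
    )


def generate_phantom(
    layout: PhantomLayout,
    timing: AcquisitionTiming,
    seed: int,
) -> DscPhantom:
    """Build a reproducible 4-D DSC phantom from a block layout.

    The signal follows ``S(t) = S0 · exp(−TE·ΔR2*(t))`` per voxel, with
    optional additive Gaussian noise of standard deviation ``S0 / SNR``.
    Arterial voxels carry the AIF itself; tissue voxels carry the convolved
    (and, for tumor, leaky) curves.  Same seed ⇒ bit-identical output.
    """
    required = {"arterial", "white_matter", "tumor_HAT", "tumor_LAT"}
    missing = required - set(layout.regions)
    if missing:
        raise ConfigurationError(f"layout missing required regions: {sorted(missing)}")

    shape = layout.shape
    masks: Dict[str, np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)
    for name, sl in layout.regions.items():
        if name not in TISSUE_CLASSES or name == "background":
            raise ConfigurationError(f"invalid region class {name!r}")
        mask = np.zeros(shape, dtype=bool)
        mask[sl] = True
        if not mask.any():
            raise ConfigurationError(f"region {name!r} is empty")
        if (mask & occupied).any():
            raise ConfigurationError(f"region {name!r} overlaps another region")
        occupied |= mask
        masks[name] = mask
    masks["background"] = ~occupied

    truth = dict(layout.tissue_truth)
    if truth["tumor_HAT"].cbv <= truth["tumor_LAT"].cbv:
        raise ConfigurationError("tumor_HAT cbv must exceed tumor_LAT cbv")

    aif = generate_aif_curve(timing, layout.aif_params)

    # per-class ΔR2* curves (leak-free versions kept as ground truth)
    clean_curves: Dict[str, ConcentrationCurve] = {}
    observed: Dict[str, np.ndarray] = {}
    for name in masks:
        if name == "background":
            observed[name] = np.zeros(timing.n_timepoints)
            continue
        if name == "arterial":
            clean_curves[name] = aif
            observed[name] = aif.values
            continue
        gt = truth[name]
        leak_free = synthesize_tissue_curve(
            aif, replace(gt, leakage_k2=0.0), timing
        )
        clean_curves[name] = leak_free
        observed[name] = synthesize_tissue_curve(aif, gt, timing).values

    signal = np.empty(shape + (timing.n_timepoints,), dtype=float)
    for name, mask in masks.items():
        s = layout.s0 * np.exp(-timing.echo_time * observed[name])
        signal[mask] = s

    rng = np.random.default_rng(seed)
    if layout.baseline_snr:
        sigma = layout.s0 / layout.baseline_snr
        signal = signal + rng.normal(0.0, sigma, size=signal.shape)

    truth["arterial"] = GroundTruthVoxel(
        cbf=0.0, cbv=0.0, mtt=1.0, leakage_k2=0.0, tissue_class="arterial"
    )
    truth["background"] = GroundTruthVoxel(
        cbf=0.0, cbv=0.0, mtt=1.0, leakage_k2=0.0, tissue_class="background"
    )

    return DscPhantom(
        signal=signal,
        masks=masks,
        timing=timing,
        truth=truth,
        aif_truth=aif,
        concentration_truth=clean_curves,
        seed=seed,
    )
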