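"""Time axes and concentration-time curves for dynamic susceptibility contrast MRI.

A DSC acquisition samples a T2*-weighted signal at a fixed repetition time
while a gadolinium bolus transits the brain.  The quantities manipulated
throughout the package are ``ΔR2*(t)`` concentration-time curves — changes in
the transverse relaxation rate, proportional to intravascular contrast
concentration — on the uniform time grid defined by
:class:`AcquisitionTiming`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["AcquisitionTiming", "ConcentrationCurve", "gamma_variate"]


@dataclass(frozen=True)
class AcquisitionTiming:
    """Sampling grid and echo parameters of a DSC acquisition.

    Parameters
    ----------
    echo_time : float
        Echo time TE in seconds; converts log signal ratios to ΔR2*.
    repetition_time : float
        Sampling interval Δt in seconds (one volume per repetition).
    n_timepoints : int
        Number of dynamic volumes.
    baseline_points : int
        Number of pre-bolus samples used to estimate the baseline signal S0.
        At least 3 are required for a stable baseline mean.
    """

    echo_time: float
    repetition_time: float
    n_timepoints: int
    baseline_points: int

    def __post_init__(self) -> None:
        if self.echo_time <= 0:
            raise ParameterError(f"echo_time must be > 0, got {self.echo_time}")
        if self.repetition_time <= 0:
            raise ParameterError(
                f"repetition_time must be > 0, got {self.repetition_time}"
            )
        if self.baseline_points < 3:
            raise ParameterError(
                f"baseline_points must be >= 3, got {self.baseline_points}"
            )
        if self.n_timepoints <= self.baseline_points:
            raise ParameterError(
                "n_timepoints must exceed baseline_points "
                f"({self.n_timepoints} <= {self.baseline_points})"
            )

    @property
    def time(self) -> np.ndarray:
        """Time of each sample in seconds, starting at 0."""
        return np.arange(self.n_timepoints) * self.repetition_time


@dataclass
class ConcentrationCurve:
    """A ΔR2*(t) time series (1/s) on a uniform time grid.

    ``baseline_points`` records how many leading samples are pre-bolus; they
    are expected to be ≈ 0 after signal conversion.
    """

    values: np.ndarray
    time: np.ndarray
    baseline_points: int = 0
    _dt: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.shape != self.time.shape or self.values.ndim != 1:
            raise ParameterError(
                f"values/time must be equal-length 1-D arrays, got "
                f"{self.values.shape} vs {self.time.shape}"
            )
        if len(self.time) < 2:
            raise ParameterError("a curve needs at least 2 samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ParameterError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise ParameterError("time grid must be uniformly spaced")
        self._dt = float(steps[0])

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return self._dt

    def __len__(self) -> int:
        return len(self.values)

    def copy_with(self, values: np.ndarray) -> "ConcentrationCurve":
        """New curve on the same grid with different values."""
        return ConcentrationCurve(
            values=np.asarray(values, dtype=float),
            time=self.time.copy(),
            baseline_points=self.baseline_points,
        )


def gamma_variate(
    t: np.ndarray, K: float, t0: float, alpha: float, beta: float
) -> np.ndarray:
    """Gamma-variate bolus shape ``K·(t−t0)^α·exp(−(t−t0)/β)``, 0 for t ≤ t0.

    The canonical parametric model of a first-pass contrast bolus.  Its
    analytic maximum sits at ``t0 + α·β``.
    """
    if alpha <= 0 or beta <= 0:
        raise ParameterError(f"alpha and beta must be > 0, got {alpha}, {beta}")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = t > t0
    u = t[rising] - t0
    out[rising] = K * u**alpha * np.exp(-u / beta)
    return out
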