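"""High-angiogenic tumor (HAT) habitat delineation and the vascular marker.

Within the contrast-enhancing tumor, voxels are partitioned into a
high-angiogenic (HAT) and a low-angiogenic (LAT) habitat from their
(rCBV, rCBF) perfusion features; the vascular marker of a patient is the
90th percentile of rCBV over the HAT habitat (rCBV_HAT), a robust surrogate
of the region's maximum perfusion.  At the cohort level, the vascularity
threshold rCBVth is the median rCBV_HAT: markers below it are "moderate",
at or above it "high".

The habitat partition here is a deterministic two-class k-means clustering
on standardized (rCBV, rCBF) features, seeded from the 10th/90th percentile
centroids — a simple, reproducible delineation of the high-perfusion
subregion (full unsupervised multi-habitat segmentation methods are out of
scope for this package).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .dsc import PerfusionMaps
from .errors import DelineationError, MarkerError, ParameterError

__all__ = [
    "HabitatMask",
    "VascularMarker",
    "VascularThreshold",
    "delineate_hat",
    "compute_rcbv_hat",
    "compute_threshold",
]


@dataclass
class HabitatMask:
    """Binary HAT/LAT partition of the enhancing tumor."""

    hat: np.ndarray
    lat: np.ndarray
    degenerate: bool = False  # homogeneous region: whole tumor treated as HAT


@dataclass(frozen=True)
class VascularMarker:
    """rCBV_HAT: the 90th percentile of rCBV over the HAT habitat."""

    rcbv_hat: float
    percentile: float
    n_voxels_hat: int


@dataclass(frozen=True)
class VascularThreshold:
    """Cohort vascularity threshold (median rCBV_HAT).

    Classification rule: ``marker < rcbv_th`` → moderate vascularity,
    ``marker >= rcbv_th`` → high (the boundary belongs to "high").
    """

    rcbv_th: float
    rule: str = "below_is_moderate"

    def classify(self, marker: float) -> str:
        return "moderate" if marker < self.rcbv_th else "high"


def delineate_hat(maps: PerfusionMaps, enhancing_mask: np.ndarray) -> HabitatMask:
    """Two-class partition of the enhancing tumor in (rCBV, rCBF) space.

    Features are z-scored within the mask; k-means with two clusters is
    initialized at the 10th and 90th percentile feature vectors (one pass,
    no random restarts), making the partition deterministic, permutation
    invariant, and invariant to common positive rescaling of the maps.  The
    cluster with the higher mean rCBV is labeled HAT.  A homogeneous region
    (zero feature variance) is flagged degenerate and treated entirely as
    HAT.
    """
    if enhancing_mask.shape != maps.rcbv.shape:
        raise ParameterError("enhancing mask is not on the map grid")
    n = int(enhancing_mask.sum())
    if n < 2:
        raise DelineationError(f"enhancing mask has {n} voxel(s); need >= 2")
    feats = np.column_stack([maps.rcbv[enhancing_mask], maps.rcbf[enhancing_mask]])
    sd = feats.std(axis=0)
    if np.all(sd <= 1e-12):
        hat = enhancing_mask.copy()
        return HabitatMask(hat=hat, lat=np.zeros_like(hat), degenerate=True)
    sd = np.where(sd > 1e-12, sd, 1.0)
    z = (feats - feats.mean(axis=0)) / sd
    init = np.vstack([
        np.percentile(z, 10, axis=0),
        np.percentile(z, 90, axis=0),
    ])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300, random_state=0)
    labels = km.fit_predict(z)
    if len(np.unique(labels)) < 2:
        hat = enhancing_mask.copy()
        return HabitatMask(hat=hat, lat=np.zeros_like(hat), degenerate=True)
    mean_rcbv = [feats[labels == k, 0].mean() for k in (0, 1)]
    hat_label = int(np.argmax(mean_rcbv))
    hat = np.zeros_like(enhancing_mask)
    lat = np.zeros_like(enhancing_mask)
    coords = np.argwhere(enhancing_mask)
    hat_sel = labels == hat_label
    hat[tuple(coords[hat_sel].T)] = True
    lat[tuple(coords[~hat_sel].T)] = True
    return HabitatMask(hat=hat, lat=lat, degenerate=False)


def compute_rcbv_hat(
    maps: PerfusionMaps, habitat: HabitatMask, percentile: float = 90.0
) -> VascularMarker:
    """The vascular marker: percentile of rCBV over the HAT habitat.

    Uses the linear-interpolation percentile convention (NumPy's default
    ``method="linear"``): between order statistics the value is interpolated
    proportionally.
    """
    if not habitat.hat.any():
        raise MarkerError("HAT habitat is empty")
    vals = maps.rcbv[habitat.hat]
    return VascularMarker(
        rcbv_hat=float(np.percentile(vals, percentile)),
        percentile=percentile,
        n_voxels_hat=int(habitat.hat.sum()),
    )


def compute_threshold(markers: Sequence[float]) -> VascularThreshold:
    """Cohort threshold rCBVth: the sample median of the rCBV_HAT values.

    For even n this is the mean of the two central order statistics.  A
    cohort of n patients with distinct markers therefore splits into
    ⌊n/2⌋ moderate and ⌈n/2⌉ high patients under the ``< rcbv_th`` rule.
    """
    arr = np.asarray(list(markers), dtype=float)
    if arr.size < 2:
        raise ParameterError(f"need >= 2 marker values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("marker values must be finite")
    return VascularThreshold(rcbv_th=float(np.median(arr)))
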