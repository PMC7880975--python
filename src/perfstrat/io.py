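"""File IO: NIfTI volumes, JSON sidecars, cohort CSVs and reports.

Phantoms are persisted as a 4-D NIfTI signal volume plus a 3-D integer label
volume and a JSON sidecar holding the acquisition timing, per-class ground
truth and the generation seed.  Perfusion maps are written as three 3-D
NIfTI volumes.  Cohorts travel as plain CSV with a fixed column schema.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import AcquisitionTiming, ConcentrationCurve
from .dsc import DscStudy, PerfusionMaps
from .errors import ConfigurationError
from .phantom import TISSUE_CLASSES, DscPhantom, GroundTruthVoxel

__all__ = [
    "save_phantom",
    "load_study",
    "save_maps",
    "load_maps",
    "save_cohort",
    "load_cohort",
]

_AFFINE = np.eye(4)


def save_phantom(phantom: DscPhantom, directory: Path, case_id: str) -> Dict[str, Path]:
    """Write signal + labels NIfTI and the JSON sidecar for one case."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "signal": directory / f"{case_id}_dsc.nii",
        "labels": directory / f"{case_id}_labels.nii",
        "sidecar": directory / f"{case_id}_sidecar.json",
    }
    nib.save(nib.Nifti1Image(phantom.signal.astype(np.float32), _AFFINE), paths["signal"])
    nib.save(nib.Nifti1Image(phantom.labels().astype(np.int16), _AFFINE), paths["labels"])
    sidecar = {
        "seed": phantom.seed,
        "timing": dataclasses.asdict(phantom.timing),
        "truth": {
            name: dataclasses.asdict(gt) for name, gt in phantom.truth.items()
        },
        "aif_truth": list(map(float, phantom.aif_truth.values)),
        "label_names": list(TISSUE_CLASSES),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths


def load_study(directory: Path, case_id: str) -> Tuple[DscStudy, dict]:
    """Read one case back as a :class:`DscStudy` plus its sidecar dict.

    The label volume is expanded into named boolean masks (label ``i+1`` is
    ``TISSUE_CLASSES[i]``; 0 is background).
    """
    directory = Path(directory)
    sidecar_path = directory / f"{case_id}_sidecar.json"
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing sidecar for case {case_id!r}")
    sidecar = json.loads(sidecar_path.read_text())
    timing = AcquisitionTiming(**sidecar["timing"])
    signal = np.asarray(
        nib.load(directory / f"{case_id}_dsc.nii").get_fdata(), dtype=float
    )
    labels = np.asarray(
        nib.load(directory / f"{case_id}_labels.nii").get_fdata(), dtype=int
    )
    names = sidecar.get("label_names", list(TISSUE_CLASSES))
    masks = {}
    for i, name in enumerate(names):
        if name == "background":
            continue
        mask = labels == i + 1
        if mask.any():
            masks[name] = mask
    masks["background"] = labels == 0
    return DscStudy(signal=signal, timing=timing, masks=masks), sidecar


def save_maps(maps: PerfusionMaps, directory: Path, case_id: str) -> Dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("rcbv", maps.rcbv), ("rcbf", maps.rcbf), ("mtt", maps.mtt)):
        p = directory / f"{case_id}_{name}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), _AFFINE), p)
        paths[name] = p
    meta = directory / f"{case_id}_maps.json"
    meta.write_text(
        json.dumps(
            {
                "reference_region_mean": maps.reference_region_mean,
                "reference_region_mean_cbf": maps.reference_region_mean_cbf,
            },
            indent=2,
        )
    )
    paths["meta"] = meta
    return paths


def load_maps(directory: Path, case_id: str) -> PerfusionMaps:
    directory = Path(directory)
    vols = {
        name: np.asarray(
            nib.load(directory / f"{case_id}_{name}.nii").get_fdata(), dtype=float
        )
        for name in ("rcbv", "rcbf", "mtt")
    }
    meta = json.loads((directory / f"{case_id}_maps.json").read_text())
    return PerfusionMaps(
        rcbv=vols["rcbv"],
        rcbf=vols["rcbf"],
        mtt=vols["mtt"],
        reference_region_mean=meta["reference_region_mean"],
        reference_region_mean_cbf=meta.get("reference_region_mean_cbf", float("nan")),
    )


def save_cohort(cohort: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, float_format="%.10g")
    return path


def load_cohort(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "mgmt_methylated", "rcbv_hat", "os_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
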