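"""NIfTI / CSV / JSON readers and writers for cohorts and studies.

On-disk layout per cohort directory::

    cohort.csv            one row per clinical record
    config.json           the CohortConfig sidecar
    <patient_id>/
        <channel>.nii.gz  one NIfTI per channel (affine encodes spacing)
        mask.nii.gz       binary tumor mask

Channel names containing ``-`` (subtraction images) are written with ``_``
in filenames and mapped back on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import ClinicalRecord, CohortConfig, MultiparametricStudy

__all__ = ["write_study", "read_study", "write_cohort", "read_cohort",
           "clinical_to_frame"]


def _fname(channel: str) -> str:
    return channel.replace("-", "_") + ".nii.gz"


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_study(study: MultiparametricStudy, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.spacing_mm)
    for name, vol in study.channels.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), directory / _fname(name))
    nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), aff), directory / "mask.nii.gz")
    return directory


def read_study(directory: str | Path, channels: tuple[str, ...],
               patient_id: str | None = None) -> MultiparametricStudy:
    """Load and validate one patient's channels + mask.

    All grids must agree (shape and affine); the mask must be binary.
    """
    directory = Path(directory)
    mask_img = nib.load(directory / "mask.nii.gz")
    mask_data = np.asarray(mask_img.dataobj)
    uniq = set(np.unique(mask_data).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"mask is not binary: values {sorted(uniq)}")
    spacing = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
    vols: dict[str, np.ndarray] = {}
    for name in channels:
        path = directory / _fname(name)
        if not path.exists():
            raise FileNotFoundError(f"missing channel file {path}")
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        if data.shape != mask_data.shape:
            raise ValueError(
                f"channel {name!r} shape {data.shape} does not match mask "
                f"shape {mask_data.shape}"
            )
        if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
            raise ValueError(f"channel {name!r} affine differs from the mask affine")
        vols[name] = data
    return MultiparametricStudy(
        patient_id=patient_id or directory.name,
        channels=vols,
        mask=mask_data.astype(bool),
        spacing_mm=spacing,
    )


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("patient_id")


def write_cohort(cohort: list[tuple[MultiparametricStudy, ClinicalRecord]],
                 directory: str | Path, config: CohortConfig | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for study, _ in cohort:
        write_study(study, directory / study.patient_id)
    clinical_to_frame([r for _, r in cohort]).to_csv(directory / "cohort.csv")
    if config is not None:
        (directory / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return directory


def read_cohort(directory: str | Path, channels: tuple[str, ...] | None = None
                ) -> list[tuple[MultiparametricStudy, ClinicalRecord]]:
    directory = Path(directory)
    if channels is None:
        cfg = json.loads((directory / "config.json").read_text())
        channels = tuple(cfg["channels"])
    clinical = pd.read_csv(directory / "cohort.csv", index_col="patient_id")
    cohort = []
    for pid, row in clinical.iterrows():
        study = read_study(directory / str(pid), channels, patient_id=str(pid))
        record = ClinicalRecord(patient_id=str(pid), **row.to_dict())
        cohort.append((study, record))
    return cohort
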