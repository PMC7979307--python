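"""Volume and manifest IO.

Volumes travel as NIfTI (``.nii`` / ``.nii.gz``, via nibabel) or NRRD
(``.nrrd``, via SimpleITK); both round-trip float32 voxel data bit-exactly
together with per-axis spacing.  Only 3-dimensional single-channel grids
are accepted — the package's coordinate convention is 0-based voxel
indices in fixed (x, y, z) axis order, with no world-coordinate handling.

Dataset manifests are plain CSV with columns ``path, label, split, seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import SPLIT_NAMES

__all__ = [
    "VolumeRecord",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "ManifestError",
]

MANIFEST_COLUMNS = ("path", "label", "split", "seed")


class ManifestError(ValueError):
    """A manifest file violates the required schema."""


@dataclass
class VolumeRecord:
    """A 3D single-channel intensity grid with voxel spacing."""

    array: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    path: str | None = None
    format: str | None = None

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError(
                f"expected a 3-dimensional volume, got {self.array.ndim} axes"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


def _detect_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith(".nrrd"):
        return "nrrd"
    raise ValueError(
        f"unrecognized volume extension on {path!r}; "
        "expected .nii, .nii.gz or .nrrd"
    )


def read_volume(path) -> VolumeRecord:
    fmt = _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        array = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    else:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK returns (z, y, x); restore (x, y, z)
        array = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(z) for z in img.GetSpacing())
    return VolumeRecord(array=array, spacing=spacing, path=str(path), format=fmt)


def write_volume(record: VolumeRecord, path) -> None:
    fmt = _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(record.spacing) + [1.0])
        nib.save(nib.Nifti1Image(record.array, affine), str(path))
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(record.array.transpose(2, 1, 0))
        img.SetSpacing(tuple(record.spacing))
        sitk.WriteImage(img, str(path))


def write_manifest(frame: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest is missing column(s): {', '.join(missing)}")
    frame.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest is missing column(s): {', '.join(missing)}")
    labels = pd.to_numeric(frame["label"], errors="coerce")
    if labels.isna().any() or not labels.isin([0, 1]).all():
        bad = frame["label"][~labels.isin([0, 1])].iloc[0]
        raise ManifestError(f"labels must be 0 or 1, found {bad!r}")
    frame["label"] = labels.astype(int)
    unknown = set(frame["split"].unique()) - set(SPLIT_NAMES)
    if unknown:
        raise ManifestError(f"unknown split name(s): {sorted(unknown)}")
    return frame
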