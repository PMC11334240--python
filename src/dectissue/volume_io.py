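"""Reading and writing scalar volumes (NIfTI via nibabel, NRRD via SimpleITK)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .dect import DectVolume


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a scalar volume; returns (array, voxel spacing in mm)."""
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img).T.astype(float)
        spacing = tuple(float(s) for s in img.GetSpacing())
    else:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return arr, spacing


def write_volume(
    array: np.ndarray, spacing: tuple[float, float, float], path: str | Path
) -> None:
    """Write a scalar volume with the given spacing on an axis-aligned grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(array, dtype=np.float32).T)
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
    else:
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def read_dect(
    low_path: str | Path, high_path: str | Path
) -> DectVolume:
    """Load a co-registered low/high-energy pair as a DECT volume."""
    low, spacing_l = read_volume(low_path)
    high, spacing_h = read_volume(high_path)
    if not np.allclose(spacing_l, spacing_h):
        raise ValueError(
            f"energy volumes disagree on spacing: {spacing_l} vs {spacing_h}"
        )
    return DectVolume(low, high, spacing_l)
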