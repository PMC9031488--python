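"""NIfTI round-tripping for images, masks and label maps.

Grids are axis-aligned, so the affine is diagonal: spacing on the diagonal
and the voxel-(0,0,0) center as translation. The unit tag travels in the
header ``descrip`` field.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import Grid3D, Image3D, Mask

__all__ = ["write_image", "read_image", "write_labelmap", "read_labelmap"]


def _affine(grid: Grid3D) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_from(img: nib.Nifti1Image) -> Grid3D:
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.max(np.abs(off)) > 1e-6:
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI is supported")
    diag = np.diag(aff[:3, :3])
    if np.any(diag <= 0):
        raise ValueError("negative or zero voxel spacing in affine")
    shape = img.shape
    if len(shape) != 3:
        raise ValueError(f"expected a 3-D volume, got shape {shape}")
    return Grid3D(dims=tuple(shape), spacing=tuple(diag), origin=tuple(aff[:3, 3]))


def write_image(image: Image3D, path: str | Path) -> None:
    nii = nib.Nifti1Image(image.values.astype(np.float64), _affine(image.grid))
    nii.header["descrip"] = f"unit={image.unit}".encode()[:79]
    nib.save(nii, str(path))


def read_image(path: str | Path) -> Image3D:
    nii = nib.load(str(path))
    grid = _grid_from(nii)
    descrip = bytes(nii.header["descrip"]).decode(errors="ignore")
    unit = "Bq/mL"
    if "unit=" in descrip:
        unit = descrip.split("unit=")[1].split("\x00")[0].strip()
    return Image3D(grid, np.asarray(nii.dataobj, dtype=np.float64), unit=unit)


def write_labelmap(labels: np.ndarray, grid: Grid3D, path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(grid))
    nib.save(nii, str(path))


def read_labelmap(path: str | Path) -> tuple[np.ndarray, Grid3D]:
    nii = nib.load(str(path))
    grid = _grid_from(nii)
    return np.asarray(nii.dataobj, dtype=np.int32), grid


def write_mask(mask: Mask, path: str | Path) -> None:
    write_labelmap(mask.data.astype(np.int16), mask.grid, path)


def read_mask(path: str | Path, label: str = "") -> Mask:
    labels, grid = read_labelmap(path)
    return Mask(grid, labels > 0, label=label)
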