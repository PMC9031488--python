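"""3-D resampling between grids: nearest, trilinear and tricubic spline.

All interpolation is defined on voxel-center world coordinates. A target
point is out of extent when it falls outside the source's physical
footprint (half a voxel beyond the outermost centers); such points take the
fill value. Inside the footprint but beyond the outermost centers, values
are clamped to the edge (linear/nearest) or mirrored (spline).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .grids import Grid3D, Image3D, Mask

__all__ = ["InterpMethod", "ResamplingChain", "resample_image", "resample_mask", "run_chain"]


class InterpMethod(str, Enum):
    NEAREST = "nearest"
    LINEAR = "linear"
    SPLINE = "spline"

    @classmethod
    def parse(cls, value: "InterpMethod | str") -> "InterpMethod":
        if isinstance(value, cls):
            return value
        aliases = {
            "nn": cls.NEAREST,
            "nearest": cls.NEAREST,
            "linear": cls.LINEAR,
            "l": cls.LINEAR,
            "spline": cls.SPLINE,
            "s": cls.SPLINE,
        }
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ValueError(f"unknown interpolation method {value!r}") from None


def _target_index_coords(source: Grid3D, target: Grid3D) -> list[np.ndarray]:
    """Fractional source-index coordinate of every target voxel center (per axis)."""
    return [
        (target.axis_centers(ax) - source.origin[ax]) / source.spacing[ax]
        for ax in range(3)
    ]


def resample_image(
    image: Image3D,
    target: Grid3D,
    method: InterpMethod | str = InterpMethod.LINEAR,
    fill: float = 0.0,
) -> Image3D:
    """Evaluate ``image`` at the voxel centers of ``target``.

    nearest: closest source center, ties broken toward the lower index.
    linear: trilinear over the 8 enclosing centers, edge-clamped.
    spline: interpolating cubic (order 3) with mirror boundary.
    """
    method = InterpMethod.parse(method)
    if any(d < 1 for d in target.dims):
        raise ValueError("degenerate target grid")

    axes = _target_index_coords(image.grid, target)
    # out-of-extent test against the physical footprint
    oob_1d = [
        (c < -0.5 - 1e-12) | (c > image.grid.dims[ax] - 0.5 + 1e-12)
        for ax, c in enumerate(axes)
    ]
    oob = (
        oob_1d[0][:, None, None]
        | oob_1d[1][None, :, None]
        | oob_1d[2][None, None, :]
    )

    if method is InterpMethod.NEAREST:
        # ceil(x - 0.5) rounds halves toward the lower index
        idx = [
            np.clip(np.ceil(c - 0.5).astype(np.int64), 0, image.grid.dims[ax] - 1)
            for ax, c in enumerate(axes)
        ]
        out = image.values[np.ix_(idx[0], idx[1], idx[2])]
    else:
        coords = np.meshgrid(*axes, indexing="ij")
        stack = np.stack([c.ravel() for c in coords])
        if method is InterpMethod.LINEAR:
            flat = ndimage.map_coordinates(
                image.values, stack, order=1, mode="nearest"
            )
        else:
            flat = ndimage.map_coordinates(
                image.values, stack, order=3, mode="mirror", prefilter=True
            )
        out = flat.reshape(target.dims)

    out = np.where(oob, fill, out)
    return Image3D(target, out, unit=image.unit)


def resample_mask(mask: Mask, target: Grid3D) -> Mask:
    """Nearest-neighbor transfer of a binary mask onto another grid."""
    img = Image3D(mask.grid, mask.data.astype(np.float64), unit="mask")
    res = resample_image(img, target, InterpMethod.NEAREST, fill=0.0)
    return Mask(target, res.values > 0.5, label=mask.label)


@dataclass(frozen=True)
class ResamplingChain:
    """Two-stage interpolation: acquisition grid -> CT grid -> dose grid.

    Grid spacings default to a 512-per-slice CT lattice (80 cm field of
    view / 512 = 1.5625 mm in plane) and a 256-per-slice dose lattice
    (3.125 mm in plane); slice spacing follows the input image unless grids
    are given explicitly.
    """

    stage1: InterpMethod
    stage2: InterpMethod
    ct_grid: Grid3D | None = None
    dose_grid: Grid3D | None = None
    ct_inplane_mm: float = 1.5625
    dose_inplane_mm: float = 3.125

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage1", InterpMethod.parse(self.stage1))
        object.__setattr__(self, "stage2", InterpMethod.parse(self.stage2))

    @property
    def chain_id(self) -> str:
        return f"{self.stage1.value}/{self.stage2.value}"

    def grids_for(self, image: Image3D) -> tuple[Grid3D, Grid3D]:
        z = image.grid.spacing[2]
        ct = self.ct_grid or Grid3D.covering(
            image.grid, (self.ct_inplane_mm, self.ct_inplane_mm, z)
        )
        dose = self.dose_grid or Grid3D.covering(
            ct, (self.dose_inplane_mm, self.dose_inplane_mm, ct.spacing[2])
        )
        return ct, dose


def run_chain(
    image: Image3D, chain: ResamplingChain, fill: float = 0.0
) -> tuple[Image3D, Image3D]:
    """Run both interpolation stages; returns (CT-grid image, dose-grid image).

    Both stage outputs are kept so segmentation and metrics can be evaluated
    at each grid of the planning chain.
    """
    ct_grid, dose_grid = chain.grids_for(image)
    if ct_grid.approx_equal(image.grid):
        ct_image = image.with_values(image.values.copy())
    else:
        ct_image = resample_image(image, ct_grid, chain.stage1, fill=fill)
    dose_image = resample_image(ct_image, dose_grid, chain.stage2, fill=fill)
    return ct_image, dose_image
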