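"""Voxel-lattice geometry and scalar fields.

Conventions used throughout the package:

* World coordinates are millimetres, axes are aligned with the array axes
  (no rotation / shear).
* ``origin`` is the world coordinate of the *center* of voxel ``(0, 0, 0)``.
* The physical extent of a grid is the union of voxel footprints, i.e. it
  extends half a voxel beyond the first and last voxel centers on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["Grid3D", "Image3D", "Mask"]

Triple = tuple[float, float, float]


@dataclass(frozen=True)
class Grid3D:
    """Geometry of an axis-aligned 3-D voxel lattice.

    Parameters
    ----------
    dims
        Number of voxels along each axis ``(nx, ny, nz)``.
    spacing
        Voxel size in mm along each axis; all components must be positive.
    origin
        World coordinate (mm) of the center of voxel index ``(0, 0, 0)``.
    """

    dims: tuple[int, int, int]
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(int(d) < 1 or int(d) != d for d in self.dims):
            raise ValueError(f"dims must be positive integers, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # ------------------------------------------------------------------ volume
    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    # ------------------------------------------------------------------ extent
    @property
    def extent(self) -> tuple[Triple, Triple]:
        """Physical bounding box ``(lower, upper)`` in mm (voxel footprints)."""
        lo = tuple(o - s / 2 for o, s in zip(self.origin, self.spacing))
        hi = tuple(
            o + (n - 0.5) * s
            for o, s, n in zip(self.origin, self.spacing, self.dims)
        )
        return lo, hi  # type: ignore[return-value]

    @property
    def center(self) -> Triple:
        lo, hi = self.extent
        return tuple((a + b) / 2 for a, b in zip(lo, hi))  # type: ignore[return-value]

    # ------------------------------------------------------------- coordinates
    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel index of world points (mm)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def meshgrid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense voxel-center coordinate arrays, shaped like the grid."""
        return np.meshgrid(
            self.axis_centers(0),
            self.axis_centers(1),
            self.axis_centers(2),
            indexing="ij",
        )

    # ------------------------------------------------------------ construction
    @classmethod
    def covering(
        cls, reference: "Grid3D", spacing: Iterable[float]
    ) -> "Grid3D":
        """Grid with the given ``spacing`` inscribed in ``reference``'s extent.

        The new lattice is centered on the reference extent and its own
        extent never exceeds the reference extent (dims are rounded down),
        so resampling onto it never needs out-of-extent fill values.
        """
        spacing = tuple(float(s) for s in spacing)
        lo, hi = reference.extent
        dims = tuple(
            max(1, int(np.floor((h - l) / s + 1e-9)))
            for l, h, s in zip(lo, hi, spacing)
        )
        center = reference.center
        origin = tuple(
            c - (n - 1) / 2 * s for c, n, s in zip(center, dims, spacing)
        )
        return cls(dims=dims, spacing=spacing, origin=origin)

    def approx_equal(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass
class Image3D:
    """A scalar field on a :class:`Grid3D`.

    ``unit`` tags the physical meaning of the values: ``"Bq/mL"`` for
    activity-concentration maps, ``"SUV"`` for calibrated maps.
    """

    grid: Grid3D
    values: np.ndarray
    unit: str = "Bq/mL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"value shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Image3D":
        return Image3D(self.grid, values, self.unit if unit is None else unit)

    @property
    def total_activity_mbq(self) -> float:
        """Integral of a Bq/mL field over the grid, in MBq."""
        return float(self.values.sum() * self.grid.voxel_volume_ml / 1e6)


@dataclass
class Mask:
    """A binary region on a :class:`Grid3D`."""

    grid: Grid3D
    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def volume_ml(self) -> float:
        return float(self.data.sum()) * self.grid.voxel_volume_ml

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())
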