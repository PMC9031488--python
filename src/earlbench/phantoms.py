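"""Digital phantoms: analytic geometry, activity assignment, rasterization.

The three stock configurations are a uniform calibration cylinder, a
six-sphere image-quality phantom with hot spheres over a warm background,
and a two-lesion insert phantom (a small tube plus a tube nested inside a
larger vial, giving one homogeneous and one heterogeneous lesion).

Rasterization is partial-volume aware: each voxel value is the mean
concentration over supersampled subvoxels, with overlapping primitives
resolved innermost-wins (later entries in the insert list override earlier
ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import Grid3D, Image3D, Mask

__all__ = [
    "Primitive",
    "PhantomSpec",
    "GroundTruth",
    "sphere",
    "cylinder",
    "capsule",
    "make_uniform_cylinder",
    "make_nema_spheres",
    "make_insert_phantom",
    "rasterize",
    "NEMA_DIAMETERS_MM",
]

#: Sphere diameters (mm) of the standard image-quality phantom set.
NEMA_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


@dataclass(frozen=True)
class Primitive:
    """An analytic solid with a uniform activity concentration.

    ``kind`` is one of ``sphere``, ``cylinder``, ``capsule``. ``radius``
    applies to all kinds; ``half_length`` to cylinders (half the total
    length) and capsules (half the cylindrical section); ``axis`` is a unit
    direction for elongated shapes. ``owned_volume_ml`` is the analytic
    volume that remains after innermost-wins nesting resolution; it defaults
    to the full geometric volume.
    """

    kind: str
    center: tuple[float, float, float]
    radius: float
    concentration: float  # Bq/mL
    half_length: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    label: str = ""
    owned_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder", "capsule"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.kind in ("cylinder", "capsule") and self.half_length < 0:
            raise ValueError("half_length must be non-negative")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", tuple(a / n))

    # ---------------------------------------------------------------- geometry
    @property
    def volume_ml(self) -> float:
        """Full geometric volume in mL (ignores nesting)."""
        r = self.radius
        if self.kind == "sphere":
            v = 4.0 / 3.0 * np.pi * r**3
        elif self.kind == "cylinder":
            v = np.pi * r**2 * (2 * self.half_length)
        else:  # capsule = cylinder + two hemispherical caps
            v = np.pi * r**2 * (2 * self.half_length) + 4.0 / 3.0 * np.pi * r**3
        return float(v) / 1000.0

    @property
    def analytic_volume_ml(self) -> float:
        """Volume after nesting resolution (``owned_volume_ml`` if set)."""
        return self.volume_ml if self.owned_volume_ml is None else self.owned_volume_ml

    @property
    def min_extent_mm(self) -> float:
        """Smallest span of the shape across any direction (its diameter)."""
        return 2.0 * self.radius

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        a = np.abs(np.asarray(self.axis))
        if self.kind == "sphere":
            half = np.full(3, self.radius)
        elif self.kind == "capsule":
            half = a * self.half_length + self.radius
        else:  # cylinder: conservative box
            half = a * self.half_length + self.radius
        return c - half, c + half

    def signed_distance(
        self, x: np.ndarray, y: np.ndarray, z: np.ndarray
    ) -> np.ndarray:
        """Exact signed distance to the surface (negative inside), mm."""
        dx = x - self.center[0]
        dy = y - self.center[1]
        dz = z - self.center[2]
        if self.kind == "sphere":
            return np.sqrt(dx * dx + dy * dy + dz * dz) - self.radius
        ax, ay, az = self.axis
        t = dx * ax + dy * ay + dz * az
        if self.kind == "capsule":
            tc = np.clip(t, -self.half_length, self.half_length)
            rx = dx - tc * ax
            ry = dy - tc * ay
            rz = dz - tc * az
            return np.sqrt(rx * rx + ry * ry + rz * rz) - self.radius
        # capped cylinder
        rx = dx - t * ax
        ry = dy - t * ay
        rz = dz - t * az
        d_rad = np.sqrt(rx * rx + ry * ry + rz * rz) - self.radius
        d_ax = np.abs(t) - self.half_length
        inside = np.minimum(np.maximum(d_rad, d_ax), 0.0)
        outside = np.sqrt(
            np.maximum(d_rad, 0.0) ** 2 + np.maximum(d_ax, 0.0) ** 2
        )
        return inside + outside

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Vectorized membership of world points (mm)."""
        dx = x - self.center[0]
        dy = y - self.center[1]
        dz = z - self.center[2]
        if self.kind == "sphere":
            return dx * dx + dy * dy + dz * dz <= self.radius**2
        ax, ay, az = self.axis
        t = dx * ax + dy * ay + dz * az
        if self.kind == "cylinder":
            rx = dx - t * ax
            ry = dy - t * ay
            rz = dz - t * az
            rad2 = rx * rx + ry * ry + rz * rz
            return (np.abs(t) <= self.half_length) & (rad2 <= self.radius**2)
        # capsule: distance to the axis segment
        tc = np.clip(t, -self.half_length, self.half_length)
        rx = dx - tc * ax
        ry = dy - tc * ay
        rz = dz - tc * az
        return rx * rx + ry * ry + rz * rz <= self.radius**2


def sphere(center, diameter_mm, concentration, label="") -> Primitive:
    return Primitive(
        kind="sphere",
        center=tuple(center),
        radius=diameter_mm / 2.0,
        concentration=concentration,
        label=label,
    )


def cylinder(center, radius_mm, length_mm, concentration, label="", axis=(0, 0, 1)) -> Primitive:
    return Primitive(
        kind="cylinder",
        center=tuple(center),
        radius=radius_mm,
        half_length=length_mm / 2.0,
        concentration=concentration,
        label=label,
        axis=tuple(axis),
    )


def capsule_half_length(volume_ml: float, radius_mm: float) -> float:
    """Half-length of the cylindrical section of a capsule of given volume."""
    cap_vol = 4.0 / 3.0 * np.pi * radius_mm**3
    cyl_vol = volume_ml * 1000.0 - cap_vol
    if cyl_vol < 0:
        raise ValueError("radius too large for the requested capsule volume")
    return cyl_vol / (np.pi * radius_mm**2) / 2.0


def capsule(center, radius_mm, volume_ml, concentration, label="", axis=(0, 0, 1)) -> Primitive:
    """Tube-like insert of an exact volume (radius chosen by the caller)."""
    return Primitive(
        kind="capsule",
        center=tuple(center),
        radius=radius_mm,
        half_length=capsule_half_length(volume_ml, radius_mm),
        concentration=concentration,
        label=label,
        axis=tuple(axis),
    )


@dataclass
class PhantomSpec:
    """Background region plus an ordered list of inserts.

    Insert order encodes nesting priority: later entries win where shapes
    overlap, so an inner tube must be listed after its host vial.
    """

    name: str
    background: Primitive
    inserts: list[Primitive] = field(default_factory=list)
    background_volume_ml: float | None = None

    def __post_init__(self) -> None:
        for ins in self.inserts:
            if ins.analytic_volume_ml <= 0:
                raise ValueError(f"insert {ins.label!r} has non-positive volume")
            blo, bhi = self.background.bounding_box()
            ilo, ihi = ins.bounding_box()
            if np.any(ilo < blo - 1e-9) or np.any(ihi > bhi + 1e-9):
                raise ValueError(
                    f"insert {ins.label!r} extends beyond the background region"
                )

    @property
    def total_volume_ml(self) -> float:
        if self.background_volume_ml is not None:
            return self.background_volume_ml
        return self.background.volume_ml

    def default_grid(self, spacing_mm: float = 1.0, margin_mm: float = 10.0) -> Grid3D:
        """Isotropic grid covering the background region plus a margin."""
        lo, hi = self.background.bounding_box()
        lo = lo - margin_mm
        hi = hi + margin_mm
        dims = tuple(int(np.ceil((h - l) / spacing_mm)) for l, h in zip(lo, hi))
        origin = tuple(float(l) + spacing_mm / 2.0 for l in lo)
        return Grid3D(dims=dims, spacing=(spacing_mm,) * 3, origin=origin)


@dataclass
class GroundTruth:
    """Rasterized activity map plus per-insert masks and analytic bookkeeping."""

    image: Image3D
    masks: dict[str, Mask]
    analytic_volumes_ml: dict[str, float]
    concentrations: dict[str, float]
    spec: PhantomSpec
    supersampling: int

    def mask(self, label: str) -> Mask:
        return self.masks[label]


# --------------------------------------------------------------------- stock


def make_uniform_cylinder(
    total_activity_mbq: float,
    volume_ml: float,
    radius_mm: float | None = None,
    name: str = "uniform-cylinder",
) -> PhantomSpec:
    """Uniform calibration cylinder: one activity uniformly distributed.

    Concentration is ``total_activity / volume``; e.g. 70 MBq in 6000 mL
    gives 11.667 kBq/mL.
    """
    if total_activity_mbq <= 0:
        raise ValueError("total activity must be positive")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    conc = total_activity_mbq * 1e6 / volume_ml  # Bq/mL
    if radius_mm is None:
        # aspect ratio ~ length = 1.55 * diameter, loosely torso-like
        radius_mm = float((volume_ml * 1000.0 / (np.pi * 2 * 1.55 * 2)) ** (1.0 / 3.0))
    length_mm = volume_ml * 1000.0 / (np.pi * radius_mm**2)
    bg = cylinder((0, 0, 0), radius_mm, length_mm, conc, label="background")
    return PhantomSpec(name=name, background=bg, background_volume_ml=volume_ml)


def make_nema_spheres(
    background_conc: float,
    contrast: float = 10.0,
    diameters_mm: tuple[float, ...] = NEMA_DIAMETERS_MM,
    ring_radius_mm: float = 57.2,
    name: str = "nema-spheres",
) -> PhantomSpec:
    """Hot spheres on a circle in one axial plane over a warm background.

    ``contrast`` is the sphere-to-background concentration ratio (10 in the
    accreditation protocol). A contrast of exactly 1 makes recovery
    undefined downstream and is rejected here.
    """
    if background_conc < 0:
        raise ValueError("background concentration must be non-negative")
    if contrast <= 1:
        raise ValueError(
            "contrast must exceed 1; spheres at background concentration make "
            "recovery coefficients undefined"
        )
    if any(d <= 0 for d in diameters_mm):
        raise ValueError("sphere diameters must be positive")

    n = len(diameters_mm)
    angles = 2 * np.pi * np.arange(n) / n
    centers = [
        (ring_radius_mm * np.cos(a), ring_radius_mm * np.sin(a), 0.0) for a in angles
    ]
    spheres = [
        sphere(c, d, contrast * background_conc, label=f"sphere-{d:g}mm")
        for c, d in zip(centers, diameters_mm)
    ]
    # reject overlap
    for i in range(n):
        for j in range(i + 1, n):
            dist = np.linalg.norm(np.subtract(centers[i], centers[j]))
            if dist <= (diameters_mm[i] + diameters_mm[j]) / 2.0:
                raise ValueError(
                    f"spheres {i} and {j} overlap (centers {dist:.1f} mm apart)"
                )
    bg_radius = ring_radius_mm + max(diameters_mm) / 2.0 + 15.0
    bg_length = max(diameters_mm) + 40.0
    bg = cylinder((0, 0, 0), bg_radius, bg_length, background_conc, label="background")
    return PhantomSpec(name=name, background=bg, inserts=spheres)


def make_insert_phantom(
    v1_volume_ml: float = 0.3,
    v1_activity_mbq: float = 0.116,
    v3_volume_ml: float = 2.0,
    v3_activity_mbq: float = 0.1,
    v2_volume_ml: float = 0.3,
    v2_concentration: float | None = None,
    background_conc: float = 0.0,
    name: str = "insert-phantom",
) -> PhantomSpec:
    """Two-lesion anthropomorphic insert set.

    V1 is a 0.3 mL tube on its own (homogeneous lesion). V2 is an identical
    0.3 mL tube nested inside the 2 mL vial V3, so the combined V2+V3
    structure occupies 2.3 mL with heterogeneous uptake. V2's concentration
    is configurable; it defaults to twice V3's so the nested tube reads
    hotter than its host.
    """
    v1_conc = v1_activity_mbq * 1e6 / v1_volume_ml
    v3_conc = v3_activity_mbq * 1e6 / v3_volume_ml
    if v2_concentration is None:
        v2_concentration = 2.0 * v3_conc

    # centers slightly off the lattice symmetry axes so that voxel coverage
    # fractions don't sit exactly on the 0.5 majority knife-edge
    v1 = capsule((-15.3, 0.2, 0.1), 3.5, v1_volume_ml, v1_conc, label="V1")
    # V3's outer shape holds the vial liquid (v3_volume) plus the nested tube.
    outer_volume = v3_volume_ml + v2_volume_ml
    v3_radius = 5.0
    v3_length = outer_volume * 1000.0 / (np.pi * v3_radius**2)
    # a slight tilt keeps the vial's flat caps off the lattice planes, which
    # would otherwise flip whole end-cap discs in or out of the voxel mask
    tilt = (0.12, 0.07, 1.0)
    v3 = Primitive(
        kind="cylinder",
        center=(10.2, -0.1, 0.3),
        radius=v3_radius,
        half_length=v3_length / 2.0,
        concentration=v3_conc,
        label="V3",
        owned_volume_ml=v3_volume_ml,
        axis=tilt,
    )
    v2 = capsule(v3.center, 3.5, v2_volume_ml, v2_concentration, label="V2", axis=tilt)

    bg = cylinder((0.0, 0.0, 0.0), 32.0, 64.0, background_conc, label="background")
    return PhantomSpec(name=name, background=bg, inserts=[v1, v3, v2])


# ----------------------------------------------------------------- rasterize


def _classify_voxels(
    grid: Grid3D, prims: list[Primitive]
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse ownership at voxel centers plus a boundary-voxel flag.

    A voxel is 'boundary' when its center lies within half a voxel diagonal
    of any primitive surface; everywhere else the center's ownership is the
    ownership of the whole voxel, exactly.
    """
    half_diag = 0.5 * float(np.linalg.norm(grid.spacing))
    owner = np.zeros(grid.dims, dtype=np.int16)
    boundary = np.zeros(grid.dims, dtype=bool)
    axes = [grid.axis_centers(ax) for ax in range(3)]
    for k, prim in enumerate(prims):
        lo, hi = prim.bounding_box()
        sl = []
        for ax in range(3):
            i0, i1 = np.searchsorted(
                axes[ax], [lo[ax] - half_diag - 1e-9, hi[ax] + half_diag + 1e-9]
            )
            sl.append(slice(int(i0), int(i1)))
        if any(s.start >= s.stop for s in sl):
            continue
        sdf = prim.signed_distance(
            axes[0][sl[0], None, None],
            axes[1][None, sl[1], None],
            axes[2][None, None, sl[2]],
        )
        sub_owner = owner[tuple(sl)]
        sub_owner[sdf <= 0] = k + 1
        boundary[tuple(sl)] |= np.abs(sdf) < half_diag
    return owner, boundary


def rasterize(spec: PhantomSpec, grid: Grid3D, supersampling: int = 4) -> GroundTruth:
    """Voxelize a phantom spec with partial-volume averaging.

    Conceptually every voxel is subdivided ``supersampling`` times per axis;
    each subvoxel takes the concentration of the innermost primitive
    containing it (later inserts override earlier ones, background lowest
    priority) and the voxel value is the subvoxel mean. Per-insert masks
    follow majority subvoxel ownership (fraction >= 0.5), which keeps them
    disjoint by construction. Voxels farther than half a voxel diagonal
    from every surface are classified exactly from their center, so only
    boundary voxels are actually supersampled. Deterministic throughout.
    """
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    s = int(supersampling)

    for ins in spec.inserts:
        if ins.min_extent_mm < 2.0 * max(grid.spacing):
            warnings.warn(
                f"insert {ins.label!r} spans fewer than 2 voxels on the "
                f"coarsest axis of the target grid",
                stacklevel=2,
            )

    prims = [spec.background, *spec.inserts]
    conc_table = np.array([0.0] + [p.concentration for p in prims])

    owner, boundary = _classify_voxels(grid, prims)
    values = conc_table[owner]
    own_frac = [
        (owner == k + 2).astype(np.float64) for k in range(len(spec.inserts))
    ]

    bidx = np.argwhere(boundary)
    if len(bidx) > 0 and s >= 1:
        # subvoxel center offsets within one voxel, in mm
        offs = [
            ((np.arange(s) + 0.5) / s - 0.5) * grid.spacing[ax] for ax in range(3)
        ]
        ox, oy, oz = np.meshgrid(*offs, indexing="ij")
        offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s^3, 3)
        n_sub = len(offsets)
        chunk = max(1, int(4e6 / n_sub))
        for c0 in range(0, len(bidx), chunk):
            sub = bidx[c0 : c0 + chunk]
            centers = grid.index_to_world(sub)  # (m, 3)
            pts = centers[:, None, :] + offsets[None, :, :]  # (m, s^3, 3)
            sub_owner = np.zeros(pts.shape[:2], dtype=np.int16)
            for k, prim in enumerate(prims):
                inside = prim.contains(pts[..., 0], pts[..., 1], pts[..., 2])
                sub_owner[inside] = k + 1
            tgt = tuple(sub.T)
            values[tgt] = conc_table[sub_owner].mean(axis=1)
            for k in range(len(spec.inserts)):
                own_frac[k][tgt] = (sub_owner == k + 2).mean(axis=1)

    image = Image3D(grid, values, unit="Bq/mL")
    # majority ownership; exact 50/50 splits go to the inner (later) insert
    masks = {}
    if spec.inserts:
        stack = np.stack(own_frac)
        winner = (len(own_frac) - 1) - np.argmax(stack[::-1], axis=0)
        for k, ins in enumerate(spec.inserts):
            data = (winner == k) & (own_frac[k] >= 0.5)
            masks[ins.label] = Mask(grid, data, label=ins.label)
    analytic = {ins.label: ins.analytic_volume_ml for ins in spec.inserts}
    concs = {ins.label: ins.concentration for ins in spec.inserts}
    return GroundTruth(
        image=image,
        masks=masks,
        analytic_volumes_ml=analytic,
        concentrations=concs,
        spec=spec,
        supersampling=s,
    )
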