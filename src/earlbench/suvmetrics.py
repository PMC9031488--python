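"""SUV statistics, recovery coefficients, and acceptance-range checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid3D, Image3D, Mask
from .phantoms import GroundTruth
from .resample import resample_mask

__all__ = [
    "VOI",
    "SUVStats",
    "RCRecord",
    "RCLimits",
    "EARL1_LIMITS",
    "EARL2_LIMITS",
    "suv_stats",
    "sphere_voi",
    "recovery_coefficients",
    "check_limits",
    "uniformity_check",
]


@dataclass
class VOI(Mask):
    """A labeled binary volume of interest with provenance metadata."""

    provenance: str = "manual"  # analytic | segmentation | manual

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.is_empty:
            raise ValueError("VOI must be non-empty")


@dataclass(frozen=True)
class SUVStats:
    suvmax: float
    suvmean: float
    suvpeak: float | None
    voi_volume_ml: float
    peak_center_mm: tuple[float, float, float] | None = None


@dataclass
class RCRecord:
    """Recovery of one insert: measured metric / actual value, per metric."""

    label: str
    actual: float
    rc_max: float
    rc_mean: float
    rc_peak: float | None
    voi_volume_ml: float
    status: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RCLimits:
    """Inclusive acceptance interval for recovery coefficients."""

    protocol: str
    metric: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def classify(self, rc: float) -> str:
        if rc < self.lower:
            return "below"
        if rc > self.upper:
            return "above"
        return "in"


EARL1_LIMITS = RCLimits("EARL1", "mean", 0.27, 0.43)
EARL2_LIMITS = RCLimits("EARL2", "mean", 0.39, 0.61)


def sphere_voi(grid: Grid3D, center_mm, diameter_mm: float, label: str = "") -> VOI:
    """Voxels whose centers lie within a world-space sphere."""
    x, y, z = grid.meshgrid_world()
    c = np.asarray(center_mm, dtype=float)
    r2 = (diameter_mm / 2.0) ** 2
    inside = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r2
    return VOI(grid, inside, label=label, provenance="analytic")


def _sphere_offsets(grid: Grid3D, diameter_mm: float) -> np.ndarray:
    """Voxel-index offsets whose center-to-center distance is within radius."""
    r = diameter_mm / 2.0
    reach = [int(np.floor(r / s)) for s in grid.spacing]
    ox, oy, oz = np.meshgrid(
        *[np.arange(-n, n + 1) for n in reach], indexing="ij"
    )
    d2 = (
        (ox * grid.spacing[0]) ** 2
        + (oy * grid.spacing[1]) ** 2
        + (oz * grid.spacing[2]) ** 2
    )
    keep = d2 <= r * r
    return np.stack([ox[keep], oy[keep], oz[keep]], axis=1)


def suv_stats(image: Image3D, voi: VOI, peak_diameter_mm: float = 12.0) -> SUVStats:
    """Max, mean, and peak statistics of an image over a VOI.

    The peak is the highest sphere-mean over candidate spheres centered on
    every VOI voxel center; sphere membership is voxel-center-in-sphere in
    world mm, so anisotropic grids are handled correctly. Voxels of a
    candidate sphere that fall outside the image are simply not part of the
    mean (the divisor is the in-image voxel count).
    """
    if image.grid.dims != voi.grid.dims or not image.grid.approx_equal(voi.grid):
        raise ValueError("image and VOI must share a grid")
    vals = image.values[voi.data]
    suvmax = float(vals.max())
    suvmean = float(vals.mean())

    offsets = _sphere_offsets(image.grid, peak_diameter_mm)
    if len(offsets) == 0:
        return SUVStats(suvmax, suvmean, None, voi.volume_ml, None)

    centers = np.argwhere(voi.data)
    dims = np.asarray(image.grid.dims)
    ravel = image.values.ravel()
    chunk = max(1, int(2e6 / len(offsets)))
    best_mean = -np.inf
    best_center = centers[0]
    for i0 in range(0, len(centers), chunk):
        sub = centers[i0 : i0 + chunk]
        cand = sub[:, None, :] + offsets[None, :, :]  # (nc, noff, 3)
        inside = np.all((cand >= 0) & (cand < dims), axis=2)
        flat = (
            cand[..., 0] * (dims[1] * dims[2]) + cand[..., 1] * dims[2] + cand[..., 2]
        )
        flat = np.where(inside, flat, 0)
        sums = np.where(inside, ravel[flat], 0.0).sum(axis=1)
        means = sums / inside.sum(axis=1)
        j = int(np.argmax(means))
        if means[j] > best_mean:
            best_mean = float(means[j])
            best_center = sub[j]
    peak_center = tuple(float(c) for c in image.grid.index_to_world(best_center))
    return SUVStats(suvmax, suvmean, best_mean, voi.volume_ml, peak_center)


def recovery_coefficients(
    image: Image3D,
    truth: GroundTruth,
    voi_policy: str = "analytic",
    threshold_fraction: float = 0.41,
    peak_diameter_mm: float = 12.0,
) -> list[RCRecord]:
    """Per-insert recovery: measured statistic divided by actual value.

    ``voi_policy`` selects how the measurement VOI is obtained: ``analytic``
    transfers each ground-truth mask to the image grid (nearest neighbor);
    ``threshold`` keeps voxels above ``threshold_fraction`` of the local max
    within the transferred mask's bounding region.

    The image must be in the same unit family as the ground truth
    (RC is a ratio, so a consistent global rescale cancels).
    """
    if voi_policy not in ("analytic", "threshold"):
        raise ValueError(f"unknown VOI policy {voi_policy!r}")
    records: list[RCRecord] = []
    for label, mask in truth.masks.items():
        actual = truth.concentrations[label]
        if actual <= 0:
            raise ValueError(f"insert {label!r} has zero actual concentration")
        tmask = resample_mask(mask, image.grid)
        if tmask.is_empty:
            raise ValueError(
                f"insert {label!r} vanished on the image grid; grid too coarse"
            )
        if voi_policy == "threshold":
            level = threshold_fraction * float(image.values[tmask.data].max())
            data = tmask.data & (image.values >= level)
            tmask = Mask(image.grid, data, label=label)
        voi = VOI(image.grid, tmask.data, label=label, provenance=voi_policy)
        stats = suv_stats(image, voi, peak_diameter_mm)
        records.append(
            RCRecord(
                label=label,
                actual=actual,
                rc_max=stats.suvmax / actual,
                rc_mean=stats.suvmean / actual,
                rc_peak=None if stats.suvpeak is None else stats.suvpeak / actual,
                voi_volume_ml=voi.volume_ml,
            )
        )
    return records


def check_limits(records: list[RCRecord], limits: RCLimits) -> dict:
    """Flag each record against an inclusive RC interval; overall = all in."""
    metric_attr = {"max": "rc_max", "mean": "rc_mean", "peak": "rc_peak"}[limits.metric]
    rows = []
    for rec in records:
        rc = getattr(rec, metric_attr)
        status = "undefined" if rc is None else limits.classify(rc)
        rec.status[limits.metric] = status
        rows.append({"label": rec.label, "rc": rc, "status": status})
    overall = all(r["status"] == "in" for r in rows)
    return {
        "protocol": limits.protocol,
        "metric": limits.metric,
        "lower": limits.lower,
        "upper": limits.upper,
        "records": rows,
        "pass": overall,
    }


def uniformity_check(image: Image3D, central_voi: VOI, tolerance: float = 0.10) -> dict:
    """Mean SUV over a central region against the expected value of 1."""
    if image.unit != "SUV":
        raise ValueError("uniformity check expects an SUV image")
    mean = float(image.values[central_voi.data].mean())
    return {
        "suvmean": mean,
        "expected": 1.0,
        "tolerance": tolerance,
        "pass": abs(mean - 1.0) <= tolerance,
    }
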