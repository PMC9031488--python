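"""Scoring of segmented volumes against ground truth.

Volumes, signed percent deviations, Jaccard shape coefficients, cumulative
(product) shape scores per interpolation chain, and the chain-selection
rule that trades cumulative shape against volume deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grids import Grid3D, Mask
from .resample import resample_mask

__all__ = [
    "VolumeRecord",
    "ShapeRecord",
    "ChainScore",
    "volume_of",
    "percent_deviation",
    "format_deviation",
    "shape_coefficient",
    "cumulative_sc",
    "select_chain",
]


def volume_of(mask: Mask) -> float:
    """Voxel count times voxel volume, in mL."""
    return mask.volume_ml


def percent_deviation(measured_ml: float, actual_ml: float) -> float:
    """Signed percent deviation: positive means oversegmentation."""
    if actual_ml <= 0:
        raise ValueError("actual volume must be positive")
    return 100.0 * (measured_ml - actual_ml) / actual_ml


def _round_half_away(x: float, decimals: int = 0) -> float:
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


def format_deviation(dev_percent: float) -> str:
    """Report style: integer percent at |dev| >= 1%, one decimal below."""
    if abs(dev_percent) >= 1.0:
        val = _round_half_away(dev_percent)
        return f"{val:+.0f}%"
    return f"{_round_half_away(dev_percent, 1):+.1f}%"


def rounded_deviation(measured_ml: float, actual_ml: float) -> float:
    """Numeric deviation rounded the way reports print it."""
    dev = percent_deviation(measured_ml, actual_ml)
    return _round_half_away(dev) if abs(dev) >= 1.0 else _round_half_away(dev, 1)


@dataclass(frozen=True)
class VolumeRecord:
    label: str
    measured_ml: float
    actual_ml: float

    @property
    def deviation_percent(self) -> float:
        return percent_deviation(self.measured_ml, self.actual_ml)

    @property
    def deviation_str(self) -> str:
        return format_deviation(self.deviation_percent)


@dataclass(frozen=True)
class ShapeRecord:
    label: str
    sc: float
    comparison_grid: Grid3D
    pair: tuple[str, str] = ("", "")


def shape_coefficient(mask_a: Mask, mask_b: Mask) -> float:
    """Intersection over union of two binary volumes.

    Masks on different grids are transferred by nearest neighbor onto the
    finer grid of the pair (smaller voxel volume) before comparison.
    Undefined (NaN) when both masks are empty.
    """
    if not mask_a.grid.approx_equal(mask_b.grid):
        if mask_b.grid.voxel_volume_mm3 < mask_a.grid.voxel_volume_mm3:
            mask_a = resample_mask(mask_a, mask_b.grid)
        else:
            mask_b = resample_mask(mask_b, mask_a.grid)
    inter = np.logical_and(mask_a.data, mask_b.data).sum()
    union = np.logical_or(mask_a.data, mask_b.data).sum()
    if union == 0:
        return float("nan")
    return float(inter) / float(union)


def cumulative_sc(scores: list[float]) -> float:
    """Product of shape coefficients over structures/stages."""
    if len(scores) == 0:
        raise ValueError("no scores to combine")
    if any(s < 0 or s > 1 for s in scores):
        raise ValueError("shape coefficients must lie in [0, 1]")
    return float(np.prod(scores))


@dataclass
class ChainScore:
    """Aggregated quality of one two-stage interpolation chain."""

    chain_id: str
    shape_scores: dict[str, float] = field(default_factory=dict)
    volume_records: list[VolumeRecord] = field(default_factory=list)

    @property
    def cumulative(self) -> float:
        return cumulative_sc(list(self.shape_scores.values()))

    @property
    def mean_abs_deviation(self) -> float:
        if not self.volume_records:
            return float("nan")
        return float(
            np.mean([abs(r.deviation_percent) for r in self.volume_records])
        )


def select_chain(scores: list[ChainScore], tie_tolerance: float = 0.10) -> ChainScore:
    """Pick the best chain: highest cumulative SC, deviation breaks near-ties.

    Chains whose cumulative SC is within ``tie_tolerance`` (relative) of the
    best are considered tied and ranked by smaller mean absolute volume
    deviation; exact ties keep the earliest chain in the input order.
    """
    if not scores:
        raise ValueError("no chains to select from")
    best_sc = max(s.cumulative for s in scores)
    candidates = [
        s for s in scores if s.cumulative >= best_sc * (1.0 - tie_tolerance)
    ]
    ranked = sorted(
        enumerate(candidates),
        key=lambda kv: (
            kv[1].mean_abs_deviation
            if not math.isnan(kv[1].mean_abs_deviation)
            else float("inf"),
            -kv[1].cumulative,
            kv[0],
        ),
    )
    return ranked[0][1]
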