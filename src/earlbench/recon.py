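"""Protocol emulation: Gaussian resolution loss, detector-grid binning, SUV.

The vendor iterative algorithms are deliberately replaced by a single
isotropic Gaussian kernel applied on the fine truth grid, followed by
box-mean binning onto the protocol grid. The blur happens *before*
downsampling so small structures are degraded, never aliased, and binning
by footprint mean preserves total activity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grids import Grid3D, Image3D

__all__ = [
    "ReconProtocol",
    "SUVCalibration",
    "EARL1",
    "EARL2",
    "PROTOCOLS",
    "emulate_recon",
    "to_suv",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class ReconProtocol:
    """An emulation recipe: post-filter width, target grid spacing, noise."""

    name: str
    psf_fwhm_mm: float
    grid_spacing_mm: tuple[float, float, float]
    noise_sigma: float = 0.0  # std as a fraction of the background level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if any(s <= 0 for s in self.grid_spacing_mm):
            raise ValueError("grid spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def target_grid(self, fine: Grid3D) -> Grid3D:
        """Protocol grid inscribed in (and centered on) the fine grid extent."""
        return Grid3D.covering(fine, self.grid_spacing_mm)

    def with_noise(self, sigma: float, seed: int = 0) -> "ReconProtocol":
        return replace(self, noise_sigma=sigma, seed=seed)


EARL1 = ReconProtocol("EARL1", psf_fwhm_mm=6.0, grid_spacing_mm=(3.1819, 3.1819, 5.0))
EARL2 = ReconProtocol("EARL2", psf_fwhm_mm=5.0, grid_spacing_mm=(1.5910, 1.5910, 1.5))
PROTOCOLS = {"EARL1": EARL1, "EARL2": EARL2}


@dataclass(frozen=True)
class SUVCalibration:
    """Body-weight SUV normalization.

    SUV = concentration[Bq/mL] * mass[g] / activity[Bq]; a uniform phantom
    with concentration = activity / volume and unit density yields SUV = 1.
    """

    injected_activity_mbq: float
    normalization_mass_kg: float

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if self.normalization_mass_kg <= 0:
            raise ValueError("normalization mass must be positive")

    @property
    def scale(self) -> float:
        """Multiplier taking Bq/mL to SUV."""
        mass_g = self.normalization_mass_kg * 1000.0
        activity_bq = self.injected_activity_mbq * 1e6
        return mass_g / activity_bq


def _box_mean_downsample(image: Image3D, target: Grid3D) -> Image3D:
    """Mean of fine-voxel values over each target voxel footprint.

    Fine voxels are assigned to the target voxel whose footprint contains
    their center; fine voxels outside the target extent are dropped.
    """
    grid = image.grid
    bins = []
    valid = []
    for ax in range(3):
        centers = grid.axis_centers(ax)
        lo = target.origin[ax] - target.spacing[ax] / 2.0
        b = np.floor((centers - lo) / target.spacing[ax]).astype(np.int64)
        ok = (b >= 0) & (b < target.dims[ax])
        bins.append(b)
        valid.append(ok)

    nx, ny, nz = target.dims
    lin = (
        bins[0][:, None, None] * (ny * nz)
        + bins[1][None, :, None] * nz
        + bins[2][None, None, :]
    )
    ok = valid[0][:, None, None] & valid[1][None, :, None] & valid[2][None, None, :]
    lin_ok = lin[ok]
    sums = np.bincount(lin_ok, weights=image.values[ok], minlength=nx * ny * nz)
    counts = np.bincount(lin_ok, minlength=nx * ny * nz)
    if np.any(counts == 0):
        raise ValueError("target grid has voxels not covered by the source grid")
    out = (sums / counts).reshape(target.dims)
    return Image3D(target, out, unit=image.unit)


def emulate_recon(
    truth: Image3D,
    protocol: ReconProtocol,
    background_value: float = 0.0,
    target_grid: Grid3D | None = None,
) -> Image3D:
    """Degrade a fine-grid truth image to a protocol's resolution and grid.

    The truth is convolved with an isotropic Gaussian of the protocol FWHM
    (constant-background padding at the field edge), box-mean binned to the
    protocol grid, optionally perturbed by seeded zero-mean Gaussian noise,
    and clipped at zero.
    """
    if target_grid is None:
        target_grid = protocol.target_grid(truth.grid)
    for ax in range(3):
        if truth.grid.spacing[ax] > target_grid.spacing[ax] + 1e-9:
            raise ValueError(
                f"truth grid ({truth.grid.spacing[ax]:g} mm on axis {ax}) is "
                f"coarser than the protocol grid "
                f"({target_grid.spacing[ax]:g} mm); refusing to fabricate "
                f"resolution"
            )

    if protocol.psf_fwhm_mm > 0:
        sigma_vox = [
            protocol.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in truth.grid.spacing
        ]
        blurred = ndimage.gaussian_filter(
            truth.values, sigma=sigma_vox, mode="constant", cval=background_value
        )
    else:
        blurred = truth.values
    out = _box_mean_downsample(Image3D(truth.grid, blurred, truth.unit), target_grid)

    if protocol.noise_sigma > 0:
        rng = np.random.default_rng(protocol.seed)
        level = background_value if background_value > 0 else float(out.values.mean())
        noise = rng.normal(0.0, protocol.noise_sigma * level, size=out.values.shape)
        out = out.with_values(out.values + noise)
    return out.with_values(np.clip(out.values, 0.0, None))


def to_suv(image: Image3D, cal: SUVCalibration) -> Image3D:
    """Linear rescale of an activity-concentration image to SUV units."""
    if image.unit == "SUV":
        raise ValueError("image is already in SUV units")
    return Image3D(image.grid, image.values * cal.scale, unit="SUV")
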