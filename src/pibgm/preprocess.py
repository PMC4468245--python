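"""PET-to-CT grid upsampling and PET-mask-based bed removal.

The acquisition grids differ: CT slices are 512x512, PET 168x168.  The
default upsampling replicates each PET pixel into a 3x3 block (168 -> 504)
and pads the four sides with an equal zero border to reach the CT size --
value-preserving, sum-preserving up to the x9 factor, and exactly invertible
by 3x3 block mode on the unpadded core.  A trilinear variant is provided as
well for users who want a smooth interpolant.

Bed removal exploits the fact that the scanner bed absorbs X-rays (it shows
in CT) but emits nothing (it cannot show in PET): a heavily smoothed,
thresholded PET volume yields the body outline, and CT voxels outside it are
replaced by air (-1000 HU).  Filling with air rather than multiplying by a
{0,1} mask matters: HU * 0 = 0 HU reads as water and would plant a spurious
soft-tissue mode in the downstream intensity histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigError, EmptyMaskError
from .volume import RegionMask, Volume3D, check_same_grid

AIR_HU = -1000.0


@dataclass
class BedRemovalParams:
    """Parameters of the PET-driven body-outline extraction."""

    smooth_sigma: float = 2.0            # voxels; 0 disables smoothing
    body_threshold_mode: str = "fraction_of_max"   # or "otsu"
    fraction: float = 0.01               # of the smoothed maximum
    fill_holes: bool = True
    keep_largest_component: bool = True
    background_fill: float = AIR_HU      # HU written outside the body

    def validate(self) -> None:
        if self.smooth_sigma < 0:
            raise ConfigError("smooth_sigma must be >= 0")
        if self.body_threshold_mode not in ("fraction_of_max", "otsu"):
            raise ConfigError(
                f"unknown body_threshold_mode {self.body_threshold_mode!r}")
        if not 0.0 < self.fraction < 1.0:
            raise ConfigError("fraction must be in (0,1)")


def upsample_pet_replicate(pet: Volume3D, target_inplane: int) -> Volume3D:
    """Replicate each in-plane pixel into a 3x3 block, then zero-pad to target.

    The slice count is unchanged; in-plane spacing is divided by 3.  Requires
    3*size <= target and an even padding total (so the border is symmetric).
    """
    ns, nr, nc = pet.shape
    if nr != nc:
        raise ConfigError(f"replicate upsampling expects square slices, got {nr}x{nc}")
    core = 3 * nr
    if core > target_inplane:
        raise ConfigError(
            f"3x{nr} = {core} exceeds target in-plane size {target_inplane}")
    leftover = target_inplane - core
    if leftover % 2 != 0:
        raise ConfigError(
            f"padding {leftover} is odd: cannot pad all four sides equally "
            f"(target {target_inplane}, replicated core {core})")
    pad = leftover // 2
    up = np.kron(pet.data, np.ones((1, 3, 3)))
    up = np.pad(up, ((0, 0), (pad, pad), (pad, pad)))
    spacing = (pet.spacing[0], pet.spacing[1] / 3.0, pet.spacing[2] / 3.0)
    affine = np.asarray(pet.affine, dtype=float).copy()
    affine[1, 1], affine[2, 2] = spacing[1], spacing[2]
    # keep the first original voxel centre fixed: the replicated block centre
    # of source voxel 0 sits at fine index pad+1.
    affine[1, 3] = pet.affine[1, 3] + pet.affine[1, 1] * 0 - spacing[1] * (pad + 1)
    affine[2, 3] = pet.affine[2, 3] - spacing[2] * (pad + 1)
    return Volume3D(up, spacing, pet.unit, affine)


def upsample_pet_trilinear(pet: Volume3D, target_grid: tuple[int, int, int]) -> Volume3D:
    """Trilinear interpolation onto a finer grid (corner-aligned sampling)."""
    src = pet.shape
    if any(t < s for t, s in zip(target_grid, src)):
        raise ConfigError(f"target grid {target_grid} is coarser than source {src}")
    if any(s < 2 for s in src):
        raise ConfigError(f"degenerate source axis in shape {src}: need >= 2 voxels")
    coords = np.meshgrid(
        *[np.linspace(0.0, s - 1.0, t) for s, t in zip(src, target_grid)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(pet.data, np.stack(coords), order=1, mode="nearest")
    spacing = tuple(sp * (s - 1) / (t - 1) for sp, s, t in zip(pet.spacing, src, target_grid))
    return Volume3D(data, spacing, pet.unit)


def body_mask_from_pet(pet: Volume3D, params: BedRemovalParams | None = None) -> RegionMask:
    """Binary body mask from PET: smooth, threshold, clean up.

    Raises :class:`EmptyMaskError` (naming the threshold) if no voxel
    survives.  With ``fraction_of_max`` the mask is invariant to positive
    rescaling of the PET values.
    """
    params = params or BedRemovalParams()
    params.validate()
    if np.any(pet.data < 0):
        raise ConfigError("body_mask_from_pet expects non-negative PET values")
    sm = (ndimage.gaussian_filter(pet.data, params.smooth_sigma)
          if params.smooth_sigma > 0 else pet.data)
    if params.body_threshold_mode == "fraction_of_max":
        thr = params.fraction * float(sm.max())
        if thr <= 0:
            raise EmptyMaskError(
                f"empty body mask: smoothed PET maximum is 0, threshold {thr}")
    else:
        thr = float(threshold_otsu(sm))
    mask = sm > thr
    if not mask.any():
        raise EmptyMaskError(f"empty body mask at threshold {thr:.6g}")
    if params.keep_largest_component:
        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            mask = lab == int(np.argmax(sizes))
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return RegionMask.like(pet, mask.astype(np.int16))


def remove_bed(ct: Volume3D, body: RegionMask,
               background_fill: float = AIR_HU) -> Volume3D:
    """Replace CT values outside the body by ``background_fill`` (air).

    Values inside the body are bit-identical to the input; the operation is
    idempotent.
    """
    check_same_grid(ct, body, "CT and body mask")
    out = np.where(body.as_bool(), ct.data, background_fill)
    return ct.with_data(out)
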