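"""Dull Razor-style hair removal.

Hairs are thin dark curvilinear structures: a grayscale morphological closing
with a linear structuring element longer than the hair width fills them in,
so the closing-minus-original residual is large exactly on hair pixels.  The
residual is taken as the maximum over several element orientations to catch
arbitrarily curved hairs, thresholded, dilated, and the flagged pixels are
replaced from their nearest unflagged neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk

__all__ = ["HairRemovalParams", "detect_hair_mask", "remove_hair", "luminance"]


@dataclass(frozen=True)
class HairRemovalParams:
    se_length: int = 11
    se_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    diff_threshold: float = 10.0
    mask_dilation: int = 1
    #: median prefilter width on the luminance; suppresses pixel noise that
    #: would otherwise swamp the closing residual (hairs are wider, they
    #: survive).  0 disables.
    median_prefilter: int = 3
    #: minimum connected-component size (pre-dilation) for a residual blob to
    #: count as hair — real hairs are long curvilinear structures, so this
    #: rejects short boundary/noise fragments.  0 disables.
    min_component_size: int = 50
    #: Gaussian sigma smoothing the replacement values inside the mask; kills
    #: the seam the nearest-neighbour fill leaves along the hair spine.
    fill_smooth_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.se_length < 3 or self.se_length % 2 == 0:
            raise ValueError("se_length must be odd and >= 3")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be > 0")
        if self.mask_dilation < 0:
            raise ValueError("mask_dilation must be >= 0")


def luminance(rgb_image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma, float64 on the 0-255 scale."""
    img = np.asarray(rgb_image, dtype=np.float64)
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Binary line footprint of given length through the centre pixel."""
    c = length // 2
    dy = -np.sin(np.deg2rad(angle_deg))
    dx = np.cos(np.deg2rad(angle_deg))
    r0 = int(round(c - dy * c))
    c0 = int(round(c - dx * c))
    r1 = int(round(c + dy * c))
    c1 = int(round(c + dx * c))
    fp = np.zeros((length, length), dtype=bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    fp[np.clip(rr, 0, length - 1), np.clip(cc, 0, length - 1)] = True
    return fp


def detect_hair_mask(
    rgb_image: np.ndarray, params: HairRemovalParams | None = None
) -> np.ndarray:
    """Boolean mask of pixels judged to be hair.

    A pixel is flagged when the maximum, over structuring-element
    orientations, of (grayscale closing - grayscale) exceeds
    ``diff_threshold``; the mask is then dilated by ``mask_dilation`` pixels.
    """
    params = params or HairRemovalParams()
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an HxWx3 image")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("empty image")
    gray = luminance(img)
    if params.median_prefilter:
        gray = ndimage.median_filter(gray, size=params.median_prefilter)
    residual = np.zeros_like(gray)
    for angle in params.se_orientations:
        fp = _line_footprint(params.se_length, angle)
        closed = ndimage.grey_closing(gray, footprint=fp, mode="nearest")
        np.maximum(residual, closed - gray, out=residual)
    mask = residual > params.diff_threshold
    if params.min_component_size and mask.any():
        comp, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        mask = np.isin(comp, np.flatnonzero(sizes >= params.min_component_size))
    if params.mask_dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=disk(params.mask_dilation))
    return mask


def remove_hair(
    rgb_image: np.ndarray,
    hair_mask: np.ndarray,
    fill_smooth_sigma: float = 1.5,
) -> np.ndarray:
    """Replace flagged pixels by interpolation from nearby non-flagged pixels.

    Each masked pixel takes its nearest non-masked pixel value (distance
    transform); the replaced region is then lightly Gaussian-smoothed so the
    fill carries no residual hair-like seam.  Pixels outside the mask are
    returned bit-identical; an empty mask returns an identical copy.
    """
    img = np.asarray(rgb_image)
    hair_mask = np.asarray(hair_mask, dtype=bool)
    if hair_mask.shape != img.shape[:2]:
        raise ValueError("hair_mask shape must match the image")
    if hair_mask.all():
        raise ValueError("hair mask covers the whole image; nothing to interpolate from")
    out = np.array(img, copy=True)
    if not hair_mask.any():
        return out
    _, (ir, ic) = ndimage.distance_transform_edt(hair_mask, return_indices=True)
    out[hair_mask] = img[ir[hair_mask], ic[hair_mask]]
    if fill_smooth_sigma > 0:
        sigma = (fill_smooth_sigma, fill_smooth_sigma) + (0,) * (img.ndim - 2)
        blur = ndimage.gaussian_filter(out.astype(np.float64), sigma=sigma)
        if np.issubdtype(img.dtype, np.integer):
            out[hair_mask] = np.clip(np.rint(blur[hair_mask]), 0, 255).astype(img.dtype)
        else:
            out[hair_mask] = blur[hair_mask]
    return out
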