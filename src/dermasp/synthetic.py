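"""Synthetic dermoscopy-like images with ground truth.

Every downstream stage of the pipeline (hair removal, graph-cut lesion
segmentation, superpixel generation, feature extraction, classification) is
exercisable on images produced here: a noisy flat skin background, one darker
lesion whose border irregularity and eccentricity depend on the diagnostic
class, optional curvilinear hair overlays, and the exact lesion mask.

The lesion boundary is a radial function ``r(theta) = r0 * (1 + a *
sum_k low-order random Fourier terms)`` followed by anisotropic scaling
(axis ratio) and a random rotation, so the two class-level effect sizes map
directly onto the geometric descriptors the pipeline measures: melanoma
configurations default to a more irregular border and a more eccentric
outline than nevus configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SyntheticConfig",
    "CLASS_DEFAULTS",
    "generate_lesion_image",
    "add_hair_overlay",
    "hair_raster",
    "generate_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "area",
    "perimeter",
    "eccentricity",
    "orientation",
    "convex_area",
    "major_axis_length",
]

#: Class-dependent effect sizes: melanoma borders are markedly more irregular
#: and the outline more elongated than nevus borders.
CLASS_DEFAULTS = {
    "nevus": {"border_irregularity": 0.05, "axis_ratio": 0.90},
    "melanoma": {"border_irregularity": 0.25, "axis_ratio": 0.55},
}

# Fourier orders perturbing the lesion radius; low orders give lobulated,
# ABCD-style border irregularity rather than high-frequency noise.
_FOURIER_ORDERS = np.arange(2, 8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic lesion image.

    Intensities are 8-bit (0-255), lengths in pixels.  ``border_irregularity``
    is the RMS relative amplitude of the radial Fourier perturbation;
    ``axis_ratio`` is minor/major axis of the pre-perturbation ellipse.
    """

    image_height: int = 256
    image_width: int = 256
    skin_mean_rgb: tuple[float, float, float] = (196.0, 152.0, 128.0)
    skin_noise_sd: float = 6.0
    lesion_mean_rgb: tuple[float, float, float] = (110.0, 72.0, 62.0)
    lesion_radius_px: float = 75.0
    border_irregularity: float = 0.05
    axis_ratio: float = 0.90
    n_hairs: int = 5
    hair_width_px: int = 3
    class_label: str = "nevus"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("skin_mean_rgb", "lesion_mean_rgb"):
            vals = getattr(self, name)
            if len(vals) != 3 or not all(0 <= v <= 255 for v in vals):
                raise ValueError(f"{name} must be 3 intensities in [0, 255]")
        if not 0 < self.axis_ratio <= 1:
            raise ValueError("axis_ratio must lie in (0, 1]")
        if self.border_irregularity < 0:
            raise ValueError("border_irregularity must be >= 0")
        if self.n_hairs < 0:
            raise ValueError("n_hairs must be >= 0")
        if self.lesion_radius_px >= min(self.image_height, self.image_width) / 2:
            raise ValueError(
                "degenerate geometry: lesion_radius_px "
                f"{self.lesion_radius_px} does not fit inside a "
                f"{self.image_height}x{self.image_width} frame"
            )

    @classmethod
    def for_class(cls, class_label: str, **overrides) -> "SyntheticConfig":
        """Config with the documented class-dependent effect sizes."""
        if class_label not in CLASS_DEFAULTS:
            raise ValueError(
                f"unknown class {class_label!r}; expected one of "
                f"{sorted(CLASS_DEFAULTS)}"
            )
        params = dict(CLASS_DEFAULTS[class_label])
        params.update(overrides)
        return cls(class_label=class_label, **params)


def _lesion_mask(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the radial-Fourier lesion outline as a boolean mask."""
    h, w = config.image_height, config.image_width
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)

    coeff_a = rng.normal(size=_FOURIER_ORDERS.size)
    coeff_b = rng.normal(size=_FOURIER_ORDERS.size)
    pert = coeff_a @ np.cos(np.outer(_FOURIER_ORDERS, theta)) + coeff_b @ np.sin(
        np.outer(_FOURIER_ORDERS, theta)
    )
    rms = np.sqrt(np.mean(pert**2))
    if rms > 0:
        pert = pert / rms
    radius = config.lesion_radius_px * (1.0 + config.border_irregularity * pert)
    # Clip against self-intersection at large irregularity (below) and keep
    # perturbation peaks inside the frame net of centre jitter (above).
    radius = np.clip(
        radius,
        0.2 * config.lesion_radius_px,
        min(h, w) / 2.0 - 10.0,
    )

    phi = rng.uniform(0.0, np.pi)
    x = radius * np.cos(theta)
    y = radius * np.sin(theta) * config.axis_ratio
    xr = x * np.cos(phi) - y * np.sin(phi)
    yr = x * np.sin(phi) + y * np.cos(phi)

    cy, cx = h / 2.0, w / 2.0
    jitter = rng.uniform(-8.0, 8.0, size=2)
    rows = yr + cy + jitter[0]
    cols = xr + cx + jitter[1]
    if rows.min() < 1 or rows.max() > h - 2 or cols.min() < 1 or cols.max() > w - 2:
        raise ValueError(
            "degenerate geometry: perturbed lesion outline leaves the frame; "
            "reduce lesion_radius_px or border_irregularity"
        )

    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=(h, w))
    mask[rr, cc] = True
    return mask


def generate_lesion_image(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one hair-free lesion image.

    Returns ``(rgb_image, truth_mask, class_label)`` where the uint8 image is
    ``HxWx3``, and ``truth_mask`` is boolean and marks exactly the lesion
    pixels.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mask = _lesion_mask(config, rng)

    h, w = config.image_height, config.image_width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(config.skin_mean_rgb)
    img[mask] = np.asarray(config.lesion_mean_rgb)
    img += rng.normal(scale=config.skin_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask, config.class_label


# Hair pixels sit well below both skin and lesion intensities so the overlay
# is unambiguous against the background it is drawn on.
_HAIR_RGB = np.array([28, 22, 18], dtype=np.uint8)


def hair_raster(
    shape: tuple[int, int], n_hairs: int, hair_width_px: int, seed: int
) -> np.ndarray:
    """Boolean raster of ``n_hairs`` random cubic Bezier arcs of given width."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if n_hairs == 0:
        return mask
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
    basis = np.hstack(
        [(1 - t) ** 3, 3 * t * (1 - t) ** 2, 3 * t**2 * (1 - t), t**3]
    )
    for _ in range(n_hairs):
        ctrl = np.column_stack(
            [rng.uniform(0, h, size=4), rng.uniform(0, w, size=4)]
        )
        pts = basis @ ctrl  # (m, 2) rows, cols along the curve
        rad = hair_width_px / 2.0
        for dr in np.arange(-np.ceil(rad), np.ceil(rad) + 1):
            for dc in np.arange(-np.ceil(rad), np.ceil(rad) + 1):
                if dr * dr + dc * dc > rad * rad + 1e-9:
                    continue
                rr = np.rint(pts[:, 0] + dr).astype(int)
                cc = np.rint(pts[:, 1] + dc).astype(int)
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                mask[rr[keep], cc[keep]] = True
    return mask


def add_hair_overlay(
    rgb_image: np.ndarray, n_hairs: int, hair_width_px: int, seed: int
) -> np.ndarray:
    """Draw dark curvilinear hair artifacts over a copy of the image.

    ``n_hairs=0`` returns an identical copy; only pixels under the drawn
    curves are modified.  The curve geometry is reproducible via
    :func:`hair_raster` with the same arguments.
    """
    if n_hairs < 0:
        raise ValueError("n_hairs must be >= 0")
    out = np.array(rgb_image, copy=True)
    if n_hairs == 0:
        return out
    mask = hair_raster(rgb_image.shape[:2], n_hairs, hair_width_px, seed)
    out[mask] = _HAIR_RGB
    return out


# ---------------------------------------------------------------------------
# Feature-table generator: a distributional stand-in for extracted superpixel
# descriptors, used to exercise the dataset/model/metric stages in isolation.
# ---------------------------------------------------------------------------

#: Per-feature means and standard deviations of the base (nevus) class, on the
#: scales an n=100 superpixel tiling of a 256x256 frame actually produces.
_TABLE_MEANS = np.array([650.0, 100.0, 0.55, 0.0, 680.0, 35.0])
_TABLE_SDS = np.array([150.0, 20.0, 0.15, 40.0, 160.0, 8.0])
#: Direction of the class shift in whitened coordinates; orientation (index 3)
#: carries no class signal, mirroring lesions of random pose.
_SHIFT_DIR = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 1.0])
_SHIFT_DIR = _SHIFT_DIR / np.linalg.norm(_SHIFT_DIR)


def generate_feature_table(
    n_per_class: int, separation: float, seed: int
) -> pd.DataFrame:
    """Balanced two-class 6-D Gaussian feature table.

    Both classes share a diagonal covariance (``_TABLE_SDS**2``); the melanoma
    mean is displaced from the nevus mean by exactly ``separation`` Mahalanobis
    units along ``_SHIFT_DIR``, so ``separation=0`` makes the two class
    distributions identical by construction.  Columns follow the feature CSV
    schema with integer class labels (nevus=0, melanoma=1).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    shift = separation * _SHIFT_DIR * _TABLE_SDS
    rows = []
    for cls, mean in ((0, _TABLE_MEANS), (1, _TABLE_MEANS + shift)):
        x = rng.normal(size=(n_per_class, 6)) * _TABLE_SDS + mean
        block = pd.DataFrame(x, columns=FEATURE_COLUMNS)
        block.insert(0, "sp_label", np.arange(1, n_per_class + 1))
        block.insert(0, "image_id", f"synthetic-class{cls}")
        block["class"] = cls
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
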