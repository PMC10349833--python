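"""Shape and geometric descriptors of one superpixel region.

Six descriptors per region, in the regionprops tradition: area (pixel
count), perimeter (length of the closed 8-connected outer boundary chain,
axis steps counting 1 and diagonal steps sqrt(2)), and four quantities of
the region's inertia-equivalent ellipse — orientation, eccentricity, major
axis length — plus the convex area (pixels of the filled convex hull of the
region's pixel centers).

The ellipse comes from the normalized second central moments with a +1/12
pixel-extent correction on the diagonal, so even a single pixel has a
well-defined ellipse (a circle of major axis 4/sqrt(12)).  Orientation is
measured from the +x (column) axis, counter-clockwise in the mathematical
y-up frame (image rows flipped), and reported in degrees in (-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import QhullError, ConvexHull
from skimage.morphology import convex_hull_image

from .islic import SuperpixelSet

__all__ = [
    "FeatureVector",
    "region_moments",
    "compute_sp_features",
    "extract_all",
]


@dataclass(frozen=True)
class FeatureVector:
    area: float
    perimeter: float
    eccentricity: float
    orientation: float
    convex_area: float
    major_axis_length: float

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("area must be >= 1")
        if self.convex_area < self.area:
            raise ValueError("convex_area must be >= area")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must lie in [0, 1)")
        if not -90 < self.orientation <= 90:
            raise ValueError("orientation must lie in (-90, 90]")
        if self.major_axis_length <= 0:
            raise ValueError("major_axis_length must be > 0")


def region_moments(region_mask: np.ndarray):
    """Area, centroid and corrected second central moments of a pixel region.

    Returns ``(area, (row_bar, col_bar), cov)`` where ``cov`` is the 2x2
    covariance ``[[mu20, mu11], [mu11, mu02]] / mu00`` in the y-up frame
    (x = column, y = -row) with +1/12 added to each diagonal entry to account
    for unit pixel extent.
    """
    mask = np.asarray(region_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty region mask")
    area = rows.size
    row_bar = rows.mean()
    col_bar = cols.mean()
    x = cols - col_bar
    y = -(rows - row_bar)
    mu20 = (x * x).mean() + 1.0 / 12.0
    mu02 = (y * y).mean() + 1.0 / 12.0
    mu11 = (x * y).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    return area, (row_bar, col_bar), cov


# Moore neighbourhood, clockwise on screen (rows grow downward), from East.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_STEP_LEN = {d: np.sqrt(2) if d[0] and d[1] else 1.0 for d in _MOORE}


def boundary_chain_perimeter(mask: np.ndarray) -> float:
    """Length of the closed outer-boundary chain (Moore-neighbour tracing)."""
    pad = np.pad(np.asarray(mask, dtype=bool), 1)
    rows, cols = np.nonzero(pad)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost

    def neighbor(p, d):
        return (p[0] + d[0], p[1] + d[1])

    current = start
    b_idx = 4  # backtrack to the West, unset for the raster-first pixel
    perimeter = 0.0
    first_move = None
    max_steps = 4 * rows.size + 8
    for _ in range(max_steps):
        nxt = None
        for i in range(b_idx + 1, b_idx + 9):
            d = _MOORE[i % 8]
            p = neighbor(current, d)
            if pad[p]:
                nxt = p
                step = d
                b_idx = (i - 1) % 8
                break
        if nxt is None:
            return 0.0  # isolated pixel
        if current == start and first_move is None:
            first_move = step
        elif current == start and step == first_move:
            break  # Jacob's stopping criterion: same re-entry into the chain
        perimeter += _STEP_LEN[step]
        # Backtrack index flips to point from the new pixel toward where we came.
        b_idx = _MOORE.index((current[0] - nxt[0], current[1] - nxt[1]))
        current = nxt
    return perimeter


def _convex_area(mask: np.ndarray) -> int:
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols])
    try:
        ConvexHull(pts)
    except (QhullError, ValueError):
        # Degenerate (collinear / tiny) region: the hull of the pixel centers
        # is a segment covering exactly the region's own pixels.
        return int(mask.sum())
    return int(convex_hull_image(mask, offset_coordinates=False).sum())


def _largest_component(mask: np.ndarray) -> np.ndarray:
    comp, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == sizes.argmax()


def compute_sp_features(region_mask: np.ndarray) -> FeatureVector:
    """The six geometric descriptors of a single (connected) pixel region.

    Multi-component masks are reduced to their largest component first.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    mask = _largest_component(mask)

    area, _, cov = region_moments(mask)
    evals = np.linalg.eigvalsh(cov)  # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    orientation = np.degrees(
        0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])
    )
    if orientation <= -90.0:
        orientation += 180.0
    eccentricity = float(np.sqrt(max(0.0, 1.0 - lam_min / lam_max)))
    major = 4.0 * np.sqrt(lam_max)
    return FeatureVector(
        area=float(area),
        perimeter=float(boundary_chain_perimeter(mask)),
        eccentricity=min(eccentricity, np.nextafter(1.0, 0.0)),
        orientation=float(orientation),
        convex_area=float(_convex_area(mask)),
        major_axis_length=float(major),
    )


def extract_all(
    sp_set: SuperpixelSet, image_id: str, class_label
) -> list[dict]:
    """One feature record per kept superpixel label.

    Each record carries ``image_id``, ``sp_label``, the six descriptors and
    ``class`` — the row schema of the feature CSV.
    """
    records = []
    for label in sp_set.kept_labels:
        fv = compute_sp_features(sp_set.label_map == label)
        rec = {"image_id": image_id, "sp_label": int(label)}
        rec.update(asdict(fv))
        rec["class"] = class_label
        records.append(rec)
    return records
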