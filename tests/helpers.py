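"""Independent oracles used by the test suite.

Everything here is deliberately written the slow, obvious way (explicit
double loops, exhaustive enumeration) and stays independent of the package
code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError


def brute_force_moments(mask: np.ndarray):
    """Second-moment ellipse quantities via explicit double loops.

    Returns (area, orientation_deg, eccentricity, major_axis_length) using
    the y-up frame and the +1/12 diagonal correction.
    """
    h, w = mask.shape
    pts = [(r, c) for r in range(h) for c in range(w) if mask[r, c]]
    n = len(pts)
    rbar = sum(p[0] for p in pts) / n
    cbar = sum(p[1] for p in pts) / n
    sxx = syy = sxy = 0.0
    for r, c in pts:
        x = c - cbar
        y = -(r - rbar)
        sxx += x * x
        syy += y * y
        sxy += x * y
    mu20 = sxx / n + 1.0 / 12.0
    mu02 = syy / n + 1.0 / 12.0
    mu11 = sxy / n
    evals = np.linalg.eigh(np.array([[mu20, mu11], [mu11, mu02]]))[0]
    lam_min, lam_max = evals
    orient = np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02))
    ecc = np.sqrt(max(0.0, 1.0 - lam_min / lam_max))
    return n, orient, ecc, 4.0 * np.sqrt(lam_max)


def brute_force_convex_area(mask: np.ndarray) -> int:
    """Count pixel centers inside the convex hull of the region's centers."""
    pts = np.argwhere(mask).astype(float)
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        return int(mask.sum())
    eqs = hull.equations
    count = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if np.all(eqs[:, 0] * r + eqs[:, 1] * c + eqs[:, 2] <= 1e-9):
                count += 1
    return count


def random_blob(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A random connected pixel region inside a size x size frame."""
    noise = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=rng.uniform(2, 6))
    mask = noise > np.quantile(noise, rng.uniform(0.6, 0.9))
    comp, n = ndimage.label(mask)
    if n == 0:
        out = np.zeros((size, size), dtype=bool)
        out[size // 2, size // 2] = True
        return out
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == sizes.argmax()


def enumerate_min_cut_energy(lum, fg, bg, params=None):
    """Exhaustive minimum of the quantised segmentation energy.

    Enumerates every labelling of the non-seed pixels (vectorised over all
    2^F assignments) and returns the minimum energy.
    """
    from dermasp.graphcut import GraphCutParams, _integer_capacities

    params = params or GraphCutParams()
    cap_src, cap_snk, links = _integer_capacities(
        np.asarray(lum, dtype=np.float64), fg, bg, params
    )
    n = lum.size
    free = np.flatnonzero(~(fg | bg).ravel())
    base = np.zeros(n, dtype=bool)
    base[fg.ravel()] = True
    m = 2 ** len(free)
    lab = np.broadcast_to(base, (m, n)).copy()
    bits = ((np.arange(m)[:, None] >> np.arange(len(free))) & 1).astype(bool)
    lab[:, free] = bits
    energy = lab @ cap_snk + (~lab) @ cap_src
    for i, j, wgt in links:
        energy = energy + (lab[:, i] != lab[:, j]) @ wgt
    return int(energy.min())


def boundary_recall(label_map: np.ndarray, true_edge: np.ndarray, tol: int = 1) -> float:
    """Fraction of true edge pixels within ``tol`` of a superpixel boundary."""
    b = np.zeros(label_map.shape, dtype=bool)
    b[:, :-1] |= label_map[:, :-1] != label_map[:, 1:]
    b[:-1, :] |= label_map[:-1, :] != label_map[1:, :]
    near = ndimage.binary_dilation(b, iterations=tol) if tol else b
    return float(near[true_edge].mean())


def two_tone_image(h: int = 60, w: int = 120) -> tuple[np.ndarray, np.ndarray]:
    """Vertical two-tone control image and the boolean mask of its edge."""
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:, : w // 2] = 40
    img[:, w // 2 :] = 200
    edge = np.zeros((h, w), dtype=bool)
    edge[:, w // 2 - 1 : w // 2 + 1] = True
    return img, edge
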