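"""SLIC superpixels with background elimination (iSLIC).

SLIC is localized k-means in joint CIELAB-spatial coordinates: cluster
centres start on a regular grid with step ``S = sqrt(HW/n)``, are nudged to
the lowest-gradient position in a 3x3 window, and pixels within a 2Sx2S
window of each centre are assigned by the joint distance

    D = sqrt(d_lab^2 + (d_xy / S)^2 * m^2)

with compactness ``m``.  After the fixed number of iterations, connectivity
is enforced (each label one 4-connected component, fragments below a minimum
size merged into their largest neighbour) and labels are compacted to 1..L.

The "i" of iSLIC is the background-elimination step: superpixels are kept
only when at least ``overlap_threshold`` of their pixels fall inside the
lesion mask, so superpixels of the blackened background never reach feature
extraction.  The full label map is retained; only the kept-label set shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab

__all__ = [
    "SlicParams",
    "SuperpixelSet",
    "slic_superpixels",
    "enforce_connectivity",
    "filter_background_superpixels",
]


@dataclass(frozen=True)
class SlicParams:
    n_superpixels: int = 100
    compactness: float = 10.0
    max_iterations: int = 10
    min_size_fraction: float = 0.25  # of the mean superpixel area HW/n

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise ValueError("n_superpixels must be >= 2")
        if self.compactness <= 0:
            raise ValueError("compactness must be > 0")
        if not 0 < self.min_size_fraction < 1:
            raise ValueError("min_size_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SuperpixelSet:
    """A label map together with the labels kept after background filtering.

    ``n_requested`` is the number of superpixels asked of SLIC (the pipeline's
    n); ``n_kept`` counts the labels surviving background elimination.
    """

    label_map: np.ndarray
    kept_labels: tuple[int, ...]
    n_requested: int
    per_label_pixel_count: dict[int, int]

    @property
    def n_kept(self) -> int:
        return len(self.kept_labels)


def _init_centers(lab: np.ndarray, n: int) -> np.ndarray:
    """Grid-initialised centres ``(k, 5)`` as (l, a, b, row, col)."""
    h, w = lab.shape[:2]
    nx = max(1, round(np.sqrt(n * w / h)))
    ny = max(1, round(n / nx))
    if nx * ny < 2:  # degenerate rounding on near-square frames at tiny n
        ny = 2
    rows = (np.arange(ny) + 0.5) * h / ny
    cols = (np.arange(nx) + 0.5) * w / nx
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    # Perturb each centre to the lowest-gradient pixel in its 3x3 window.
    gy, gx = np.gradient(lab[..., 0])
    grad = gy**2 + gx**2
    centers = np.empty((ny * nx, 5))
    for k, (r, c) in enumerate(zip(rr.ravel(), cc.ravel())):
        r0, c0 = int(round(r)), int(round(c))
        r0 = min(max(r0, 1), h - 2)
        c0 = min(max(c0, 1), w - 2)
        win = grad[r0 - 1 : r0 + 2, c0 - 1 : c0 + 2]
        dr, dc = np.unravel_index(win.argmin(), win.shape)
        r0, c0 = r0 - 1 + dr, c0 - 1 + dc
        centers[k] = (*lab[r0, c0], r0, c0)
    return centers


def slic_superpixels(rgb_image: np.ndarray, params: SlicParams | None = None) -> np.ndarray:
    """Partition the image into near-uniform superpixels; labels 1..L.

    Deterministic: identical image and parameters give an identical label
    map.  Connectivity is enforced before returning.
    """
    params = params or SlicParams()
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("expected an HxWx3 image of size >= 2x2")
    h, w = img.shape[:2]
    if params.n_superpixels > h * w:
        raise ValueError("n_superpixels exceeds the number of pixels")

    lab = rgb2lab(img)
    s = np.sqrt(h * w / params.n_superpixels)
    m2_s2 = (params.compactness / s) ** 2
    centers = _init_centers(lab, params.n_superpixels)
    k = len(centers)

    rows_grid, cols_grid = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    labels = np.zeros((h, w), dtype=np.int32)
    for _ in range(params.max_iterations):
        dist = np.full((h, w), np.inf)
        labels.fill(-1)
        half = int(np.ceil(s))
        for ck in range(k):
            cl, ca, cb, cr, cc = centers[ck]
            r0, r1 = max(int(cr) - half, 0), min(int(cr) + half + 1, h)
            c0, c1 = max(int(cc) - half, 0), min(int(cc) + half + 1, w)
            win = lab[r0:r1, c0:c1]
            d_lab = (
                (win[..., 0] - cl) ** 2
                + (win[..., 1] - ca) ** 2
                + (win[..., 2] - cb) ** 2
            )
            d_xy = (rows_grid[r0:r1, c0:c1] - cr) ** 2 + (
                cols_grid[r0:r1, c0:c1] - cc
            ) ** 2
            d = d_lab + d_xy * m2_s2
            sub = dist[r0:r1, c0:c1]
            upd = d < sub
            sub[upd] = d[upd]
            labels[r0:r1, c0:c1][upd] = ck

        if (labels < 0).any():
            # Pixels outside every search window: nearest centre spatially.
            miss = labels < 0
            mr, mc = rows_grid[miss], cols_grid[miss]
            d2 = (mr[:, None] - centers[None, :, 3]) ** 2 + (
                mc[:, None] - centers[None, :, 4]
            ) ** 2
            labels[miss] = d2.argmin(axis=1)

        flat = labels.ravel()
        counts = np.bincount(flat, minlength=k).astype(np.float64)
        counts[counts == 0] = 1.0
        for d in range(3):
            centers[:, d] = np.bincount(flat, lab[..., d].ravel(), minlength=k) / counts
        centers[:, 3] = np.bincount(flat, rows_grid.ravel(), minlength=k) / counts
        centers[:, 4] = np.bincount(flat, cols_grid.ravel(), minlength=k) / counts

    min_size = int(h * w / params.n_superpixels * params.min_size_fraction)
    return enforce_connectivity(labels + 1, min_size)


def enforce_connectivity(label_map: np.ndarray, min_size: int) -> np.ndarray:
    """Make every label a single 4-connected component of at least ``min_size``.

    Each connected component of the input becomes its own region; regions
    smaller than ``min_size`` are absorbed by their largest adjacent region.
    Output labels are compacted to 1..L.
    """
    labels = np.asarray(label_map)
    comp, ncomp = _components(labels)
    sizes = np.bincount(comp.ravel(), minlength=ncomp + 1).astype(np.int64)

    neighbors: list[set[int]] = [set() for _ in range(ncomp + 1)]
    for a, b in ((comp[:, :-1], comp[:, 1:]), (comp[:-1, :], comp[1:, :])):
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            neighbors[u].add(v)
            neighbors[v].add(u)

    parent = np.arange(ncomp + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # Absorb undersized regions smallest-first so chains of fragments can
    # coalesce into a region that finally clears min_size.
    for c in sorted(range(1, ncomp + 1), key=lambda c: sizes[c]):
        root = find(c)
        if sizes[root] >= min_size:
            continue
        adj = {find(v) for v in neighbors[root]} - {root}
        if not adj:
            continue  # isolated region, e.g. a single-label map
        target = max(adj, key=lambda r: (sizes[r], -r))
        parent[root] = target
        sizes[target] += sizes[root]
        neighbors[target] |= neighbors[root]

    roots = np.array([find(c) for c in range(ncomp + 1)])
    _, compact = np.unique(roots[comp], return_inverse=True)
    return (compact + 1).reshape(comp.shape).astype(np.int32)


def _components(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected components of equal-valued regions, ids 1..n."""
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    comp = np.zeros(labels.shape, dtype=np.int64)
    ncomp = 0
    for val in np.unique(labels):
        cc, n = ndimage.label(labels == val, structure=four)
        comp[cc > 0] = cc[cc > 0] + ncomp
        ncomp += n
    return comp, ncomp


def filter_background_superpixels(
    label_map: np.ndarray,
    lesion_mask: np.ndarray,
    overlap_threshold: float = 0.5,
    n_requested: int | None = None,
) -> SuperpixelSet:
    """Keep superpixels whose in-mask pixel fraction reaches the threshold.

    The label map itself is unchanged; discarded labels simply drop out of
    the kept set.  An empty mask therefore keeps nothing, a full mask keeps
    everything, and the kept set shrinks weakly as the threshold rises.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must lie in (0, 1]")
    labels = np.asarray(label_map)
    mask = np.asarray(lesion_mask, dtype=bool)
    if mask.shape != labels.shape:
        raise ValueError("mask shape must match the label map")
    total = np.bincount(labels.ravel())
    inside = np.bincount(labels.ravel(), mask.ravel().astype(np.float64))
    inside = inside.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, inside / np.maximum(total, 1), 0.0)
    present = np.nonzero(total)[0]
    present = present[present > 0]
    kept = tuple(int(l) for l in present if frac[l] >= overlap_threshold)
    counts = {int(l): int(total[l]) for l in present}
    return SuperpixelSet(
        label_map=labels,
        kept_labels=kept,
        n_requested=len(present) if n_requested is None else n_requested,
        per_label_pixel_count=counts,
    )
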