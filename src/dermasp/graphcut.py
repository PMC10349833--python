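"""Seeded graph-cut lesion segmentation.

The lesion region of interest is found as the minimum s-t cut of a pixel grid
graph in the Boykov-Jolly style: terminal (data) capacities are negative
log-likelihoods of each pixel's luminance under Gaussian models fitted to the
foreground and background seed pixels, and neighbour (smoothness) capacities
are contrast-sensitive, ``lambda * exp(-(Ii-Ij)^2 / (2 sigma^2)) / dist``.
Seeds are hard constraints.  Since lesions are darker than the surrounding
skin, seeds are placed automatically: background seeds on the image border
frame, foreground seeds on the darkest central pixels.

Capacities are scaled to integers (``_SCALE``) for the max-flow solver; the
energy minimised is exact on that quantised scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .preprocess import luminance

__all__ = [
    "GraphCutParams",
    "auto_seeds",
    "graph_cut_segment",
    "apply_black_mask",
    "cut_energy",
    "data_terms",
    "pairwise_weight",
]

_SCALE = 50  # integer quantisation of capacities
_DATA_CLIP = 25.0  # cap on -log-likelihood data terms
_SEED_CAP = 10**9  # "infinite" capacity pinning seed labels


@dataclass(frozen=True)
class GraphCutParams:
    lambda_smooth: float = 50.0
    sigma_contrast: float = 10.0
    neighborhood: int = 4
    border_margin: int = 8
    fg_quantile: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_smooth <= 0:
            raise ValueError("lambda_smooth must be > 0")
        if self.sigma_contrast <= 0:
            raise ValueError("sigma_contrast must be > 0")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if not 0 < self.fg_quantile < 1:
            raise ValueError("fg_quantile must lie in (0, 1)")


def auto_seeds(
    rgb_image: np.ndarray, params: GraphCutParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Automatic seed masks: border frame as background, dark centre as foreground.

    Background seeds are the frame of width ``border_margin``; foreground
    seeds are pixels strictly darker than the ``fg_quantile`` luminance
    quantile, restricted to the central half of the image, reduced to the
    largest connected component.
    """
    params = params or GraphCutParams()
    img = np.asarray(rgb_image)
    h, w = img.shape[:2]
    m = params.border_margin
    if h <= 2 * m or w <= 2 * m:
        raise ValueError("image too small for the requested border_margin")

    bg = np.zeros((h, w), dtype=bool)
    bg[:m, :] = bg[-m:, :] = True
    bg[:, :m] = bg[:, -m:] = True

    lum = luminance(img)
    thresh = np.quantile(lum, params.fg_quantile)
    fg = lum < thresh
    central = np.zeros((h, w), dtype=bool)
    central[h // 4 : h - h // 4, w // 4 : w - w // 4] = True
    fg &= central & ~bg
    if not fg.any():
        raise ValueError(
            "no foreground seed pixels: no central pixel is darker than the "
            f"{params.fg_quantile:g} luminance quantile"
        )
    comp, n = ndimage.label(fg)
    if n > 1:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        fg = comp == sizes.argmax()
    return fg, bg


def data_terms(
    lum: np.ndarray, fg_seed_mask: np.ndarray, bg_seed_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel costs of labelling foreground/background.

    Costs are negative log densities of the luminance under Gaussian models
    fitted to the respective seed pixels (sd floored at 1 intensity unit),
    clipped at ``_DATA_CLIP``.
    """
    costs = []
    for seeds in (fg_seed_mask, bg_seed_mask):
        mu = lum[seeds].mean()
        sd = max(lum[seeds].std(), 1.0)
        nll = 0.5 * ((lum - mu) / sd) ** 2 + np.log(sd * np.sqrt(2 * np.pi))
        costs.append(np.clip(nll, 0.0, _DATA_CLIP))
    return costs[0], costs[1]


def pairwise_weight(li: np.ndarray, lj: np.ndarray, params: GraphCutParams) -> np.ndarray:
    """Contrast-sensitive smoothness weight between neighbouring luminances."""
    return params.lambda_smooth * np.exp(
        -((li - lj) ** 2) / (2.0 * params.sigma_contrast**2)
    )


def _neighbor_pairs(h: int, w: int, neighborhood: int):
    """(i, j, dist) index arrays of unique grid-neighbour pairs."""
    idx = np.arange(h * w).reshape(h, w)
    pairs = [
        (idx[:, :-1].ravel(), idx[:, 1:].ravel(), 1.0),
        (idx[:-1, :].ravel(), idx[1:, :].ravel(), 1.0),
    ]
    if neighborhood == 8:
        pairs += [
            (idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), np.sqrt(2)),
            (idx[:-1, 1:].ravel(), idx[1:, :-1].ravel(), np.sqrt(2)),
        ]
    return pairs


def _integer_capacities(
    lum: np.ndarray,
    fg_seed_mask: np.ndarray,
    bg_seed_mask: np.ndarray,
    params: GraphCutParams,
):
    """Quantised t-link and n-link capacities of the segmentation graph."""
    cost_fg, cost_bg = data_terms(lum, fg_seed_mask, bg_seed_mask)
    # Source side = foreground: cutting the pixel->sink edge pays the cost of
    # labelling the pixel foreground, cutting source->pixel pays background.
    cap_src = np.rint(cost_bg * _SCALE).astype(np.int64).ravel()
    cap_snk = np.rint(cost_fg * _SCALE).astype(np.int64).ravel()
    cap_src[fg_seed_mask.ravel()] = _SEED_CAP
    cap_snk[fg_seed_mask.ravel()] = 0
    cap_snk[bg_seed_mask.ravel()] = _SEED_CAP
    cap_src[bg_seed_mask.ravel()] = 0

    flat = lum.ravel()
    links = []
    for i, j, dist in _neighbor_pairs(*lum.shape, params.neighborhood):
        wgt = np.rint(pairwise_weight(flat[i], flat[j], params) / dist * _SCALE)
        links.append((i, j, wgt.astype(np.int64)))
    return cap_src, cap_snk, links


def graph_cut_segment(
    rgb_image: np.ndarray,
    fg_seed_mask: np.ndarray,
    bg_seed_mask: np.ndarray,
    params: GraphCutParams | None = None,
    *,
    postprocess: bool = True,
) -> np.ndarray:
    """Binary lesion mask from a seeded minimum s-t cut.

    Every foreground seed ends up inside the mask and every background seed
    outside.  With ``postprocess`` the raw cut is reduced to the connected
    component(s) containing foreground seeds and holes are filled, matching
    the single filled lesion region the pipeline expects.
    """
    params = params or GraphCutParams()
    img = np.asarray(rgb_image)
    fg = np.asarray(fg_seed_mask, dtype=bool)
    bg = np.asarray(bg_seed_mask, dtype=bool)
    if fg.shape != img.shape[:2] or bg.shape != img.shape[:2]:
        raise ValueError("seed masks must match the image size")
    if not fg.any() or not bg.any():
        raise ValueError("both seed masks must be non-empty")
    if (fg & bg).any():
        raise ValueError("infeasible seeds: foreground and background overlap")

    lum = luminance(img) if img.ndim == 3 else np.asarray(img, dtype=np.float64)
    h, w = lum.shape
    n = h * w
    src, snk = n, n + 1
    cap_src, cap_snk, links = _integer_capacities(lum, fg, bg, params)

    rows = [np.full(n, src), np.arange(n)]
    cols = [np.arange(n), np.full(n, snk)]
    caps = [cap_src, cap_snk]
    for i, j, wgt in links:
        rows += [i, j]
        cols += [j, i]
        caps += [wgt, wgt]
    graph = csr_matrix(
        (
            np.concatenate(caps),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(n + 2, n + 2),
        dtype=np.int64,
    )
    graph = graph.astype(np.int32)
    graph.eliminate_zeros()

    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    mask = np.zeros(n + 2, dtype=bool)
    mask[reachable] = True
    lesion = mask[:n].reshape(h, w)

    if postprocess:
        comp, ncomp = ndimage.label(lesion)
        if ncomp > 1:
            keep = np.unique(comp[fg])
            lesion = np.isin(comp, keep[keep > 0])
        lesion = ndimage.binary_fill_holes(lesion)
    return lesion


def cut_energy(
    labels: np.ndarray,
    lum: np.ndarray,
    fg_seed_mask: np.ndarray,
    bg_seed_mask: np.ndarray,
    params: GraphCutParams | None = None,
) -> int:
    """Quantised energy of a binary labelling (1=foreground) of the grid.

    Uses exactly the integer capacities the solver minimises, so the solver's
    output can be compared against exhaustive enumeration on miniatures.
    Seed-violating labellings get ``_SEED_CAP``-sized penalties.
    """
    params = params or GraphCutParams()
    lab = np.asarray(labels, dtype=bool).ravel()
    cap_src, cap_snk, links = _integer_capacities(
        np.asarray(lum, dtype=np.float64), fg_seed_mask, bg_seed_mask, params
    )
    # Foreground pixels cut their sink edge, background pixels their source edge.
    energy = int(cap_snk[lab].sum() + cap_src[~lab].sum())
    for i, j, wgt in links:
        energy += int(wgt[lab[i] != lab[j]].sum())
    return energy


def apply_black_mask(rgb_image: np.ndarray, lesion_mask: np.ndarray) -> np.ndarray:
    """Blacken every pixel outside the lesion mask; inside pixels unchanged."""
    img = np.asarray(rgb_image)
    mask = np.asarray(lesion_mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape must match the image")
    out = np.array(img, copy=True)
    out[~mask] = 0
    return out
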