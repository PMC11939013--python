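"""Context-aware spatial decomposition segmentation (CASDN).

The segmenter scores every pixel of a preprocessed image by decomposing it
into a regular grid of cells, weighting each cell by how structured it is
relative to the others (softmax over z-scored cell statistics,
``w_i = exp(alpha * Rel_i) / sum_j exp(alpha * Rel_j)``), assembling a
weighted per-cell local-contrast map, gating it by a saliency map,
folding in coarser spatial context over a small hierarchy of scales, and
applying a sigmoid-contrast refinement step
``F_refined = F + beta_refine * (g(F) - F)``.

Training minimizes the combined loss

    L = lambda * [alpha_spatial * SpatialLoss + alpha_context_w * ContextLoss]

where SpatialLoss is a soft-Dice term plus a total-variation coherence term
and ContextLoss is pixelwise binary cross-entropy. The four shape
parameters (softmax sharpness, saliency gating, refinement step, mask
threshold) are fitted by greedy coordinate descent over fixed grids, which
keeps the procedure deterministic and exhaustively checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, transform

from .aipt import _remove_small_components, _sobel_magnitude, _upsample
from .exceptions import DimensionError, ValidationError
from .io import CasdnConfig, validate_image, validate_mask

_EPS = 1e-6

#: fixed parameter grids swept by :func:`fit`
FIT_GRIDS: Dict[str, Tuple[float, ...]] = {
    "alpha_context": (0.0, 0.5, 1.0, 2.0, 4.0),
    "beta_context": (0.0, 0.25, 0.5, 0.75, 1.0),
    "beta_refine": (0.0, 0.25, 0.5, 0.75, 1.0),
    "score_threshold": (0.3, 0.4, 0.5, 0.6, 0.7),
}


# ---------------------------------------------------------------------------
# grid decomposition and per-cell features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """One grid cell: indices, half-open pixel box and the pixel block."""

    row: int
    col: int
    box: Tuple[int, int, int, int]  # (r0, r1, c0, c1), half-open
    block: np.ndarray


@dataclass(frozen=True)
class GridDecomposition:
    cells: Tuple[Cell, ...]
    grid_side: int
    shape: Tuple[int, int]


def _tile_bounds(extent: int, tiles: int) -> List[Tuple[int, int]]:
    base = extent // tiles
    bounds = [(i * base, (i + 1) * base) for i in range(tiles)]
    bounds[-1] = (bounds[-1][0], extent)  # remainder absorbed by the last tile
    return bounds


def decompose_grid(img: np.ndarray, n_cells: int = 16) -> GridDecomposition:
    """Near-equal ``sqrt(n) x sqrt(n)`` tiling; remainder pixels go to the
    last row/column so the boxes tile the image exactly."""
    img = np.asarray(img, dtype=np.float64)
    side = int(round(n_cells ** 0.5))
    if n_cells < 4 or side * side != n_cells:
        raise ValidationError(
            f"n_cells must be a perfect square >= 4, got {n_cells}"
        )
    if side > min(img.shape):
        raise ValidationError(
            f"grid side {side} exceeds the smallest image side {min(img.shape)}"
        )
    rows = _tile_bounds(img.shape[0], side)
    cols = _tile_bounds(img.shape[1], side)
    cells = tuple(
        Cell(i, j, (r0, r1, c0, c1), img[r0:r1, c0:c1])
        for i, (r0, r1) in enumerate(rows)
        for j, (c0, c1) in enumerate(cols)
    )
    return GridDecomposition(cells=cells, grid_side=side, shape=img.shape)


def process_cell(block: np.ndarray) -> np.ndarray:
    """Four-component cell feature vector:
    (mean, standard deviation, mean Sobel magnitude, 16-bin entropy in bits).
    """
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValidationError("cell block must be nonempty")
    grad = _sobel_magnitude(block).mean()
    idx = np.minimum((block * 16).astype(np.intp), 15)
    p = np.bincount(idx.ravel(), minlength=16).astype(np.float64)
    p /= p.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    return np.array([block.mean(), block.std(), grad, entropy])


def cell_relevances(features: Sequence[np.ndarray]) -> np.ndarray:
    """Structure score per cell: the sum of across-cell standard scores of
    the spread, gradient and entropy components (a zero-variance component
    contributes 0). Higher means more structured."""
    if len(features) < 2:
        raise ValidationError("relevance needs at least 2 cells")
    feats = np.asarray(features, dtype=np.float64)
    rel = np.zeros(feats.shape[0])
    for comp in (1, 2, 3):  # std, gradient, entropy
        col = feats[:, comp]
        sd = col.std()
        if sd > 0:
            rel += (col - col.mean()) / sd
    return rel


def fusion_weights(relevances: np.ndarray, alpha_context: float = 1.0) -> np.ndarray:
    """Softmax ``exp(alpha * rel) / sum`` with max-subtraction for stability."""
    if alpha_context < 0:
        raise ValidationError(f"alpha_context must be >= 0, got {alpha_context}")
    z = alpha_context * np.asarray(relevances, dtype=np.float64)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# score-map construction
# ---------------------------------------------------------------------------

def _cell_contrast(block: np.ndarray) -> np.ndarray:
    """Cell block min-max normalized to [0,1]; constant cells map to 0."""
    lo, hi = float(block.min()), float(block.max())
    if hi - lo <= 0.0:
        return np.zeros_like(block)
    return (block - lo) / (hi - lo)


def fuse_cells(
    img: np.ndarray, decomp: GridDecomposition, weights: np.ndarray
) -> np.ndarray:
    """Assemble the weighted per-cell local-contrast map.

    Cell ``i`` receives ``clip(n_cells * w_i * contrast_i, 0, 1)``; the
    ``n_cells`` factor makes uniform weights the neutral element (plain
    contrast-map assembly).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.shape != decomp.shape:
        raise DimensionError(
            f"image shape {img.shape} does not match decomposition {decomp.shape}"
        )
    n = len(decomp.cells)
    if len(weights) != n:
        raise DimensionError(f"expected {n} weights, got {len(weights)}")
    fused = np.empty(img.shape)
    for cell, w in zip(decomp.cells, weights):
        r0, r1, c0, c1 = cell.box
        fused[r0:r1, c0:c1] = n * w * _cell_contrast(img[r0:r1, c0:c1])
    return np.clip(fused, 0.0, 1.0)


def adaptive_weighting(
    fused: np.ndarray, saliency: np.ndarray, beta_context: float = 0.5
) -> np.ndarray:
    """Saliency-gated reweighting
    ``(1 - b) * F + b * (F * S)``; ``beta_context=0`` is the identity."""
    fused = np.asarray(fused, dtype=np.float64)
    saliency = np.asarray(saliency, dtype=np.float64)
    if fused.shape != saliency.shape:
        raise DimensionError(
            f"shape mismatch: {fused.shape} vs {saliency.shape}"
        )
    if not 0.0 <= beta_context <= 1.0:
        raise ValidationError(
            f"beta_context must lie in [0, 1], got {beta_context}"
        )
    return (1.0 - beta_context) * fused + beta_context * fused * saliency


def hierarchical_integrate(fmap: np.ndarray, l_context: int = 3) -> np.ndarray:
    """Fold coarser spatial context into the map, level by level.

    For level ``l = 1..L`` the map is averaged with a version of itself
    downsampled by ``2**l``, Gaussian smoothed (sigma=1) and upsampled back:
    ``map <- 0.5 * map + 0.5 * up(G_1(down(map)))``. Each fold builds on the
    previous one, and the averaging can only reduce total variation.
    """
    fmap = np.asarray(fmap, dtype=np.float64)
    if l_context < 1:
        raise ValidationError(f"l_context must be >= 1, got {l_context}")
    out = fmap
    for l in range(1, l_context + 1):
        shape = (max(1, -(-out.shape[0] // 2 ** l)),
                 max(1, -(-out.shape[1] // 2 ** l)))
        coarse = transform.resize(
            out, shape, order=1, mode="reflect",
            anti_aliasing=True, preserve_range=True,
        )
        coarse = ndi.gaussian_filter(coarse, 1.0, mode="reflect")
        out = 0.5 * out + 0.5 * _upsample(coarse, out.shape)
    return np.clip(out, 0.0, 1.0)


def _sigmoid_contrast(f: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-10.0 * (f - 0.5)))


def refine(f_hier: np.ndarray, beta_refine: float = 0.3,
           n_iter: int = 1) -> np.ndarray:
    """Sigmoid-contrast refinement ``F + beta * (g(F) - F)`` with
    ``g(F) = 1 / (1 + exp(-10 (F - 0.5)))``; 0.5 is a fixed point and
    ``beta_refine=0`` is the identity."""
    f = np.asarray(f_hier, dtype=np.float64)
    if not 0.0 <= beta_refine <= 1.0:
        raise ValidationError(
            f"beta_refine must lie in [0, 1], got {beta_refine}"
        )
    for _ in range(n_iter):
        f = np.clip(f + beta_refine * (_sigmoid_contrast(f) - f), 0.0, 1.0)
    return f


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def spatial_loss(scores: np.ndarray, truth: np.ndarray) -> float:
    """Soft-Dice loss plus a total-variation coherence term.

    ``1 - 2*sum(s*t) / (sum(s) + sum(t) + eps)`` plus the mean absolute
    forward difference of the scores along both axes.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = validate_mask(truth).astype(np.float64)
    if scores.shape != truth.shape:
        raise DimensionError(f"shape mismatch: {scores.shape} vs {truth.shape}")
    dice_term = 1.0 - 2.0 * (scores * truth).sum() / (
        scores.sum() + truth.sum() + _EPS
    )
    d0 = np.abs(np.diff(scores, axis=0))
    d1 = np.abs(np.diff(scores, axis=1))
    tv = (d0.sum() + d1.sum()) / (d0.size + d1.size)
    return float(dice_term + tv)


def context_loss(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mean pixelwise binary cross-entropy with scores clipped to
    ``[1e-6, 1 - 1e-6]``."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = validate_mask(truth).astype(np.float64)
    if scores.shape != truth.shape:
        raise DimensionError(f"shape mismatch: {scores.shape} vs {truth.shape}")
    s = np.clip(scores, 1e-6, 1.0 - 1e-6)
    return float(-np.mean(truth * np.log(s) + (1.0 - truth) * np.log(1.0 - s)))


def casdn_loss(scores: np.ndarray, truth: np.ndarray, cfg: CasdnConfig) -> float:
    """Combined loss
    ``lambda * [alpha_spatial * SpatialLoss + alpha_context_w * ContextLoss]``."""
    return cfg.lambda_loss * (
        cfg.alpha_spatial * spatial_loss(scores, truth)
        + cfg.alpha_context_weight * context_loss(scores, truth)
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationResult:
    scores: np.ndarray          # refined score map in [0, 1]
    mask: np.ndarray            # post-processed {0,1} mask
    boundary: Set[Tuple[int, int]]
    loss: float | None = None   # combined loss when truth was supplied


def _boundary_set(mask: np.ndarray) -> Set[Tuple[int, int]]:
    """Mask pixels with at least one background 4-neighbor (out-of-image
    counts as background)."""
    m = mask.astype(bool)
    interior = ndi.binary_erosion(
        m, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    rr, cc = np.nonzero(m & ~interior)
    return set(zip(rr.tolist(), cc.tolist()))


class _ImageContext:
    """Per-image quantities that do not depend on the fitted parameters."""

    def __init__(self, img: np.ndarray, saliency: np.ndarray, n_cells: int):
        self.img = validate_image(img)
        self.saliency = np.asarray(saliency, dtype=np.float64)
        if self.saliency.shape != self.img.shape:
            raise DimensionError(
                f"saliency shape {self.saliency.shape} does not match image "
                f"{self.img.shape}"
            )
        self.decomp = decompose_grid(self.img, n_cells)
        feats = [process_cell(c.block) for c in self.decomp.cells]
        self.relevances = cell_relevances(feats)
        self.n = len(self.decomp.cells)
        self.contrast = [
            (_cell_contrast(c.block), c.box) for c in self.decomp.cells
        ]

    def scores(self, cfg: CasdnConfig) -> np.ndarray:
        w = fusion_weights(self.relevances, cfg.alpha_context)
        fused = np.empty(self.img.shape)
        for (contrast, (r0, r1, c0, c1)), wi in zip(self.contrast, w):
            fused[r0:r1, c0:c1] = self.n * wi * contrast
        fused = np.clip(fused, 0.0, 1.0)
        adaptive = adaptive_weighting(fused, self.saliency, cfg.beta_context)
        hier = hierarchical_integrate(adaptive, cfg.l_context)
        return refine(hier, cfg.beta_refine, cfg.n_refine_iter)


def predict(
    img: np.ndarray,
    cfg: CasdnConfig,
    saliency: np.ndarray,
    truth: np.ndarray | None = None,
) -> SegmentationResult:
    """Full scoring chain plus mask post-processing.

    The refined score map is cut at ``score_threshold``; the mask is closed
    with a radius-1 disk, components smaller than 0.05% of the image area
    are dropped, and the boundary set uses the 4-neighbor rule. When a
    ground-truth mask is supplied the combined loss is evaluated on the
    refined scores.
    """
    ctx = _ImageContext(img, saliency, cfg.n_cells)
    scores = ctx.scores(cfg)
    mask = scores >= cfg.score_threshold
    mask = ndi.binary_closing(mask, structure=morphology.disk(1))
    mask = _remove_small_components(mask, 5e-4 * mask.size)
    mask = mask.astype(np.uint8)
    loss = casdn_loss(scores, truth, cfg) if truth is not None else None
    return SegmentationResult(
        scores=scores, mask=mask, boundary=_boundary_set(mask), loss=loss
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _snap(value: float, grid: Sequence[float]) -> float:
    return min(grid, key=lambda g: (abs(g - value), g))


def fit(
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    cfg: CasdnConfig | None = None,
    saliencies: Sequence[np.ndarray] | None = None,
) -> Tuple[CasdnConfig, List[float]]:
    """Greedy coordinate descent over the fixed parameter grids.

    Sweeps (alpha_context, beta_context, beta_refine, score_threshold) one
    at a time over :data:`FIT_GRIDS`, accepting a move only when it strictly
    lowers the mean combined loss over the training pairs; ties keep the
    incumbent. Sweeps repeat until a full pass changes nothing, or 5 passes.
    Returns the fitted config and the accepted-step loss history (which is
    non-increasing by construction). Deterministic for fixed inputs.

    The softmax sharpness and the saliency gating interact, so a single
    greedy descent can stall in a coordinate-wise local minimum; the descent
    is therefore restarted from every (alpha_context, beta_context) grid
    pair (the shared evaluation cache keeps the total cost bounded by the
    125 distinct loss evaluations of the grid) and the best end point wins,
    with ties resolved by restart order.

    ``saliencies`` defaults to the center-surround saliency of each image;
    pass the AIPT-trace maps when the images are AIPT outputs.
    """
    cfg = cfg or CasdnConfig()
    if len(images) == 0 or len(images) != len(truths):
        raise ValidationError("fit needs >= 1 matching (image, truth) pair")
    if saliencies is None:
        from .aipt import center_surround_saliency
        saliencies = [center_surround_saliency(im) for im in images]
    contexts = [
        _ImageContext(im, sal, cfg.n_cells)
        for im, sal in zip(images, saliencies)
    ]
    truths = [validate_mask(t, like=im) for t, im in zip(truths, images)]

    cache: Dict[Tuple[float, float, float], float] = {}

    def mean_loss(c: CasdnConfig) -> float:
        key = (c.alpha_context, c.beta_context, c.beta_refine)
        if key not in cache:
            cache[key] = float(np.mean([
                casdn_loss(ctx.scores(c), t, c)
                for ctx, t in zip(contexts, truths)
            ]))
        return cache[key]

    snapped = replace(cfg, **{
        name: _snap(getattr(cfg, name), grid)
        for name, grid in FIT_GRIDS.items()
    })

    def descend(start: CasdnConfig) -> Tuple[CasdnConfig, float, List[float]]:
        current = start
        best = mean_loss(current)
        history = [best]
        for _ in range(5):
            changed = False
            for name, grid in FIT_GRIDS.items():
                for value in grid:
                    if value == getattr(current, name):
                        continue
                    cand = replace(current, **{name: value})
                    loss = mean_loss(cand)
                    if loss < best:  # strict: ties keep the incumbent
                        current, best = cand, loss
                        history.append(best)
                        changed = True
            if not changed:
                break
        return current, best, history

    result = None
    for a in FIT_GRIDS["alpha_context"]:
        for bc in FIT_GRIDS["beta_context"]:
            start = replace(snapped, alpha_context=a, beta_context=bc)
            current, best, history = descend(start)
            if result is None or best < result[1]:
                result = (current, best, history)
    return result[0], result[2]
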