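"""Segmentation-quality metrics.

Six metrics compare a predicted mask ``B`` against a ground-truth mask ``A``
(and, for SSIM, two gray images):

* Dice coefficient ``2|A∩B| / (|A| + |B|)``
* IoU / Jaccard index ``|A∩B| / |A∪B|`` (so ``DSC = 2·IoU / (1 + IoU)``)
* boundary accuracy — the fraction of ground-truth boundary pixels that are
  also predicted boundary pixels
* Hausdorff distance — the exact max-min Euclidean distance between the two
  boundary point sets, in pixels
* SSIM — mean local structural similarity, 11x11 Gaussian window sigma=1.5,
  stabilizers ``C1=(0.01)^2``, ``C2=(0.03)^2`` on the [0,1] range
* PCP (proportion of correct patches) — the fraction of image tiles whose
  predicted and truth sub-masks agree (per-tile IoU >= 0.5, or both empty)

Boundary pixels are mask pixels with at least one background 4-neighbor,
with the image border counting as background. Two empty masks agree
perfectly for the overlap metrics (dice = iou = pcp = 1); the boundary
metrics are undefined on empty boundary sets and raise
:class:`~casdn.exceptions.UndefinedMetricError`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Set, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import directed_hausdorff
from skimage.metrics import structural_similarity

from .exceptions import DimensionError, UndefinedMetricError, ValidationError
from .io import validate_image, validate_mask


@dataclass(frozen=True)
class MetricReport:
    """All six metrics for one (prediction, truth) pair."""

    dsc: float
    iou: float
    boundary_accuracy: float
    hausdorff: float
    ssim: float
    pcp: float

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = validate_mask(a)
    b = validate_mask(b)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a.astype(bool), b.astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """``2|A∩B| / (|A| + |B|)``; two empty masks agree perfectly (1)."""
    a, b = _pair(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """``|A∩B| / |A∪B|``; two empty masks agree perfectly (1)."""
    a, b = _pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def boundary_pixels(m: np.ndarray) -> Set[Tuple[int, int]]:
    """Pixels of ``m`` with value 1 and at least one 4-neighbor equal to 0
    (out-of-image neighbors count as 0)."""
    m = validate_mask(m).astype(bool)
    interior = ndi.binary_erosion(
        m, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    rr, cc = np.nonzero(m & ~interior)
    return set(zip(rr.tolist(), cc.tolist()))


def boundary_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of ground-truth boundary pixels matched by predicted
    boundary pixels."""
    pred, truth = _pair(pred, truth)
    bt = boundary_pixels(truth.astype(np.uint8))
    if not bt:
        raise UndefinedMetricError(
            "boundary accuracy is undefined for an empty truth boundary"
        )
    bp = boundary_pixels(pred.astype(np.uint8))
    return len(bp & bt) / len(bt)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Exact symmetric Hausdorff distance between the two boundary sets,
    in pixels (Euclidean); 0 iff the boundary sets coincide."""
    a, b = _pair(a, b)
    pa = np.array(sorted(boundary_pixels(a.astype(np.uint8))), dtype=np.float64)
    pb = np.array(sorted(boundary_pixels(b.astype(np.uint8))), dtype=np.float64)
    if pa.size == 0 or pb.size == 0:
        raise UndefinedMetricError(
            "Hausdorff distance is undefined for an empty boundary set"
        )
    return float(max(
        directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]
    ))


def ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Mean local SSIM (11x11 Gaussian window, sigma=1.5, K1=0.01, K2=0.03)
    on the [0,1] intensity range; symmetric in its arguments."""
    x = validate_image(x)
    y = validate_image(y)
    if x.shape != y.shape:
        raise DimensionError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < 11:
        raise ValidationError(
            f"SSIM needs min(H, W) >= 11, got shape {x.shape}"
        )
    return float(structural_similarity(
        x, y, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, data_range=1.0,
    ))


def pcp(pred: np.ndarray, truth: np.ndarray, patch: int = 16,
        tile_iou_threshold: float = 0.5) -> float:
    """Proportion of correct patches.

    Both masks are tiled into ``patch x patch`` tiles (remainders absorbed
    by the last row/column); a tile is correct when its per-tile IoU is at
    least ``tile_iou_threshold``, or when both tiles are empty.
    """
    pred, truth = _pair(pred, truth)
    h, w = truth.shape
    if patch < 1:
        raise ValidationError(f"patch must be >= 1, got {patch}")
    if patch > min(h, w):
        raise ValidationError(
            f"patch={patch} exceeds the smallest mask side {min(h, w)}"
        )

    def edges(extent: int) -> np.ndarray:
        tiles = extent // patch
        e = np.arange(tiles + 1) * patch
        e[-1] = extent
        return e

    re, ce = edges(h), edges(w)
    correct = total = 0
    for r0, r1 in zip(re[:-1], re[1:]):
        for c0, c1 in zip(ce[:-1], ce[1:]):
            tp = pred[r0:r1, c0:c1]
            tt = truth[r0:r1, c0:c1]
            union = np.logical_or(tp, tt).sum()
            if union == 0:
                correct += 1
            elif np.logical_and(tp, tt).sum() / union >= tile_iou_threshold:
                correct += 1
            total += 1
    return correct / total


def evaluate(pred: np.ndarray, truth: np.ndarray,
             img_pred: np.ndarray | None = None,
             img_truth: np.ndarray | None = None,
             patch: int = 16) -> MetricReport:
    """All six metrics for one pair.

    SSIM compares ``img_pred`` with ``img_truth`` when both are given and
    falls back to comparing the masks as gray images otherwise.
    """
    if img_pred is None or img_truth is None:
        img_pred = validate_mask(pred).astype(np.float64)
        img_truth = validate_mask(truth).astype(np.float64)
    return MetricReport(
        dsc=dice(pred, truth),
        iou=iou(pred, truth),
        boundary_accuracy=boundary_accuracy(pred, truth),
        hausdorff=hausdorff(pred, truth),
        ssim=ssim(img_pred, img_truth),
        pcp=pcp(pred, truth, patch=patch),
    )
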