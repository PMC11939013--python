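"""Image, mask and configuration I/O.

Numeric contract used everywhere in the package:

* a *gray image* is a 2-D ``float64`` array with every value finite and in
  ``[0, 1]``, at least 8x8 pixels, row-major, origin at the top-left,
  0-based indices; window and box extents are half-open ``[r0, r1) x [c0, c1)``;
* a *binary mask* is a 2-D ``uint8`` array with values in ``{0, 1}``.

Images are stored on disk as 8- or 16-bit grayscale PNG or TIFF and rescaled
to ``[0, 1]`` by dividing by the bit-depth maximum; masks are 0/255 PNG.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from typing import Tuple

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .exceptions import FormatError, InputOutputError, ValidationError

logger = logging.getLogger("casdn")

MIN_SIDE = 8


# ---------------------------------------------------------------------------
# array validation
# ---------------------------------------------------------------------------

def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a gray image array (float64, [0,1], >= 8x8)."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"gray image must be 2-D, got ndim={arr.ndim}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ValidationError(
            f"gray image must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("gray image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(
            f"gray image values must lie in [0, 1], got range "
            f"[{arr.min():.6g}, {arr.max():.6g}]"
        )
    return arr


def validate_mask(pixels: np.ndarray, *, like: np.ndarray | None = None) -> np.ndarray:
    """Validate and return a binary mask array (uint8, {0,1})."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValidationError(f"binary mask must be 2-D, got ndim={arr.ndim}")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"binary mask values must be 0/1, got {vals[:8]}")
    if like is not None and arr.shape != np.asarray(like).shape:
        raise ValidationError(
            f"mask shape {arr.shape} does not match paired image shape "
            f"{np.asarray(like).shape}"
        )
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# image / mask files
# ---------------------------------------------------------------------------

_BIT_DEPTH_MAX = {8: 255, 16: 65535}


def _read_raw(path: str | os.PathLike) -> np.ndarray:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputOutputError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        return np.asarray(iio.imread(path))
    except (OSError, ValueError) as exc:  # pragma: no cover - delegated parsers
        raise FormatError(f"cannot decode {path}: {exc}") from exc


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load an 8- or 16-bit grayscale PNG/TIFF as a [0,1] float image.

    Multi-channel inputs are averaged to a single channel.
    """
    raw = _read_raw(path)
    if raw.ndim == 3:
        raw = raw.mean(axis=-1)
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D frame, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        scale = _BIT_DEPTH_MAX[8]
    elif raw.dtype == np.uint16:
        scale = _BIT_DEPTH_MAX[16]
    elif np.issubdtype(raw.dtype, np.floating):
        # channel averaging of integer data produces floats on the same scale
        scale = _BIT_DEPTH_MAX[8] if raw.max() > 1.0 else 1
        if raw.max() > 255.0:
            scale = _BIT_DEPTH_MAX[16]
    else:
        raise FormatError(f"{path}: unsupported pixel type {raw.dtype}")
    return validate_image(raw.astype(np.float64) / scale)


def save_image(img: np.ndarray, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a [0,1] gray image as an 8- or 16-bit PNG/TIFF.

    Round-trip through :func:`load_image` is exact to within one quantization
    step, ``1 / (2**bit_depth - 1)``.
    """
    if bit_depth not in _BIT_DEPTH_MAX:
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    img = validate_image(img)
    scale = _BIT_DEPTH_MAX[bit_depth]
    quant = np.rint(img * scale).astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            tifffile.imwrite(path, quant)
        else:
            iio.imwrite(path, quant)
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a 0/255 PNG mask as a {0,1} array.

    Any nonzero value is treated as foreground; values other than 0/255
    trigger a warning but are accepted.
    """
    raw = _read_raw(path)
    if raw.ndim == 3:
        raw = raw.max(axis=-1)
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D mask, got shape {raw.shape}")
    vals = np.unique(raw)
    if not np.isin(vals, (0, 255)).all():
        logger.warning(
            "%s: mask contains values other than 0/255 (%s); nonzero mapped to 1",
            path, vals[:8],
        )
    return validate_mask(raw != 0)


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as a 0/255 8-bit PNG; round-trip is exact."""
    mask = validate_mask(mask)
    try:
        iio.imwrite(os.fspath(path), (mask * 255).astype(np.uint8))
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AiptConfig:
    """Tunables of the eight-stage preprocessing chain.

    t_sobel          threshold on the max-normalized Sobel magnitude, [0, 1]
    t_canny          (low, high) percentiles of the nonzero gradient
                     magnitudes used for hysteresis, each in [0, 100]
    w_c              sliding-window side for local contrast normalization,
                     odd pixels
    sigma_c          Gaussian scale of the contextual map, pixels
    l_pyr            number of pyramid levels, >= 1
    t_saliency       saliency cut for region extraction, [0, 1]
    lambda_noise     context-aware noise filter strength, >= 0
    b_hist           histogram tile count per axis, >= 1
    alpha_edge       Sobel weight in the edge fusion, [0, 1]
    beta             image weight in the contextual fusion, [0, 1]
    """

    t_sobel: float = 0.1
    t_canny: Tuple[float, float] = (70.0, 90.0)
    w_c: int = 63
    sigma_c: float = 2.0
    l_pyr: int = 3
    t_saliency: float = 0.5
    lambda_noise: float = 1.0
    b_hist: int = 2
    alpha_edge: float = 0.5
    beta: float = 0.7

    def __post_init__(self) -> None:
        _check_range("t_sobel", self.t_sobel, 0.0, 1.0)
        low, high = self.t_canny
        _check_range("t_canny low", low, 0.0, 100.0)
        _check_range("t_canny high", high, 0.0, 100.0)
        if not low < high:
            raise ValidationError(
                f"t_canny requires low < high, got ({low}, {high})"
            )
        if self.w_c < 3 or self.w_c % 2 == 0:
            raise ValidationError(f"w_c must be odd and >= 3, got {self.w_c}")
        if self.sigma_c <= 0:
            raise ValidationError(f"sigma_c must be > 0, got {self.sigma_c}")
        if self.l_pyr < 1:
            raise ValidationError(f"l_pyr must be >= 1, got {self.l_pyr}")
        _check_range("t_saliency", self.t_saliency, 0.0, 1.0)
        if self.lambda_noise < 0:
            raise ValidationError(
                f"lambda_noise must be >= 0, got {self.lambda_noise}"
            )
        if self.b_hist < 1:
            raise ValidationError(f"b_hist must be >= 1, got {self.b_hist}")
        _check_range("alpha_edge", self.alpha_edge, 0.0, 1.0)
        _check_range("beta", self.beta, 0.0, 1.0)


@dataclass(frozen=True)
class CasdnConfig:
    """Tunables of the grid-decomposition segmenter.

    n_cells              grid-cell count, perfect square >= 4
    alpha_context        softmax sharpness on cell relevance, >= 0
    beta_context         saliency-gated adaptive-weighting strength, [0, 1]
    l_context            hierarchy level count, >= 1
    beta_refine          sigmoid-contrast refinement step, [0, 1]
    lambda_loss          overall loss scale, > 0
    alpha_spatial        spatial-loss weight, >= 0
    alpha_context_weight context-loss weight, >= 0 (stored separately from the
                         softmax sharpness so fitting one never rescales the
                         other)
    score_threshold      mask cut on the refined score map, (0, 1)
    n_refine_iter        refinement iterations (default 1)
    seed                 tie-breaking seed for fitting
    """

    n_cells: int = 16
    alpha_context: float = 1.0
    beta_context: float = 0.5
    l_context: int = 3
    beta_refine: float = 0.3
    lambda_loss: float = 1.0
    alpha_spatial: float = 0.5
    alpha_context_weight: float = 0.5
    score_threshold: float = 0.5
    n_refine_iter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        root = int(round(self.n_cells ** 0.5))
        if self.n_cells < 4 or root * root != self.n_cells:
            raise ValidationError(
                f"n_cells must be a perfect square >= 4, got {self.n_cells}"
            )
        if self.alpha_context < 0:
            raise ValidationError(
                f"alpha_context must be >= 0, got {self.alpha_context}"
            )
        _check_range("beta_context", self.beta_context, 0.0, 1.0)
        if self.l_context < 1:
            raise ValidationError(f"l_context must be >= 1, got {self.l_context}")
        _check_range("beta_refine", self.beta_refine, 0.0, 1.0)
        if self.lambda_loss <= 0:
            raise ValidationError(
                f"lambda_loss must be > 0, got {self.lambda_loss}"
            )
        if self.alpha_spatial < 0 or self.alpha_context_weight < 0:
            raise ValidationError("loss weights must be nonnegative")
        if not 0.0 < self.score_threshold < 1.0:
            raise ValidationError(
                f"score_threshold must lie in (0, 1), got {self.score_threshold}"
            )
        if self.n_refine_iter < 1:
            raise ValidationError(
                f"n_refine_iter must be >= 1, got {self.n_refine_iter}"
            )

    @property
    def grid_side(self) -> int:
        return int(round(self.n_cells ** 0.5))


_AIPT_KEYS = {f.name for f in dataclasses.fields(AiptConfig)}
_CASDN_KEYS = {f.name for f in dataclasses.fields(CasdnConfig)}


def load_config(path: str | os.PathLike) -> Tuple[AiptConfig, CasdnConfig]:
    """Parse a flat YAML key-value file into the two config objects.

    Missing keys take the documented defaults; unknown keys are rejected;
    out-of-range values raise :class:`ValidationError` naming the key.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputOutputError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a flat key-value mapping")
    unknown = set(data) - _AIPT_KEYS - _CASDN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    aipt_kwargs = {k: v for k, v in data.items() if k in _AIPT_KEYS}
    if "t_canny" in aipt_kwargs:
        aipt_kwargs["t_canny"] = tuple(aipt_kwargs["t_canny"])
    casdn_kwargs = {k: v for k, v in data.items() if k in _CASDN_KEYS}
    return AiptConfig(**aipt_kwargs), CasdnConfig(**casdn_kwargs)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValidationError(f"{name} must lie in [{lo}, {hi}], got {value}")
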