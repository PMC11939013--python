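"""Synthetic breast-imaging phantoms with exact lesion masks.

Real thermograms and mammograms suffer from inhomogeneous brightness, low
contrast and noise; the generator emulates exactly those degradations on an
image whose lesion mask is known by construction:

* background — a mid-gray plate (0.4) plus a Gaussian-smoothed random
  texture field of amplitude 0.1, standing in for parenchymal texture;
* lesions — non-overlapping soft-edged disks: a disk indicator smoothed
  with a 2-pixel Gaussian and raised by ``lesion_contrast``, so lesion
  edges roll off over a few pixels like real lesion margins; the mask is
  the half-contrast level set, which sits at the nominal disk radius;
* degradation — a linear illumination ramp of the given amplitude in a
  random direction, additive Gaussian noise, and a clip to [0, 1].

Each phantom draws from its own seeded generator, so every image/mask pair
is exactly reproducible and a dataset is defined by a base seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi

from .exceptions import CasdnError, ValidationError
from .io import validate_image, validate_mask


class PlacementError(CasdnError):
    """Could not place the requested non-overlapping lesions."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom.

    height, width            frame size, pixels
    n_lesions                lesion count, >= 0
    radius_range             (min, max) lesion radius, pixels, min >= 2
    lesion_contrast          intensity added inside a lesion, [0.05, 0.5]
    background_texture_sigma Gaussian scale of the background texture, pixels
    noise_sigma              additive Gaussian noise level, >= 0
    illumination_amplitude   end-to-end brightness ramp, [0, 0.4]
    seed                     generator seed
    """

    height: int = 128
    width: int = 128
    n_lesions: int = 1
    radius_range: Tuple[float, float] = (8.0, 16.0)
    lesion_contrast: float = 0.3
    background_texture_sigma: float = 6.0
    noise_sigma: float = 0.03
    illumination_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValidationError("phantom frame must be at least 8x8")
        if self.n_lesions < 0:
            raise ValidationError("n_lesions must be >= 0")
        rmin, rmax = self.radius_range
        if rmin < 2 or rmax < rmin:
            raise ValidationError(
                f"radius_range must satisfy 2 <= min <= max, got {self.radius_range}"
            )
        if rmax * 2 + 8 > min(self.height, self.width):
            raise ValidationError("lesions must fit inside the frame")
        if not 0.05 <= self.lesion_contrast <= 0.5:
            raise ValidationError(
                f"lesion_contrast must lie in [0.05, 0.5], got {self.lesion_contrast}"
            )
        if self.background_texture_sigma <= 0:
            raise ValidationError("background_texture_sigma must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0.0 <= self.illumination_amplitude <= 0.4:
            raise ValidationError(
                "illumination_amplitude must lie in [0, 0.4], "
                f"got {self.illumination_amplitude}"
            )


_EDGE_SIGMA = 2.0  # lesion edge falloff, pixels


def _ramp(shape: Tuple[int, int], amplitude: float, theta: float) -> np.ndarray:
    """Linear brightness ramp spanning ``amplitude`` end to end along the
    direction ``theta``, zero-mean."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    proj = np.cos(theta) * rr / max(h - 1, 1) + np.sin(theta) * cc / max(w - 1, 1)
    lo, hi = proj.min(), proj.max()
    t = (proj - lo) / (hi - lo) if hi > lo else np.zeros(shape)
    return amplitude * (t - 0.5)


def _apply_degradation(img: np.ndarray, noise_sigma: float,
                       illumination_amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    out = img + _ramp(img.shape, illumination_amplitude,
                      rng.uniform(0.0, 2.0 * np.pi))
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(out, 0.0, 1.0)


def degrade(img: np.ndarray, noise_sigma: float = 0.03,
            illumination_amplitude: float = 0.2, seed: int = 0) -> np.ndarray:
    """Apply ramp + noise + clip to an existing image (for clean-vs-degraded
    ablations); identity when both magnitudes are 0; deterministic per seed."""
    img = validate_image(img)
    if noise_sigma < 0 or not 0.0 <= illumination_amplitude <= 0.4:
        raise ValidationError("degradation parameters out of range")
    if noise_sigma == 0 and illumination_amplitude == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    return _apply_degradation(img, noise_sigma, illumination_amplitude, rng)


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Render one phantom and its exact lesion mask (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    texture = ndi.gaussian_filter(
        rng.standard_normal((h, w)), spec.background_texture_sigma, mode="reflect"
    )
    peak = np.abs(texture).max()
    if peak > 0:
        texture *= 0.1 / peak
    background = 0.4 + texture

    # rejection-sample non-overlapping lesion centers
    margin = _EDGE_SIGMA * 3
    placed: List[Tuple[float, float, float]] = []  # (row, col, radius)
    attempts = 0
    while len(placed) < spec.n_lesions:
        if attempts >= 1000:
            raise PlacementError(
                f"could not place {spec.n_lesions} non-overlapping lesions "
                f"in a {h}x{w} frame after 1000 attempts"
            )
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        cy = rng.uniform(r + margin, h - r - margin)
        cx = rng.uniform(r + margin, w - r - margin)
        if all(
            np.hypot(cy - py, cx - px) > r + pr + 2 * margin
            for py, px, pr in placed
        ):
            placed.append((cy, cx, r))

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    indicator = np.zeros((h, w))
    for cy, cx, r in placed:
        indicator = np.maximum(
            indicator, (np.hypot(rr - cy, cc - cx) <= r).astype(np.float64)
        )
    soft = ndi.gaussian_filter(indicator, _EDGE_SIGMA, mode="constant")
    # half-contrast level set: the smoothed step crosses 0.5 at the disk edge
    mask = validate_mask(soft >= 0.5)
    img = background + spec.lesion_contrast * soft
    img = _apply_degradation(
        np.clip(img, 0.0, 1.0), spec.noise_sigma,
        spec.illumination_amplitude, rng,
    )
    return validate_image(img), mask


def generate_dataset(
    spec: PhantomSpec, n: int, base_seed: int | None = None
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """n phantoms with seeds ``base_seed .. base_seed + n - 1``."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if base_seed is None:
        base_seed = spec.seed
    return [
        generate_phantom(replace(spec, seed=base_seed + i)) for i in range(n)
    ]
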