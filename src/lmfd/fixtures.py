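"""Deterministic synthetic-image generators.

Everything the robustness protocols need is generated here: textured
8-bit rasters, homography-warped pairs with exact ground truth, rotation
series about the image centre, additive-Gaussian-noise corruption and
multi-class texture datasets.  All generators are pure functions of their
arguments — the same seed always yields a bit-identical raster — which
keeps every downstream pipeline run reproducible.

The pixel model is 8-bit unsigned throughout; difference arithmetic in
the descriptor modules is done on signed integers.  Warping uses bilinear
interpolation, fills out-of-frame pixels with 0, and noise is applied
after warping (sensor noise on the second exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "SyntheticPair",
    "TextureDataset",
    "make_texture_image",
    "make_homography_pair",
    "make_rotation_series",
    "rotation_homography",
    "add_gaussian_noise",
    "make_texture_dataset",
    "TEXTURE_KINDS",
]

TEXTURE_KINDS = ("checker", "gabor", "blob_noise", "gradient")


@dataclass(frozen=True)
class SyntheticPair:
    """Two views of the same scene related by a known homography.

    ``image_b`` is ``image_a`` warped by ``h_true`` (a 3x3 matrix acting
    on homogeneous (col, row, 1) points, mapping a-coordinates to
    b-coordinates), optionally with Gaussian noise added after warping.
    """

    image_a: np.ndarray
    image_b: np.ndarray
    h_true: np.ndarray
    seed: int = 0


@dataclass(frozen=True)
class TextureDataset:
    """Labelled synthetic texture images for classification experiments."""

    images: list[np.ndarray]
    labels: np.ndarray
    n_classes: int
    seed: int = 0


def _to_uint8(a: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)


def _rescale_full_range(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.zeros_like(a, dtype=np.uint8)
    return _to_uint8((a - lo) / (hi - lo) * 255.0)


def make_texture_image(kind: str, size: int, seed: int) -> np.ndarray:
    """Generate a ``size`` x ``size`` textured 8-bit raster.

    Kinds: ``checker`` (binary {0, 255} checkerboard, cell size and phase
    seed-derived), ``gabor`` (oriented sinusoidal grating), ``blob_noise``
    (Gaussian-smoothed white noise), ``gradient`` (horizontal ramp, each
    column constant).  Non-degenerate kinds are rescaled to use the full
    0–255 range.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"unknown texture kind {kind!r}; expected one of {TEXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "checker":
        cell = int(rng.integers(5, 10))
        pr, pc = (int(v) for v in rng.integers(0, cell, size=2))
        r, c = np.mgrid[0:size, 0:size]
        return (((r + pr) // cell + (c + pc) // cell) % 2 * 255).astype(np.uint8)
    if kind == "gradient":
        col = np.rint(np.linspace(0.0, 255.0, size))
        return np.tile(col, (size, 1)).astype(np.uint8)
    if kind == "gabor":
        theta = rng.uniform(0.0, np.pi)
        freq = rng.uniform(0.06, 0.18)          # cycles per pixel
        phase = rng.uniform(0.0, 2 * np.pi)
        r, c = np.mgrid[0:size, 0:size]
        u = c * np.cos(theta) + r * np.sin(theta)
        v = -c * np.sin(theta) + r * np.cos(theta)
        g = np.sin(2 * np.pi * freq * u + phase) + 0.35 * np.sin(
            2 * np.pi * freq * 1.7 * v)
        return _rescale_full_range(g)
    # blob_noise
    sigma = rng.uniform(2.0, 3.5)
    noise = rng.standard_normal((size, size))
    return _rescale_full_range(ndimage.gaussian_filter(noise, sigma))


def warp_image(image: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply homography ``h`` (a->b on (col, row, 1) points) to an 8-bit
    raster with bilinear interpolation; exterior filled with 0."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape != (3, 3) or abs(np.linalg.det(h)) < 1e-12:
        raise ValueError("homography must be an invertible 3x3 matrix")
    tf = ProjectiveTransform(matrix=h)
    out = warp(np.asarray(image, dtype=np.float64), tf.inverse,
               order=1, cval=0.0, preserve_range=True)
    return _to_uint8(out)


def make_homography_pair(image: np.ndarray, h: np.ndarray,
                         noise_sigma: float = 0.0, seed: int = 0) -> SyntheticPair:
    """Warp ``image`` by ``h`` and (optionally) add sensor noise to the
    warped view; the exact ground-truth homography is stored."""
    h = np.asarray(h, dtype=np.float64)
    if h.shape != (3, 3) or abs(np.linalg.det(h)) < 1e-12:
        raise ValueError("homography must be an invertible 3x3 matrix")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    image = np.asarray(image, dtype=np.uint8)
    image_b = warp_image(image, h)
    if noise_sigma > 0:
        image_b = add_gaussian_noise(image_b, noise_sigma, seed)
    return SyntheticPair(image_a=image, image_b=image_b, h_true=h.copy(), seed=seed)


_EXACT_TRIG = {0: (1.0, 0.0), 90: (0.0, 1.0), 180: (-1.0, 0.0),
               270: (0.0, -1.0), 360: (1.0, 0.0)}


def rotation_homography(angle_deg: float, shape: tuple[int, int]) -> np.ndarray:
    """Homography rotating by ``angle_deg`` about the image centre.

    Acts on (col, row, 1) points; multiples of 90° use exact trigonometric
    values so lattice rotations stay exact.
    """
    h, w = shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    key = angle_deg % 360 if float(angle_deg).is_integer() else None
    if key is not None and int(key) in _EXACT_TRIG:
        ca, sa = _EXACT_TRIG[int(key)]
    else:
        t = np.deg2rad(angle_deg)
        ca, sa = np.cos(t), np.sin(t)
    T = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    R = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    Ti = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    return T @ R @ Ti


def make_rotation_series(image: np.ndarray, angles) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotate ``image`` about its centre for each angle in degrees.

    Returns ``[(rotated_raster, h_true), ...]`` with the exact per-angle
    ground-truth homography; out-of-frame pixels are filled with 0.
    """
    angles = list(angles)
    for a in angles:
        if not (0 <= a <= 360):
            raise ValueError(f"angles must lie in [0, 360], got {a}")
    image = np.asarray(image, dtype=np.uint8)
    out = []
    for a in angles:
        h = rotation_homography(a, image.shape)
        out.append((warp_image(image, h), h))
    return out


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise, clip to [0, 255] and round."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.uint8)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    return _to_uint8(noisy)


# Per-class parameter tiers for the texture dataset.  Classes cycle through
# the four generator kinds; each new cycle shifts the kind's parameters into
# a different band so classes stay visually and statistically distinct.
def _class_image(kind: str, tier: int, size: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "checker":
        cell = int(rng.integers(5, 9)) + 6 * tier
        pr, pc = (int(v) for v in rng.integers(0, cell, size=2))
        r, c = np.mgrid[0:size, 0:size]
        return (((r + pr) // cell + (c + pc) // cell) % 2 * 255).astype(np.uint8)
    if kind == "gabor":
        theta = rng.uniform(0.0, np.pi)
        freq = rng.uniform(0.05, 0.09) * (2.2 ** tier)
        phase = rng.uniform(0.0, 2 * np.pi)
        r, c = np.mgrid[0:size, 0:size]
        u = c * np.cos(theta) + r * np.sin(theta)
        return _rescale_full_range(np.sin(2 * np.pi * freq * u + phase))
    if kind == "blob_noise":
        sigma = rng.uniform(2.0, 3.0) * (2.0 ** tier)
        return _rescale_full_range(
            ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma))
    # gradient: ramp with seed-derived orientation flip per tier
    col = np.rint(np.linspace(0.0, 255.0, size))
    img = np.tile(col, (size, 1))
    if tier % 2 == 1:
        img = img.T
    return img.astype(np.uint8)


def make_texture_dataset(n_classes: int, per_class: int, size: int = 128,
                         seed: int = 0) -> TextureDataset:
    """Multi-class synthetic texture dataset.

    Classes differ by generator kind and parameter tier; within-class
    variation comes from seed-derived parameter jitter, a small random
    rotation (±8°) and mild sensor noise (sigma 4), emulating the
    appearance variation of real texture-classification benchmarks.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if per_class < 2:
        raise ValueError("per_class must be >= 2")
    images: list[np.ndarray] = []
    labels = np.repeat(np.arange(n_classes), per_class)
    for k in range(n_classes):
        kind = TEXTURE_KINDS[k % len(TEXTURE_KINDS)]
        tier = k // len(TEXTURE_KINDS)
        for i in range(per_class):
            rng = np.random.default_rng([seed, k, i])
            img = _class_image(kind, tier, size, rng)
            angle = float(rng.uniform(-8.0, 8.0)) % 360
            img = warp_image(img, rotation_homography(angle, img.shape))
            img = add_gaussian_noise(img, 4.0, int(rng.integers(0, 2**31)))
            images.append(img)
    return TextureDataset(images=images, labels=labels, n_classes=n_classes, seed=seed)
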