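"""Homography estimation and two-image stitching.

Registration uses the normalized (Hartley) direct linear transform inside
a seeded RANSAC loop; fusion is inverse bilinear warping onto a shared
canvas, a scalar exposure gain on the second image (ratio of overlap
means) and distance-weighted feather blending.

Point coordinates throughout are (col, row) = (x, y) with 0-based pixel
centres; homographies are 3x3 matrices on homogeneous (x, y, 1) points,
normalized so the bottom-right entry is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.transform import ProjectiveTransform, warp

from .descriptors import DescriptorParams, PatchDescriptor
from .detection import DetectorConfig, detect
from .matching import Match, match_nn

__all__ = [
    "DegenerateGeometryError",
    "RansacFailure",
    "StitchResult",
    "estimate_homography_dlt",
    "ransac_homography",
    "project",
    "stitch",
]


class DegenerateGeometryError(ValueError):
    """Point configuration does not determine a homography."""


class RansacFailure(RuntimeError):
    """RANSAC found no model supported by at least 4 inliers."""


@dataclass(frozen=True)
class StitchResult:
    """Output of the two-image stitching pipeline."""

    panorama: np.ndarray
    h_used: np.ndarray          # maps image_a (x, y, 1) -> image_b coordinates
    inlier_count: int
    gain: float
    n_matches: int = 0


def project(h: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a homography to an (n, 2) array of (x, y) points."""
    pts = np.asarray(pts, dtype=np.float64)
    ones = np.ones((pts.shape[0], 1))
    q = np.hstack([pts, ones]) @ np.asarray(h, dtype=np.float64).T
    return q[:, :2] / q[:, 2:3]


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid to origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1).mean()
    if dist < 1e-12:
        raise DegenerateGeometryError("all points coincide")
    s = np.sqrt(2.0) / dist
    return np.array([[s, 0, -s * centroid[0]],
                     [0, s, -s * centroid[1]],
                     [0, 0, 1.0]])


def estimate_homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares homography mapping src -> dst (both (n, 2), n >= 4).

    Hartley-normalized DLT; exact (to rounding) for noise-free inputs
    generated by a true homography.  Degenerate configurations (e.g. all
    points collinear) are rejected.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be (n, 2) arrays of equal shape")
    n = src.shape[0]
    if n < 4:
        raise DegenerateGeometryError(f"need >= 4 correspondences, got {n}")
    Ts = _normalization(src)
    Td = _normalization(dst)
    s = project(Ts, src)
    d = project(Td, dst)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -s * d[:, 0:1]
    A[0::2, 8] = -d[:, 0]
    A[1::2, 3:5] = s
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -s * d[:, 1:2]
    A[1::2, 8] = -d[:, 1]
    _, sv, vt = np.linalg.svd(A)
    # rank < 8 means the system does not pin down a homography
    if n == 4 and sv[7] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("degenerate (near-collinear) configuration")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise DegenerateGeometryError("homography at infinity for these points")
    H = H / H[2, 2]
    if abs(np.linalg.det(H)) < 1e-12:
        raise DegenerateGeometryError("estimated homography is singular")
    return H


def ransac_homography(src: np.ndarray, dst: np.ndarray, iterations: int = 2000,
                      inlier_px: float = 3.0, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Robust homography fit; returns (H, inlier_mask).

    Minimal 4-point DLT models are scored by inlier count (reprojection
    error <= ``inlier_px``), ties broken by lower total inlier error; the
    winner is refit on all its inliers.  Deterministic per seed.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    n = src.shape[0]
    if n < 4:
        raise RansacFailure(f"need >= 4 matches for RANSAC, got {n}")
    rng = np.random.default_rng(seed)
    best_count = 0
    best_err = np.inf
    best_mask = None
    for _ in range(iterations):
        idx = rng.choice(n, size=4, replace=False)
        try:
            H = estimate_homography_dlt(src[idx], dst[idx])
        except DegenerateGeometryError:
            continue
        err = np.linalg.norm(project(H, src) - dst, axis=1)
        mask = err <= inlier_px
        count = int(mask.sum())
        if count < 4:
            continue
        total = float(err[mask].sum())
        if count > best_count or (count == best_count and total < best_err):
            best_count, best_err, best_mask = count, total, mask
    if best_mask is None:
        raise RansacFailure(
            f"no homography with >= 4 inliers at {inlier_px} px over "
            f"{iterations} iterations ({n} matches)")
    H = estimate_homography_dlt(src[best_mask], dst[best_mask])
    return H, best_mask


def _warp_onto(image: np.ndarray, inv_map: np.ndarray,
               shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Warp image and its validity mask onto a canvas.

    ``inv_map`` maps canvas (x, y, 1) to source coordinates.
    """
    tf = ProjectiveTransform(matrix=inv_map)
    out = warp(image.astype(np.float64), tf, output_shape=shape,
               order=1, cval=0.0, preserve_range=True)
    mask = warp(np.ones(image.shape, dtype=np.float64), tf, output_shape=shape,
                order=1, cval=0.0, preserve_range=True)
    return out, mask > 0.999


def stitch(image_a: np.ndarray, image_b: np.ndarray,
           params: DescriptorParams | None = None,
           detector: DetectorConfig | None = None,
           seed: int = 0, ransac_iterations: int = 2000,
           inlier_px: float = 3.0) -> StitchResult:
    """Full pipeline: detect, describe, match, RANSAC, gain-correct,
    warp and feather-blend two overlapping greyscale images."""
    from .descriptors import describe  # local import keeps module load light

    params = params or DescriptorParams()
    detector = detector or DetectorConfig()
    kps_a = detect(image_a, detector, params)
    kps_b = detect(image_b, detector, params)
    desc_a = describe(image_a, kps_a, params)
    desc_b = describe(image_b, kps_b, params)
    if not desc_a or not desc_b:
        raise RansacFailure(
            f"not enough descriptors to register (a: {len(desc_a)}, b: {len(desc_b)})")
    matches = match_nn(desc_a, desc_b, cross_check=True)
    if len(matches) < 4:
        raise RansacFailure(f"only {len(matches)} matches; need >= 4")
    src = np.array([[desc_a[m.index_a].keypoint.col, desc_a[m.index_a].keypoint.row]
                    for m in matches], dtype=np.float64)
    dst = np.array([[desc_b[m.index_b].keypoint.col, desc_b[m.index_b].keypoint.row]
                    for m in matches], dtype=np.float64)
    try:
        H, mask = ransac_homography(src, dst, iterations=ransac_iterations,
                                    inlier_px=inlier_px, seed=seed)
    except RansacFailure as e:
        raise RansacFailure(
            f"registration failed ({len(matches)} matches): {e}") from e

    # canvas: union of a's frame and b's footprint mapped into a's frame
    ha, wa = image_a.shape[:2]
    hb, wb = image_b.shape[:2]
    Hinv = np.linalg.inv(H)
    corners_b = np.array([[0, 0], [wb - 1, 0], [wb - 1, hb - 1], [0, hb - 1]],
                         dtype=np.float64)
    fb = project(Hinv, corners_b)
    xs = np.concatenate([[0, wa - 1], fb[:, 0]])
    ys = np.concatenate([[0, ha - 1], fb[:, 1]])
    x0, y0 = int(np.floor(xs.min())), int(np.floor(ys.min()))
    x1, y1 = int(np.ceil(xs.max())), int(np.ceil(ys.max()))
    shape = (y1 - y0 + 1, x1 - x0 + 1)
    T = np.array([[1, 0, -x0], [0, 1, -y0], [0, 0, 1.0]])  # a-frame -> canvas
    # inverse maps: canvas -> source image coordinates
    A_img, A_mask = _warp_onto(np.asarray(image_a, dtype=np.float64),
                               np.linalg.inv(T), shape)
    B_img, B_mask = _warp_onto(np.asarray(image_b, dtype=np.float64),
                               H @ np.linalg.inv(T), shape)

    overlap = A_mask & B_mask
    if overlap.any() and B_img[overlap].mean() > 0:
        gain = float(A_img[overlap].mean() / B_img[overlap].mean())
    else:
        gain = 1.0
    B_img = np.clip(B_img * gain, 0, 255)

    wA = distance_transform_edt(A_mask)
    wB = distance_transform_edt(B_mask)
    wsum = wA + wB
    pano = np.zeros(shape, dtype=np.float64)
    both = wsum > 0
    pano[both] = (wA[both] * A_img[both] + wB[both] * B_img[both]) / wsum[both]
    only_a = A_mask & ~B_mask
    only_b = B_mask & ~A_mask
    pano[only_a] = A_img[only_a]
    pano[only_b] = B_img[only_b]
    panorama = np.clip(np.rint(pano), 0, 255).astype(np.uint8)
    return StitchResult(panorama=panorama, h_used=H,
                        inlier_count=int(mask.sum()), gain=gain,
                        n_matches=len(matches))
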