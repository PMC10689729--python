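"""Segment-test corner detection on the 16-point circle.

A pixel is a corner when at least ``arc_length`` contiguous circle pixels
are all brighter than the centre by more than ``threshold`` or all darker
by more than ``threshold`` (the FAST criterion).  The score of a corner
is the largest sum of ``|d_p| - t`` over any qualifying contiguous arc,
followed by score-based non-maximum suppression with lexicographic
tie-breaking for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import CIRCLE16_OFFSETS, DescriptorParams, Keypoint

__all__ = ["DetectorConfig", "Keypoint", "segment_test", "detect"]


@dataclass(frozen=True)
class DetectorConfig:
    """Segment-test parameters.

    threshold:
        Intensity difference a circle pixel must exceed (default 20).
    arc_length:
        Minimum contiguous arc length, 9..16 (default 9, the FAST-9
        convention).
    nms_radius:
        Chebyshev radius of non-maximum suppression (default 3).
    """

    threshold: int = 20
    arc_length: int = 9
    nms_radius: int = 3

    def __post_init__(self):
        if not (1 <= self.threshold <= 254):
            raise ValueError(f"threshold must be in [1, 254], got {self.threshold}")
        if not (9 <= self.arc_length <= 16):
            raise ValueError(f"arc_length must be in [9, 16], got {self.arc_length}")
        if self.nms_radius < 0:
            raise ValueError("nms_radius must be >= 0")


def _arc_score(d: np.ndarray, t: int, arc_length: int) -> tuple[bool, int]:
    """Exact run-based segment test for one circle of differences.

    Considers circular runs of pixels all > t (bright) or all < -t (dark);
    the score is the maximum of sum(|d| - t) over maximal qualifying runs.
    """
    best = 0
    excess = np.abs(d) - t
    for mask in (d > t, d < -t):
        if mask.all():
            # the entire circle qualifies
            best = max(best, int(excess.sum()))
            continue
        # doubling the circle turns circular runs into linear ones; the
        # running sum peaks at the end of each maximal run (excess > 0
        # inside a run), and runs cannot exceed 16 unless mask.all()
        m2 = np.concatenate([mask, mask])
        e2 = np.concatenate([excess, excess])
        run = 0
        run_sum = 0
        for i in range(32):
            if m2[i]:
                run += 1
                run_sum += int(e2[i])
                if run >= arc_length:
                    best = max(best, run_sum)
            else:
                run = 0
                run_sum = 0
    return best > 0, best


def segment_test(image: np.ndarray, p: tuple[int, int],
                 config: DetectorConfig | None = None) -> tuple[bool, int]:
    """Segment test at one pixel: (is_corner, score)."""
    config = config or DetectorConfig()
    image = np.asarray(image)
    r, c = int(p[0]), int(p[1])
    h, w = image.shape[:2]
    if not (3 <= r < h - 3 and 3 <= c < w - 3):
        raise ValueError(
            f"position ({r}, {c}) violates the 3 px circle margin of a {h}x{w} image")
    pc = int(image[r, c])
    d = np.array([int(image[r + dr, c + dc]) - pc for dr, dc in CIRCLE16_OFFSETS],
                 dtype=np.int64)
    return _arc_score(d, config.threshold, config.arc_length)


def _candidate_mask(image: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Vectorized corner predicate over the whole image (3 px margin)."""
    im = np.asarray(image, dtype=np.int64)
    h, w = im.shape
    core = im[3:h - 3, 3:w - 3]
    d = np.stack([im[3 + dr:h - 3 + dr, 3 + dc:w - 3 + dc] - core
                  for dr, dc in CIRCLE16_OFFSETS])
    corner = np.zeros(core.shape, dtype=bool)
    for sign_mask in (d > config.threshold, d < -config.threshold):
        ext = np.concatenate([sign_mask, sign_mask[:config.arc_length - 1]], axis=0)
        for s in range(16):
            acc = ext[s].copy()
            for i in range(1, config.arc_length):
                acc &= ext[s + i]
                if not acc.any():
                    break
            corner |= acc
    full = np.zeros(im.shape, dtype=bool)
    full[3:h - 3, 3:w - 3] = corner
    return full


def detect(image: np.ndarray, config: DetectorConfig | None = None,
           params: DescriptorParams | None = None) -> list[Keypoint]:
    """Detect corners and suppress non-maxima.

    Keypoints closer to the border than the descriptor's patch-plus-circle
    margin are excluded so downstream description never drops them.
    Surviving keypoints are pairwise more than ``nms_radius`` apart in
    Chebyshev distance; ties in score resolve toward the smaller
    (row, col).
    """
    config = config or DetectorConfig()
    params = params or DescriptorParams()
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < 2 * params.ps or w < 2 * params.ps:
        raise ValueError(f"image {h}x{w} smaller than (2*ps)^2 = {2 * params.ps}^2")
    margin = params.border_margin
    mask = _candidate_mask(image, config)
    mask[:margin, :] = False
    mask[h - margin:, :] = False
    mask[:, :margin] = False
    mask[:, w - margin:] = False
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    im = np.asarray(image, dtype=np.int64)
    cand = []
    for r, c in zip(rows.tolist(), cols.tolist()):
        d = np.array([im[r + dr, c + dc] - im[r, c] for dr, dc in CIRCLE16_OFFSETS])
        ok, score = _arc_score(d, config.threshold, config.arc_length)
        if ok and score > 0:
            cand.append((score, r, c))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[Keypoint] = []
    kr = np.empty(len(cand), dtype=np.int64)
    kc = np.empty(len(cand), dtype=np.int64)
    n = 0
    for score, r, c in cand:
        if n:
            if (np.maximum(np.abs(kr[:n] - r), np.abs(kc[:n] - c)) <= config.nms_radius).any():
                continue
        kr[n] = r
        kc[n] = c
        n += 1
        kept.append(Keypoint(row=r, col=c, score=score))
    kept.sort(key=lambda k: (k.row, k.col))
    return kept
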