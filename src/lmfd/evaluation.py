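"""Robustness-measurement protocols on synthetic ground-truth fixtures.

Three protocols are implemented at desk scale:

* mean matching accuracy (MMA) versus pixel threshold 1..10 under a known
  homography;
* rotation sweep: correct cross-checked matches between an image and its
  rotations 0–360°;
* Gaussian-noise sweep: ratio of correct matches after noise of sigma
  10..50 is added to the second view, relative to the noise-free count;

plus a comparison of the six descriptor block orders under an identical
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixtures
from .descriptors import ORDERS, DescriptorParams
from .detection import DetectorConfig
from .geometry import project
from .matching import Match
from .pipeline import (correct_match_count, detect_and_describe, match_points,
                       truncate_to_prefix)

__all__ = ["MMACurve", "SweepResult", "EmptyMatchSetError", "mma_curve",
           "rotation_sweep", "noise_sweep", "order_comparison"]


class EmptyMatchSetError(ValueError):
    """A protocol was asked to score an empty match set."""


@dataclass(frozen=True)
class MMACurve:
    """Matching accuracy per pixel threshold."""

    thresholds: tuple[int, ...]
    mma: tuple[float, ...]
    n_matches: int
    n_features: int = 0


@dataclass(frozen=True)
class SweepResult:
    """One robustness sweep: x values and the measured response per x."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    raw_counts: tuple[int, ...] = ()
    params: DescriptorParams | None = None


def mma_curve(pts_a: np.ndarray, pts_b: np.ndarray, h_true: np.ndarray,
              thresholds=range(1, 11), n_features: int = 0) -> MMACurve:
    """Fraction of matches whose reprojection error under ``h_true`` is
    within each threshold.  ``pts_a``/``pts_b`` are matched (x, y) arrays.
    """
    pts_a = np.asarray(pts_a, dtype=np.float64).reshape(-1, 2)
    pts_b = np.asarray(pts_b, dtype=np.float64).reshape(-1, 2)
    if len(pts_a) == 0:
        raise EmptyMatchSetError("cannot compute MMA from zero matches")
    if len(pts_a) != len(pts_b):
        raise ValueError("matched point arrays must have equal length")
    err = np.linalg.norm(project(h_true, pts_a) - pts_b, axis=1)
    ths = tuple(int(t) for t in thresholds)
    mma = tuple(float((err <= t).mean()) for t in ths)
    return MMACurve(thresholds=ths, mma=mma, n_matches=len(pts_a),
                    n_features=n_features)


def rotation_sweep(image: np.ndarray, angles=tuple(range(0, 361, 15)),
                   params: DescriptorParams | None = None,
                   detector: DetectorConfig | None = None,
                   tol_px: float = 3.0) -> SweepResult:
    """Correct cross-checked matches between ``image`` and its rotations.

    ``y`` holds the count of matches consistent with the known rotation
    homography within ``tol_px``; ``raw_counts`` the unfiltered match
    counts.
    """
    params = params or DescriptorParams()
    detector = detector or DetectorConfig()
    base = detect_and_describe(image, params, detector)
    correct, raw = [], []
    for rotated, h in fixtures.make_rotation_series(image, angles):
        rot_desc = detect_and_describe(rotated, params, detector)
        if not base or not rot_desc:
            correct.append(0)
            raw.append(0)
            continue
        _, pts_a, pts_b = match_points(base, rot_desc)
        raw.append(len(pts_a))
        correct.append(correct_match_count(pts_a, pts_b, h, tol_px))
    return SweepResult(x=tuple(float(a) for a in angles),
                       y=tuple(float(c) for c in correct),
                       raw_counts=tuple(raw), params=params)


def noise_sweep(pair: fixtures.SyntheticPair, sigmas=(10, 20, 30, 40, 50),
                params: DescriptorParams | None = None,
                detector: DetectorConfig | None = None,
                seed: int = 0, tol_px: float = 3.0) -> SweepResult:
    """Correct-match ratio after adding Gaussian noise to the second view.

    ``ratio(sigma) = correct(sigma) / correct(0)``; sigma 0, if requested,
    is exactly 1.  Raises when the noise-free pipeline yields no correct
    matches (the ratio would be 0/0).
    """
    params = params or DescriptorParams()
    detector = detector or DetectorConfig()
    desc_a = detect_and_describe(pair.image_a, params, detector)

    def correct_for(image_b: np.ndarray) -> int:
        desc_b = detect_and_describe(image_b, params, detector)
        if not desc_a or not desc_b:
            return 0
        _, pts_a, pts_b = match_points(desc_a, desc_b)
        return correct_match_count(pts_a, pts_b, pair.h_true, tol_px)

    base = correct_for(pair.image_b)
    if base == 0:
        raise EmptyMatchSetError("no correct matches at sigma = 0; "
                                 "ratios are undefined")
    ratios, raw = [], []
    for i, sigma in enumerate(sigmas):
        if sigma == 0:
            ratios.append(1.0)
            raw.append(base)
            continue
        noisy = fixtures.add_gaussian_noise(pair.image_b, float(sigma),
                                            seed=seed + i)
        c = correct_for(noisy)
        raw.append(c)
        ratios.append(c / base)
    return SweepResult(x=tuple(float(s) for s in sigmas), y=tuple(ratios),
                       raw_counts=tuple(raw), params=params)


def order_comparison(pairs: list[fixtures.SyntheticPair], orders=ORDERS,
                     params: DescriptorParams | None = None,
                     detector: DetectorConfig | None = None,
                     tol_px: float = 3.0, prefix_bits: int | None = None,
                     ratio: float | None = None,
                     max_distance: int | None = None) -> list[tuple[str, float]]:
    """Mean correct-match count per block order, ranked best-first.

    With plain mutual-NN Hamming matching all orders give identical
    counts (reordering blocks permutes both descriptors' bits
    identically, preserving every pairwise distance).  The comparison
    becomes discriminative with ``prefix_bits`` (match only the
    high-order bits of each combination) and/or a ratio/distance filter.
    """
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 pairs, got {len(pairs)}")
    base_params = params or DescriptorParams()
    detector = detector or DetectorConfig()
    results: dict[str, list[int]] = {o: [] for o in orders}
    for pair in pairs:
        for order in orders:
            p = DescriptorParams(r=base_params.r, kz=base_params.kz,
                                 ps=base_params.ps, order=order)
            desc_a = detect_and_describe(pair.image_a, p, detector)
            desc_b = detect_and_describe(pair.image_b, p, detector)
            if not desc_a or not desc_b:
                results[order].append(0)
                continue
            if prefix_bits is not None:
                desc_a = truncate_to_prefix(desc_a, prefix_bits)
                desc_b = truncate_to_prefix(desc_b, prefix_bits)
            _, pts_a, pts_b = match_points(desc_a, desc_b, ratio=ratio,
                                           max_distance=max_distance)
            results[order].append(
                correct_match_count(pts_a, pts_b, pair.h_true, tol_px))
    table = [(o, float(np.mean(results[o]))) for o in orders]
    table.sort(key=lambda t: (-t[1], t[0]))
    return table
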