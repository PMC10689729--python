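"""Naive brute-force reference implementations used as independent oracles.

Everything here is written as plain nested loops, directly from the
definitions, with no shared code paths with the package internals.
"""

from __future__ import annotations

import numpy as np


def ring_offsets_naive(w: int) -> list[tuple[int, int]]:
    """Ring-by-ring outward, each ring clockwise from its top-left."""
    kz = (w - 1) // 2
    out = []
    for k in range(1, kz + 1):
        ring = []
        for c in range(-k, k):
            ring.append((-k, c))
        for r in range(-k, k):
            ring.append((r, k))
        for c in range(k, -k, -1):
            ring.append((k, c))
        for r in range(k, -k, -1):
            ring.append((r, -k))
        out.extend(ring)
    return out


def symbolic_naive(patch: np.ndarray, kz: int) -> list[int]:
    patch = np.asarray(patch, dtype=int)
    w = 2 * kz + 1
    ps = patch.shape[0]
    bits = []
    for i in range(ps - w + 1):
        for j in range(ps - w + 1):
            win = patch[i:i + w, j:j + w]
            center = int(win[kz, kz])
            for dr, dc in ring_offsets_naive(w):
                bits.append(1 if center > int(win[kz + dr, kz + dc]) else 0)
    return bits


def mean_naive(patch: np.ndarray, kz: int) -> list[int]:
    patch = np.asarray(patch, dtype=float)
    w = 2 * kz + 1
    ps = patch.shape[0]
    pc = (ps - 1) // 2
    m_c = patch[pc - kz:pc + kz + 1, pc - kz:pc + kz + 1].mean()
    bits = []
    for i in range(ps - w + 1):
        for j in range(ps - w + 1):
            bits.append(1 if patch[i:i + w, j:j + w].mean() > m_c else 0)
    return bits


def centroid_naive(patch: np.ndarray, kz: int, image_mean: float) -> list[int]:
    patch = np.asarray(patch, dtype=float)
    w = 2 * kz + 1
    ps = patch.shape[0]
    c_ref = (patch.mean() + image_mean) / 2.0
    bits = []
    for i in range(ps - w + 1):
        for j in range(ps - w + 1):
            win = patch[i:i + w, j:j + w]
            total = win.sum()
            if total > 0:
                rbar = sum(r * win[r, c] for r in range(w) for c in range(w)) / total
                cbar = sum(c * win[r, c] for r in range(w) for c in range(w)) / total
            else:
                rbar = cbar = float(kz)
            ri = _nearest_naive(rbar, kz, w)
            ci = _nearest_naive(cbar, kz, w)
            bits.append(1 if win[ri, ci] > c_ref else 0)
    return bits


def _nearest_naive(x: float, center: int, w: int) -> int:
    f = min(max(int(np.floor(x)), 0), w - 1)
    g = min(f + 1, w - 1)
    if abs(x - g) < abs(x - f):
        return g
    if abs(x - g) == abs(x - f) and abs(g - center) < abs(f - center):
        return g
    return f


CIRCLE16 = [(-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
            (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1)]


def segment_test_naive(image: np.ndarray, r: int, c: int, t: int,
                       arc_length: int) -> tuple[bool, int]:
    """Exhaustive over all 16 start positions and arc lengths."""
    image = np.asarray(image, dtype=int)
    d = [int(image[r + dr, c + dc]) - int(image[r, c]) for dr, dc in CIRCLE16]
    best = 0
    found = False
    for start in range(16):
        for length in range(arc_length, 17):
            arc = [d[(start + i) % 16] for i in range(length)]
            if all(v > t for v in arc) or all(v < -t for v in arc):
                found = True
                best = max(best, sum(abs(v) - t for v in arc))
    return found, best


def hamming_naive(bits_a, bits_b) -> int:
    return sum(1 for x, y in zip(bits_a, bits_b) if bool(x) != bool(y))


def mutual_nn_naive(bit_lists_a, bit_lists_b) -> list[tuple[int, int, int]]:
    """All-pairs mutual nearest neighbours, ties to the smallest index."""
    na, nb = len(bit_lists_a), len(bit_lists_b)
    D = [[hamming_naive(bit_lists_a[i], bit_lists_b[j]) for j in range(nb)]
         for i in range(na)]
    nn_b = [min(range(nb), key=lambda j: (D[i][j], j)) for i in range(na)]
    nn_a = [min(range(na), key=lambda i: (D[i][j], i)) for j in range(nb)]
    return [(i, nn_b[i], D[i][nn_b[i]]) for i in range(na) if nn_a[nn_b[i]] == i]
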