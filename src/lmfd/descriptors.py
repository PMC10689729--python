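"""Multi-feature binary descriptors built on a circular sign/magnitude transform.

A keypoint is described by three binary blocks computed from the square
patch around it with a sliding window of side ``w = 2*kz + 1``:

symbolic
    per window, one bit per surrounding pixel — 1 iff the window's central
    pixel is strictly brighter than that surrounding pixel;
mean
    per window, one bit — 1 iff the window's mean exceeds the mean of the
    window centred on the keypoint;
centroid
    per window, one bit — 1 iff the intensity at the window's
    intensity-weighted centroid exceeds the average of the patch mean and
    the whole-image mean.

The blocks are concatenated in a configurable order (MSC, CSM, ...) into a
single packed bit vector matched by Hamming distance.  The sign/magnitude
split of the 16-point circular difference vector (the same circle the
segment-test detector uses) is exposed as :func:`decompose` /
:func:`reconstruct`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CIRCLE16_OFFSETS",
    "circle16_offsets",
    "DifferenceDecomposition",
    "difference_vector",
    "decompose",
    "reconstruct",
    "DescriptorParams",
    "BlockLayout",
    "PatchDescriptor",
    "window_ring_offsets",
    "symbolic_descriptor",
    "mean_descriptor",
    "centroid_descriptor",
    "combine",
    "split",
    "describe",
    "pack_bits",
    "unpack_bits",
]

log = logging.getLogger(__name__)

ORDERS = ("CSM", "CMS", "SCM", "SMC", "MSC", "MCS")

#: The 16 (row, col) offsets of the discrete radius-3 (Bresenham) circle,
#: clockwise from 12 o'clock, i.e. starting at (-3, 0).
CIRCLE16_OFFSETS: tuple[tuple[int, int], ...] = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3),
    (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3),
    (0, -3), (-1, -3), (-2, -2), (-3, -1),
)


def circle16_offsets() -> list[tuple[int, int]]:
    """Ordered (row, col) offsets of the 16-point circle of radius 3."""
    return list(CIRCLE16_OFFSETS)


# ---------------------------------------------------------------------------
# sign/magnitude difference transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferenceDecomposition:
    """Circular difference vector and its sign/magnitude split.

    ``d[p] = ring[p] - center``; ``s[p] = 1`` iff ``d[p] >= 0``;
    ``m[p] = |d[p]|``.  ``(2*s - 1) * m`` reconstructs ``d`` elementwise.
    """

    d: np.ndarray
    s: np.ndarray
    m: np.ndarray


def decompose(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed difference vector into sign (0/1) and magnitude parts.

    The sign is 1 where ``d >= 0`` (zero differences count as positive,
    so they carry sign 1 and magnitude 0).
    """
    d = np.asarray(d, dtype=np.int64)
    s = (d >= 0).astype(np.uint8)
    m = np.abs(d)
    return s, m


def reconstruct(s: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Rebuild the signed difference vector from sign and magnitude parts."""
    s = np.asarray(s)
    m = np.asarray(m, dtype=np.int64)
    if s.shape != m.shape:
        raise ValueError(f"sign/magnitude length mismatch: {s.shape} vs {m.shape}")
    if np.any(m < 0):
        raise ValueError("magnitudes must be non-negative")
    if not np.all((s == 0) | (s == 1)):
        raise ValueError("sign vector must be 0/1")
    return np.where(s == 1, m, -m)


def difference_vector(image: np.ndarray, center: tuple[int, int]) -> DifferenceDecomposition:
    """Circular difference vector at ``center`` and its sign/magnitude split.

    Parameters
    ----------
    image:
        2-D 8-bit raster.
    center:
        (row, col) of the central pixel; must lie at least 3 px from
        every border so the 16-point circle fits.
    """
    image = np.asarray(image)
    r, c = int(center[0]), int(center[1])
    h, w = image.shape[:2]
    if not (3 <= r < h - 3 and 3 <= c < w - 3):
        raise ValueError(
            f"center ({r}, {c}) closer than the required 3 px margin to the "
            f"border of a {h}x{w} image"
        )
    pc = int(image[r, c])
    ring = np.array([int(image[r + dr, c + dc]) for dr, dc in CIRCLE16_OFFSETS],
                    dtype=np.int64)
    d = ring - pc
    s, m = decompose(d)
    return DifferenceDecomposition(d=d, s=s, m=m)


# ---------------------------------------------------------------------------
# parameters and layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorParams:
    """Geometry and layout of the combined descriptor.

    Parameters
    ----------
    r:
        Detection-region radius in pixels.  Sets the default patch side
        ``ps = 2*r - 1``.
    kz:
        Sliding-window half-width; window side ``w = 2*kz + 1``.
    ps:
        Patch side in pixels (odd, >= w + 2).  ``None`` means ``2*r - 1``.
    order:
        Block concatenation order; one of CSM, CMS, SCM, SMC, MSC, MCS,
        first-named block at the lowest bit indices.
    """

    r: int = 3
    kz: int = 1
    ps: int | None = None
    order: str = "MSC"

    def __post_init__(self):
        if self.ps is None:
            object.__setattr__(self, "ps", 2 * self.r - 1)
        if self.kz < 1:
            raise ValueError("kz must be >= 1")
        if self.ps % 2 == 0:
            raise ValueError(f"patch side ps={self.ps} must be odd")
        if self.ps < self.w + 2:
            raise ValueError(f"patch side ps={self.ps} must be >= w + 2 = {self.w + 2}")
        if self.order not in ORDERS:
            raise ValueError(f"unknown order {self.order!r}; expected one of {ORDERS}")

    @property
    def w(self) -> int:
        """Sliding-window side, ``2*kz + 1``."""
        return 2 * self.kz + 1

    @property
    def n_windows(self) -> int:
        """Number of sliding-window positions W = (ps - w + 1)^2."""
        return (self.ps - self.w + 1) ** 2

    @property
    def code_len(self) -> int:
        """Symbolic bits per window, ``w^2 - 1``."""
        return self.w ** 2 - 1

    @property
    def bit_width(self) -> int:
        """Total bits: W*(w^2-1) symbolic + W mean + W centroid."""
        return self.n_windows * (self.code_len + 2)

    @property
    def border_margin(self) -> int:
        """Minimum keypoint distance from the border: patch plus circle."""
        return math.ceil(self.ps / 2) + 3

    @property
    def layout(self) -> "BlockLayout":
        return BlockLayout(order=self.order, n_windows=self.n_windows,
                           code_len=self.code_len)


@dataclass(frozen=True)
class BlockLayout:
    """How the three blocks partition the combined bit vector."""

    order: str
    n_windows: int
    code_len: int

    @property
    def block_lengths(self) -> dict[str, int]:
        return {"S": self.n_windows * self.code_len,
                "M": self.n_windows,
                "C": self.n_windows}

    @property
    def bit_width(self) -> int:
        return self.n_windows * (self.code_len + 2)

    def slices(self) -> dict[str, slice]:
        """Bit-index slice of each block in concatenation order."""
        out, start = {}, 0
        for name in self.order:
            n = self.block_lengths[name]
            out[name] = slice(start, start + n)
            start += n
        return out


@dataclass(frozen=True)
class Keypoint:
    """A detected corner: 0-based (row, col) and a non-negative score."""

    row: int
    col: int
    score: int = 0


@dataclass(frozen=True)
class PatchDescriptor:
    """Packed binary descriptor of one keypoint's patch."""

    packed: np.ndarray          # uint8, little-endian bit packing
    layout: BlockLayout
    keypoint: Keypoint

    @property
    def bits(self) -> np.ndarray:
        return unpack_bits(self.packed, self.layout.bit_width)

    @property
    def bit_width(self) -> int:
        return self.layout.bit_width


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a 0/1 vector into bytes, little-endian within each byte."""
    return np.packbits(np.asarray(bits, dtype=np.uint8), bitorder="little")


def unpack_bits(packed: np.ndarray, n_bits: int) -> np.ndarray:
    return np.unpackbits(packed, count=n_bits, bitorder="little").astype(bool)


# ---------------------------------------------------------------------------
# per-window orderings
# ---------------------------------------------------------------------------

def window_ring_offsets(w: int) -> list[tuple[int, int]]:
    """Offsets of the ``w^2 - 1`` non-central window pixels.

    Ordered ring-by-ring outward from the centre; within each ring
    clockwise starting at the ring's top-left corner.  For ``w = 3`` this
    is the familiar 8-neighbour clockwise walk from (-1, -1).
    """
    if w % 2 == 0 or w < 3:
        raise ValueError(f"window side must be odd and >= 3, got {w}")
    kz = (w - 1) // 2
    offsets: list[tuple[int, int]] = []
    for k in range(1, kz + 1):
        ring: list[tuple[int, int]] = []
        ring += [(-k, c) for c in range(-k, k)]        # top edge, left -> right
        ring += [(r, k) for r in range(-k, k)]         # right edge, top -> bottom
        ring += [(k, c) for c in range(k, -k, -1)]     # bottom edge, right -> left
        ring += [(r, -k) for r in range(k, -k, -1)]    # left edge, bottom -> top
        offsets += ring
    return offsets


def _windows(patch: np.ndarray, kz: int) -> np.ndarray:
    """All sliding windows of a patch: shape (nw, nw, w, w), raster order."""
    patch = np.asarray(patch)
    w = 2 * kz + 1
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2-D, got shape {patch.shape}")
    if patch.shape[0] < w:
        raise ValueError(f"patch side {patch.shape[0]} smaller than window side {w}")
    return sliding_window_view(patch, (w, w))


# ---------------------------------------------------------------------------
# the three descriptor blocks
# ---------------------------------------------------------------------------

def symbolic_descriptor(patch: np.ndarray, kz: int) -> np.ndarray:
    """Symbolic block: centre-vs-surround comparison bits for every window.

    Windows are enumerated in raster order over the patch; within each
    window the central pixel is compared to each surrounding pixel in the
    :func:`window_ring_offsets` order, bit 1 iff strictly greater.
    Returns a boolean vector of length ``W * (w^2 - 1)``.
    """
    win = _windows(np.asarray(patch, dtype=np.int64), kz)
    center = win[..., kz, kz]
    bits = [center > win[..., kz + dr, kz + dc]
            for dr, dc in window_ring_offsets(2 * kz + 1)]
    # stack -> (nw, nw, code_len), then raster-flatten windows
    return np.stack(bits, axis=-1).reshape(-1)


def mean_descriptor(patch: np.ndarray, kz: int) -> np.ndarray:
    """Mean block: one bit per window, 1 iff its mean exceeds the mean of
    the window centred on the patch centre (the keypoint's own window)."""
    patch = np.asarray(patch, dtype=np.float64)
    win = _windows(patch, kz)
    means = win.mean(axis=(2, 3))
    pc = (patch.shape[0] - 1) // 2          # patch centre index
    m_c = means[pc - kz, pc - kz]           # window centred on the keypoint
    return (means > m_c).reshape(-1)


def centroid_descriptor(patch: np.ndarray, kz: int, image_mean: float) -> np.ndarray:
    """Centroid block: one bit per window.

    For each window the intensity-weighted centroid location is computed
    (the window centre when total intensity is zero); the centroid value
    is the intensity of the nearest pixel to that location, ties broken
    toward the window centre.  Bit 1 iff that value strictly exceeds
    ``c = (patch_mean + image_mean) / 2``.
    """
    patch = np.asarray(patch, dtype=np.float64)
    w = 2 * kz + 1
    win = _windows(patch, kz)
    total = win.sum(axis=(2, 3))
    idx = np.arange(w, dtype=np.float64)
    rbar = np.where(total > 0, (win * idx[None, None, :, None]).sum(axis=(2, 3))
                    / np.where(total > 0, total, 1.0), float(kz))
    cbar = np.where(total > 0, (win * idx[None, None, None, :]).sum(axis=(2, 3))
                    / np.where(total > 0, total, 1.0), float(kz))
    ri = _nearest_index(rbar, kz, w)
    ci = _nearest_index(cbar, kz, w)
    nw = win.shape[0]
    g = win[np.arange(nw)[:, None], np.arange(nw)[None, :], ri, ci]
    c_ref = (patch.mean() + float(image_mean)) / 2.0
    return (g > c_ref).reshape(-1)


def _nearest_index(x: np.ndarray, center: int, w: int) -> np.ndarray:
    """Nearest integer index to x in [0, w-1]; exact .5 ties resolve toward
    ``center``."""
    f = np.floor(x).astype(np.int64)
    f = np.clip(f, 0, w - 1)
    g = np.clip(f + 1, 0, w - 1)
    df = np.abs(x - f)
    dg = np.abs(x - g)
    pick_g = (dg < df) | ((dg == df) & (np.abs(g - center) < np.abs(f - center)))
    return np.where(pick_g, g, f)


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combine(S: np.ndarray, M: np.ndarray, C: np.ndarray, order: str = "MSC") -> np.ndarray:
    """Concatenate the three blocks; the first-named block of ``order``
    occupies the lowest bit indices (most significant position)."""
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    S = np.asarray(S, dtype=bool).ravel()
    M = np.asarray(M, dtype=bool).ravel()
    C = np.asarray(C, dtype=bool).ravel()
    nw = M.size
    if C.size != nw or nw == 0 or S.size % nw != 0:
        raise ValueError(
            f"inconsistent block lengths: S={S.size}, M={M.size}, C={C.size}")
    blocks = {"S": S, "M": M, "C": C}
    return np.concatenate([blocks[name] for name in order])


def split(bits: np.ndarray, layout: BlockLayout) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (S, M, C) from a combined bit vector."""
    bits = np.asarray(bits, dtype=bool).ravel()
    if bits.size != layout.bit_width:
        raise ValueError(f"expected {layout.bit_width} bits, got {bits.size}")
    sl = layout.slices()
    return bits[sl["S"]], bits[sl["M"]], bits[sl["C"]]


# ---------------------------------------------------------------------------
# whole-image description
# ---------------------------------------------------------------------------

def describe(image: np.ndarray, keypoints: list[Keypoint],
             params: DescriptorParams | None = None) -> list[PatchDescriptor]:
    """Describe each keypoint's patch; border-violating keypoints are
    dropped (and logged), not an error.

    The whole-image mean used by the centroid block is computed once.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot describe an empty image")
    params = params or DescriptorParams()
    h, w = image.shape[:2]
    margin = params.border_margin
    half = (params.ps - 1) // 2
    image_mean = float(image.mean())
    layout = params.layout
    out: list[PatchDescriptor] = []
    n_dropped = 0
    for kp in keypoints:
        r, c = kp.row, kp.col
        if not (margin <= r < h - margin and margin <= c < w - margin):
            n_dropped += 1
            continue
        patch = image[r - half: r + half + 1, c - half: c + half + 1]
        S = symbolic_descriptor(patch, params.kz)
        M = mean_descriptor(patch, params.kz)
        C = centroid_descriptor(patch, params.kz, image_mean)
        bits = combine(S, M, C, params.order)
        out.append(PatchDescriptor(packed=pack_bits(bits), layout=layout, keypoint=kp))
    if n_dropped:
        log.info("describe: dropped %d keypoint(s) within %d px of the border",
                 n_dropped, margin)
    return out
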