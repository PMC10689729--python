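"""Hamming nearest-neighbour matching of packed binary descriptors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import BlockLayout, PatchDescriptor

__all__ = ["Match", "hamming", "match_nn"]


@dataclass(frozen=True)
class Match:
    """One correspondence between descriptor lists a and b."""

    index_a: int
    index_b: int
    distance: int


def _check_layouts(la: BlockLayout, lb: BlockLayout) -> None:
    if la != lb:
        raise ValueError(
            f"descriptor layouts are not comparable: {la} vs {lb} "
            "(block orders permute bits, so Hamming distances across "
            "orders are meaningless)")


def hamming(a: PatchDescriptor, b: PatchDescriptor) -> int:
    """Hamming distance = popcount of XOR of the packed bit vectors."""
    _check_layouts(a.layout, b.layout)
    return int(np.bitwise_count(a.packed ^ b.packed).sum())


def _packed_matrix(descs: list[PatchDescriptor]) -> np.ndarray:
    return np.stack([d.packed for d in descs])


def match_nn(desc_a: list[PatchDescriptor], desc_b: list[PatchDescriptor],
             cross_check: bool = True, max_distance: int | None = None,
             ratio: float | None = None) -> list[Match]:
    """Nearest-neighbour matches from a to b by Hamming distance.

    Ties resolve to the smallest b index.  With ``cross_check`` (the
    default) only mutual nearest pairs are kept.  Optional filters:
    ``max_distance`` caps the accepted distance; ``ratio`` keeps a match
    only when nearest/second-nearest < ratio (skipped when b has a single
    descriptor).  Results are sorted by (distance, index_a).
    """
    if not desc_a or not desc_b:
        raise ValueError("descriptor lists must be non-empty")
    _check_layouts(desc_a[0].layout, desc_b[0].layout)
    A = _packed_matrix(desc_a)
    B = _packed_matrix(desc_b)
    # (na, nb) distance matrix; popcount over byte axis
    D = np.bitwise_count(A[:, None, :] ^ B[None, :, :]).sum(axis=2, dtype=np.int64)
    nn_b = D.argmin(axis=1)                      # first minimum = smallest index
    nn_dist = D[np.arange(D.shape[0]), nn_b]
    keep = np.ones(D.shape[0], dtype=bool)
    if cross_check:
        nn_a = D.argmin(axis=0)
        keep &= nn_a[nn_b] == np.arange(D.shape[0])
    if max_distance is not None:
        keep &= nn_dist <= max_distance
    if ratio is not None and D.shape[1] >= 2:
        part = np.partition(D, 1, axis=1)
        second = part[:, 1].astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(second > 0, nn_dist / second, np.where(nn_dist == 0, 0.0, np.inf))
        keep &= rr < ratio
    matches = [Match(index_a=int(i), index_b=int(nn_b[i]), distance=int(nn_dist[i]))
               for i in np.nonzero(keep)[0]]
    matches.sort(key=lambda m: (m.distance, m.index_a))
    return matches
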