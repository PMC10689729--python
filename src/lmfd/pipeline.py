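"""Small helpers chaining detect -> describe -> match for the protocols."""

from __future__ import annotations

import numpy as np

from .descriptors import DescriptorParams, PatchDescriptor, describe, pack_bits
from .detection import DetectorConfig, detect
from .geometry import project
from .matching import Match, match_nn

__all__ = ["detect_and_describe", "match_points", "correct_match_count",
           "truncate_to_prefix"]


def detect_and_describe(image: np.ndarray, params: DescriptorParams | None = None,
                        detector: DetectorConfig | None = None
                        ) -> list[PatchDescriptor]:
    params = params or DescriptorParams()
    detector = detector or DetectorConfig()
    return describe(image, detect(image, detector, params), params)


def match_points(desc_a: list[PatchDescriptor], desc_b: list[PatchDescriptor],
                 **kwargs) -> tuple[list[Match], np.ndarray, np.ndarray]:
    """Match and return the matched (x, y) coordinate arrays alongside."""
    matches = match_nn(desc_a, desc_b, **kwargs)
    pts_a = np.array([[desc_a[m.index_a].keypoint.col,
                       desc_a[m.index_a].keypoint.row] for m in matches],
                     dtype=np.float64).reshape(-1, 2)
    pts_b = np.array([[desc_b[m.index_b].keypoint.col,
                       desc_b[m.index_b].keypoint.row] for m in matches],
                     dtype=np.float64).reshape(-1, 2)
    return matches, pts_a, pts_b


def correct_match_count(pts_a: np.ndarray, pts_b: np.ndarray, h_true: np.ndarray,
                        tol_px: float = 3.0) -> int:
    """Matches whose reprojection error under the ground truth is <= tol."""
    if len(pts_a) == 0:
        return 0
    err = np.linalg.norm(project(h_true, pts_a) - pts_b, axis=1)
    return int((err <= tol_px).sum())


def truncate_to_prefix(descs: list[PatchDescriptor], prefix_bits: int
                       ) -> list[PatchDescriptor]:
    """Restrict descriptors to their first ``prefix_bits`` bits.

    Plain Hamming matching is blind to block order (a fixed bit
    permutation applied to both sides preserves every distance), so order
    comparisons only become discriminative when matching is limited to a
    bit prefix — the high-order blocks of the chosen combination.
    """
    from dataclasses import replace

    out = []
    for d in descs:
        bits = d.bits[:prefix_bits]
        layout = replace(d.layout)  # same layout; prefix recorded via packed size
        out.append(PatchDescriptor(packed=pack_bits(bits), layout=layout,
                                   keypoint=d.keypoint))
    return out
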