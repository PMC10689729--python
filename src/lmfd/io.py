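"""Readers/writers for images, keypoints, descriptors, matches,
homographies, and the run configuration.

All on-disk coordinates are 0-based (row, col); descriptor bit vectors
are stored as hex with little-endian bit packing within bytes.  Every
format round-trips byte-identically (write -> read -> write).
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .descriptors import (BlockLayout, DescriptorParams, Keypoint,
                          PatchDescriptor, pack_bits, unpack_bits)
from .matching import Match

__all__ = [
    "read_image", "write_image",
    "read_keypoints", "write_keypoints",
    "read_descriptors", "write_descriptors",
    "read_matches", "write_matches",
    "read_homography", "write_homography",
    "RunConfig",
]

_FORMAT_VERSION = 1


def read_image(path) -> np.ndarray:
    """Load PNG/TIFF/PGM as an 8-bit greyscale raster.

    Colour inputs are converted with ITU-R BT.601 luma
    (0.299 R + 0.587 G + 0.114 B), rounded half-up.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            if im.mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            elif im.mode in ("P", "RGBA", "LA"):
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                arr = _bt601(rgb)
            elif im.mode == "RGB":
                arr = _bt601(np.asarray(im, dtype=np.float64))
            elif im.mode == "1":
                arr = (np.asarray(im, dtype=np.uint8) * 255).astype(np.uint8)
            else:
                raise ValueError(
                    f"unsupported image mode {im.mode!r} in {path}; "
                    "expected an 8-bit greyscale or colour PNG/TIFF/PGM")
    except (OSError, SyntaxError) as e:
        raise ValueError(f"cannot read {path} as PNG/TIFF/PGM: {e}") from e
    return arr


def _bt601(rgb: np.ndarray) -> np.ndarray:
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)  # half-up


def write_image(path, raster: np.ndarray) -> None:
    Image.fromarray(np.asarray(raster, dtype=np.uint8), mode="L").save(Path(path))


# -- keypoints ---------------------------------------------------------------

def write_keypoints(path, keypoints: list[Keypoint]) -> None:
    with open(path, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["row", "col", "score"])
        for kp in keypoints:
            wr.writerow([kp.row, kp.col, kp.score])


def read_keypoints(path) -> list[Keypoint]:
    with open(path, newline="") as f:
        rd = csv.reader(f)
        header = next(rd)
        if header != ["row", "col", "score"]:
            raise ValueError(f"bad keypoint header in {path}: {header}")
        return [Keypoint(row=int(r), col=int(c), score=int(s)) for r, c, s in rd]


# -- descriptors -------------------------------------------------------------

def write_descriptors(path, descs: list[PatchDescriptor],
                      params: DescriptorParams) -> None:
    """Header (version, geometry, order, bit_width, count) + one
    ``row col hexbits`` line per keypoint."""
    with open(path, "w") as f:
        f.write(f"LMFD {_FORMAT_VERSION} r={params.r} kz={params.kz} "
                f"ps={params.ps} order={params.order} "
                f"bit_width={params.bit_width} count={len(descs)}\n")
        for d in descs:
            f.write(f"{d.keypoint.row} {d.keypoint.col} "
                    f"{bytes(d.packed).hex()}\n")


def read_descriptors(path) -> tuple[list[PatchDescriptor], DescriptorParams]:
    with open(path) as f:
        header = f.readline().split()
        if len(header) != 8 or header[0] != "LMFD":
            raise ValueError(f"bad descriptor header in {path}")
        kv = dict(tok.split("=", 1) for tok in header[2:])
        params = DescriptorParams(r=int(kv["r"]), kz=int(kv["kz"]),
                                  ps=int(kv["ps"]), order=kv["order"])
        if params.bit_width != int(kv["bit_width"]):
            raise ValueError(
                f"bit_width {kv['bit_width']} inconsistent with geometry "
                f"(expected {params.bit_width}) in {path}")
        layout = params.layout
        descs = []
        for line in f:
            r, c, hx = line.split()
            packed = np.frombuffer(bytes.fromhex(hx), dtype=np.uint8)
            descs.append(PatchDescriptor(packed=packed, layout=layout,
                                         keypoint=Keypoint(int(r), int(c))))
        if len(descs) != int(kv["count"]):
            raise ValueError(f"descriptor count mismatch in {path}")
    return descs, params


# -- matches -----------------------------------------------------------------

def write_matches(path, matches: list[Match]) -> None:
    with open(path, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["index_a", "index_b", "distance"])
        for m in matches:
            wr.writerow([m.index_a, m.index_b, m.distance])


def read_matches(path) -> list[Match]:
    with open(path, newline="") as f:
        rd = csv.reader(f)
        header = next(rd)
        if header != ["index_a", "index_b", "distance"]:
            raise ValueError(f"bad match header in {path}: {header}")
        return [Match(index_a=int(a), index_b=int(b), distance=int(d))
                for a, b, d in rd]


# -- homographies ------------------------------------------------------------

def write_homography(path, h: np.ndarray) -> None:
    np.savetxt(path, np.asarray(h, dtype=np.float64), fmt="%.17g")


def read_homography(path) -> np.ndarray:
    h = np.loadtxt(path)
    if h.shape != (3, 3):
        raise ValueError(f"homography file {path} must hold a 3x3 matrix")
    return h


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable of the end-to-end pipeline, YAML-serializable."""

    r: int = 3
    kz: int = 1
    ps: int | None = None
    order: str = "MSC"
    threshold: int = 20
    arc_length: int = 9
    nms_radius: int = 3
    cross_check: bool = True
    max_distance: int | None = None
    ratio: float | None = None
    ransac_iterations: int = 2000
    inlier_px: float = 3.0
    tol_px: float = 3.0
    prefix_bits: int | None = None
    seed: int = 0
    verbosity: int = 1

    @property
    def descriptor_params(self) -> DescriptorParams:
        return DescriptorParams(r=self.r, kz=self.kz, ps=self.ps, order=self.order)

    @property
    def detector_config(self):
        from .detection import DetectorConfig
        return DetectorConfig(threshold=self.threshold, arc_length=self.arc_length,
                              nms_radius=self.nms_radius)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
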