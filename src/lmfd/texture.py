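"""Texture classification with dense descriptor-code histograms.

Images are contrast-normalized with CLAHE, then described densely: square
patches on a regular grid, each contributing its per-window 8-bit
symbolic codes to a 256-bin histogram (the LBP-style featurization) plus
the frequencies of the mean and centroid bits.  A radial-basis-function
SVM with stratified k-fold cross-validation scores the features.

For window half-widths kz > 1 the symbolic code is computed on the 8 ring
pixels at the window's axis and diagonal extremes, keeping the code 8-bit
and the histogram 256-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.exposure import equalize_adapthist
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import DescriptorParams
from .fixtures import TextureDataset

__all__ = ["TextureFeature", "CVReport", "clahe", "extract_features",
           "cross_validate"]


@dataclass(frozen=True)
class TextureFeature:
    """Per-image histogram feature, L1-normalized per block."""

    symbolic_hist: np.ndarray    # 256 bins over per-window 8-bit codes
    mean_freq: np.ndarray        # [P(bit=0), P(bit=1)]
    centroid_freq: np.ndarray    # [P(bit=0), P(bit=1)]

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.symbolic_hist, self.mean_freq,
                               self.centroid_freq])


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    confusion: np.ndarray


def clahe(image: np.ndarray, clip_limit: float = 2.0, tile: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, 8-bit in and out.

    ``clip_limit`` is in multiples of the mean histogram bin (the common
    convention); ``tile`` is the contextual-region side in pixels.
    Constant images pass through unchanged.
    """
    image = np.asarray(image, dtype=np.uint8)
    if image.min() == image.max():
        return image.copy()
    out = equalize_adapthist(image, kernel_size=tile,
                             clip_limit=clip_limit / 256.0, nbins=256)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def _ring8_offsets(kz: int) -> list[tuple[int, int]]:
    """Axis/diagonal extremes of the radius-kz ring, clockwise from the
    top-left corner (the full 8-neighbour ring when kz = 1)."""
    return [(-kz, -kz), (-kz, 0), (-kz, kz), (0, kz),
            (kz, kz), (kz, 0), (kz, -kz), (0, -kz)]


def extract_features(image: np.ndarray, params: DescriptorParams | None = None,
                     grid_stride: int | None = None) -> TextureFeature:
    """Dense descriptor-code histograms for one image.

    Patches of side ``ps`` are sampled on a regular grid (stride defaults
    to ``ps``, i.e. non-overlapping); no keypoint detection is involved.
    Every patch contributes its per-window symbolic codes, mean bits and
    centroid bits to the pooled histograms.
    """
    params = params or DescriptorParams()
    image = np.asarray(image, dtype=np.uint8)
    ps, kz, w = params.ps, params.kz, params.w
    h, wd = image.shape[:2]
    if h < 2 * ps or wd < 2 * ps:
        raise ValueError(f"image {h}x{wd} too small; need >= 2*ps = {2 * ps} per side")
    stride = grid_stride or ps
    im = image.astype(np.int64)
    image_mean = float(image.mean())

    patches = sliding_window_view(im, (ps, ps))[::stride, ::stride]
    patches = patches.reshape(-1, ps, ps)                    # (np, ps, ps)
    win = sliding_window_view(patches, (w, w), axis=(1, 2))  # (np, nw, nw, w, w)
    n_p = patches.shape[0]
    nw = ps - w + 1

    # symbolic 8-bit codes: centre vs 8 ring extremes, LSB first
    center = win[..., kz, kz]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(_ring8_offsets(kz)):
        codes += (center > win[..., kz + dr, kz + dc]).astype(np.int64) << p
    symbolic_hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    symbolic_hist /= symbolic_hist.sum()

    # mean bits: window mean vs the patch-centre window's mean
    means = win.mean(axis=(3, 4))
    ci = (ps - 1) // 2 - kz
    m_c = means[:, ci, ci]
    mean_bits = means > m_c[:, None, None]
    f_m = float(mean_bits.mean())

    # centroid bits: nearest-pixel centroid value vs (patch mean + image mean)/2
    total = win.sum(axis=(3, 4)).astype(np.float64)
    idx = np.arange(w, dtype=np.float64)
    safe = np.where(total > 0, total, 1.0)
    rbar = np.where(total > 0,
                    (win * idx[None, None, None, :, None]).sum(axis=(3, 4)) / safe,
                    float(kz))
    cbar = np.where(total > 0,
                    (win * idx[None, None, None, None, :]).sum(axis=(3, 4)) / safe,
                    float(kz))
    from .descriptors import _nearest_index
    ri = _nearest_index(rbar, kz, w)
    cc = _nearest_index(cbar, kz, w)
    ii = np.arange(n_p)[:, None, None]
    jj = np.arange(nw)[None, :, None]
    kk = np.arange(nw)[None, None, :]
    g = win[ii, jj, kk, ri, cc]
    c_ref = (patches.mean(axis=(1, 2)) + image_mean) / 2.0
    cent_bits = g > c_ref[:, None, None]
    f_c = float(cent_bits.mean())

    return TextureFeature(symbolic_hist=symbolic_hist,
                          mean_freq=np.array([1.0 - f_m, f_m]),
                          centroid_freq=np.array([1.0 - f_c, f_c]))


def cross_validate(dataset: TextureDataset, folds: int = 5,
                   params: DescriptorParams | None = None,
                   grid_stride: int | None = None, seed: int = 0,
                   C: float = 10.0, gamma="scale",
                   clip_limit: float = 2.0, tile: int = 8) -> CVReport:
    """Stratified k-fold RBF-SVM accuracy on dense LMFD features.

    Feature scaling is fit on each training fold only; the report carries
    per-fold accuracies, their mean and standard deviation, and the
    pooled confusion matrix.
    """
    labels = np.asarray(dataset.labels)
    counts = np.bincount(labels, minlength=dataset.n_classes)
    if (counts < folds).any():
        bad = np.nonzero(counts < folds)[0].tolist()
        raise ValueError(f"classes {bad} have fewer than {folds} samples")
    X = np.stack([extract_features(clahe(img, clip_limit, tile), params,
                                   grid_stride).vector
                  for img in dataset.images])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    y_true_all, y_pred_all = [], []
    for train, test in skf.split(X, labels):
        clf = make_pipeline(StandardScaler(),
                            SVC(kernel="rbf", C=C, gamma=gamma))
        clf.fit(X[train], labels[train])
        pred = clf.predict(X[test])
        accs.append(float((pred == labels[test]).mean()))
        y_true_all.append(labels[test])
        y_pred_all.append(pred)
    accs = np.array(accs)
    conf = confusion_matrix(np.concatenate(y_true_all), np.concatenate(y_pred_all),
                            labels=np.arange(dataset.n_classes))
    return CVReport(fold_accuracies=accs, mean_accuracy=float(accs.mean()),
                    std_accuracy=float(accs.std()), confusion=conf)
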