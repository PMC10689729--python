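"""Classify synthetic textures with dense LMFD histograms and an RBF-SVM.

Builds a 5-class, 100-image synthetic texture dataset, extracts CLAHE +
dense code-histogram features, and reports stratified 5-fold
cross-validated accuracy with the confusion matrix.
"""

import numpy as np

from lmfd import cross_validate, make_texture_dataset

ds = make_texture_dataset(n_classes=5, per_class=20, size=128, seed=0)
print(f"dataset: {len(ds.images)} images, "
      f"class counts {np.bincount(ds.labels).tolist()}")

report = cross_validate(ds, folds=5, seed=0)
print(f"fold accuracies: {[round(a, 3) for a in report.fold_accuracies.tolist()]}")
print(f"mean accuracy: {report.mean_accuracy:.3f} ± {report.std_accuracy:.3f}")
print("confusion matrix (rows = true class):")
print(report.confusion)
# The synthetic classes differ by generator family (checker, grating,
# smoothed noise, ramp), which the 256-bin symbolic-code histogram
# separates almost perfectly.
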