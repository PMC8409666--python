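"""Lesion-wise evaluation and count categorization.

Sensitivity = TP/(TP+FN) over manual lesions, FDR = FP/(FP+TP) over
predicted components, stratified by lesion size; per-scan lesion counts
are binned 0 / 1 / >=2 and compared in a confusion matrix.
"""

import warnings

warnings.filterwarnings("ignore", message="volume shape")

import numpy as np

from gadseg import (PhantomSpec, categorize_scan, count_confusion,
                    evaluate_scans, generate_cohort)
from gadseg.candidates import connected_components_6, filter_min_size
from gadseg.metrics import format_report

one = PhantomSpec(shape=(16, 48, 48), n_lesions=1,
                  size_groups=(("11-20", 1),), seed=0)
two = PhantomSpec(shape=(16, 48, 48), n_lesions=2,
                  size_groups=(("11-20", 1), ("21-50", 1)), seed=0)
a, cats_a = generate_cohort(6, 0.5, one, seed=4)
b, cats_b = generate_cohort(6, 0.7, two, seed=5)
phantoms, true_cats = a + b, cats_a + cats_b

# use the ground truth as the 'prediction', dropping one lesion-bearing
# scan's mask to show an imperfect confusion matrix
pred_masks = [p.mask.copy() for p in phantoms]
drop = next(i for i, c in enumerate(true_cats) if c != "0")
pred_masks[drop][:] = 0

report = evaluate_scans(pred_masks, [p.mask for p in phantoms])
print(format_report(report))

pred_cats = []
for m in pred_masks:
    _, comps = connected_components_6(m)
    pred_cats.append(categorize_scan(len(filter_min_size(comps))))
conf = count_confusion(pred_cats, true_cats)
print("\ncount confusion matrix (rows: predicted, cols: true):")
print(conf.matrix.to_string())
print(f"column-normalized diagonal (%): "
      f"{np.round(np.diag(conf.normalized.to_numpy()), 1)}")
print(f"overall accuracy: {conf.accuracy:.1f}%")
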