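"""Run all three two-sample tests on one simulated subgroup shift.

The target distribution contains only images with co-morbidities (a
subgroup of the source support, so no single image is an outlier).  Each
detector gets the same four folds: training folds of 200 images per side
for the trainable detectors, and held-out test folds of 100 per side.
A p-value at or below alpha = 0.05 means the shift was detected.
"""

import shiftwatch as sw

spec = sw.GeneratorSpec(image_size=32)
pool = sw.generate_dataset(spec, n=2000, fold="train", seed=1)

# MUKS monitors the deployed grading model, so train one on source data.
task_train = sw.generate_dataset(spec, n=1500, fold="train", seed=3)
task_val = sw.generate_dataset(spec, n=300, fold="val", seed=4)
task_model = sw.train_task_classifier(task_train, task_val)

shift = sw.ShiftSpec(kind="subgroup_filter", attribute="comorbidity",
                     allowed_values=(True,))
source, target = sw.samplers_for_shift(pool, shift)
splits = sw.make_splits(source, target, n_train=200, m=100, seed=7)

for method in ("c2st", "mmdd", "muks"):
    fn = sw.make_test_fn(method, alpha=0.05, task_model=task_model)
    res = fn(splits, 7)
    print(f"{method:5s}  statistic={res.statistic:+.4f}  "
          f"p={res.p_value:.4f}  reject={res.reject}")
print("reject=True: the detector flags that deployment data no longer "
      "match the validation distribution")
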