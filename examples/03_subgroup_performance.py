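"""Subgroup performance report for the grading model.

Trains the desk-scale 5-grade classifier and reports, per image-quality
subgroup of a held-out fold, the 5-class accuracy (acc5) and the binary
referable-DR metrics (acc2 / sens2 / spec2, referable = grade >= 2).
Performance differences across subgroups are what make undetected
subgroup shifts harmful.
"""

import shiftwatch as sw

spec = sw.GeneratorSpec(image_size=32)
train = sw.generate_dataset(spec, n=1500, fold="train", seed=3)
val = sw.generate_dataset(spec, n=300, fold="val", seed=4)
test = sw.generate_dataset(spec, n=2000, fold="test", seed=5)

model = sw.train_task_classifier(train, val)
table = sw.subgroup_performance(model, test, "quality")
cols = ["subgroup", "n", "acc5", "acc2", "sens2", "spec2"]
print(table[cols].round(3).to_string(index=False))
print("\nsens2 = recall on referable (grade >= 2) images; "
      "NaN marks subgroups with no referable cases")
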