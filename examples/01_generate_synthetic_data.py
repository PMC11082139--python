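"""Generate a synthetic screening population and inspect its structure.

Builds a small fundus-like dataset with the default attribute prevalences
(60/40 female/male, 79% healthy grade 0, 10% co-morbidities, quality split
adequate/good/excellent), plus a separate pool of insufficient-quality
out-of-distribution images, and prints the attribute marginals actually
realised in the sample.
"""

import shiftwatch as sw

spec = sw.GeneratorSpec(image_size=32)
dataset = sw.generate_dataset(spec, n=1000, fold="train", seed=1)
ood = sw.generate_dataset(spec, n=200, fold="ood", seed=2)

print(f"in-distribution pool: {len(dataset)} images "
      f"of shape {dataset.images.shape[1:]}")
for attr in ("sex", "quality", "comorbidity", "dr_grade"):
    counts = dataset.attrs[attr].value_counts(normalize=True).round(3)
    print(f"  {attr}: {counts.to_dict()}")
print(f"OOD pool: {len(ood)} images, "
      f"all quality={ood.attrs['quality'].unique().tolist()}")

# Round-trip through the on-disk PNG + CSV format is bit-exact.
out = sw.save_dataset(dataset.subset(range(10)), "scratch/example_dataset")
back = sw.load_dataset(out)
print(f"wrote and re-read {len(back)} images losslessly from {out}")
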