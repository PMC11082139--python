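"""Desk-scale diabetic-retinopathy grading model and subgroup report.

The monitored algorithm is a 5-grade classifier (0 healthy .. 4
proliferative).  Besides serving as the MUKS feature extractor, it produces
the subgroup performance table that motivates shift detection: 5-class
accuracy plus, after binarising at the referable threshold (grade >= 2),
binary accuracy, sensitivity and specificity per subgroup.

Training follows the stated recipe: cross-entropy, SGD with Nesterov
momentum, initial learning rate 0.001 with multiplicative decay 0.9 per
epoch, light augmentation, up to 25 epochs with the final model chosen by
validation loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import MLP, TrainConfig, train_classifier, softmax
from .synthdata import LabeledDataset

__all__ = [
    "N_GRADES",
    "TaskClassifier",
    "train_task_classifier",
    "referable_binarize",
    "subgroup_performance",
]

N_GRADES = 5
REFERABLE_THRESHOLD = 2


@dataclass
class TaskClassifier:
    """Trained 5-grade classifier with evaluation-mode determinism."""

    net: MLP
    image_shape: tuple[int, ...]
    metadata: dict
    trained: bool = True

    @property
    def n_classes(self) -> int:
        return N_GRADES

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise ValueError("task classifier is not trained")
        logits = self.net.forward(np.asarray(images, dtype=np.float32))
        return softmax(logits).astype(np.float64)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    # -- checkpointing (npz weights + JSON sidecar) --------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", *self.net.get_params())
        sidecar = {
            "sizes": list(self.net.sizes),
            "image_shape": list(self.image_shape),
            "n_classes": N_GRADES,
            **self.metadata,
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TaskClassifier":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text())
        net = MLP(tuple(sidecar["sizes"]), seed=0)
        with np.load(path / "weights.npz") as data:
            net.set_params([data[k] for k in data.files])
        meta = {
            k: v
            for k, v in sidecar.items()
            if k not in ("sizes", "image_shape", "n_classes")
        }
        return cls(
            net=net,
            image_shape=tuple(sidecar["image_shape"]),
            metadata=meta,
        )


def _task_augment(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flips, quarter rotations, small shifts and mild colour jitter."""
    out = images.copy()
    flip_h = rng.random(len(out)) < 0.5
    flip_v = rng.random(len(out)) < 0.5
    out[flip_h] = out[flip_h, :, ::-1]
    out[flip_v] = out[flip_v, ::-1]
    k = rng.integers(0, 4)
    if k:
        out = np.rot90(out, k=k, axes=(1, 2)).copy()
    shift = rng.integers(-2, 3, size=2)
    out = np.roll(out, tuple(shift), axis=(1, 2))
    gains = 1.0 + rng.uniform(-0.05, 0.05, size=(len(out), 1, 1, 3))
    return np.clip(out * gains.astype(np.float32), 0.0, 1.0)


def train_task_classifier(
    train_set: LabeledDataset,
    val_set: LabeledDataset | None = None,
    config: TrainConfig | None = None,
    hidden: tuple[int, ...] = (64,),
) -> TaskClassifier:
    """Fit the grading model on a labelled training fold.

    Requires every one of the 5 grades to appear in the training labels.
    When ``val_set`` is given it drives model selection; otherwise a
    held-out slice of the training fold does.
    """
    config = config or TrainConfig(epochs=25)
    labels = train_set.attrs["dr_grade"].to_numpy(dtype=float)
    if np.isnan(labels).any():
        raise ValueError("training set contains ungraded (insufficient) images")
    labels = labels.astype(int)
    present = set(labels.tolist())
    missing = sorted(set(range(N_GRADES)) - present)
    if missing:
        raise ValueError(f"training data is missing DR grades {missing}")

    d = int(np.prod(train_set.images.shape[1:]))
    net = MLP((d, *hidden, N_GRADES), seed=config.seed)
    val_data = None
    if val_set is not None:
        val_labels = val_set.attrs["dr_grade"].to_numpy(dtype=float)
        if np.isnan(val_labels).any():
            raise ValueError("validation set contains ungraded images")
        val_data = (val_set.images, val_labels.astype(int))
    fit = train_classifier(
        net, train_set.images, labels, config, augment_fn=_task_augment,
        val_data=val_data,
    )
    metadata = {
        "epochs": config.epochs,
        "seed": config.seed,
        "selection": "validation loss",
        "best_epoch": fit.best_epoch,
    }
    clf = TaskClassifier(
        net=net, image_shape=train_set.images.shape[1:], metadata=metadata
    )
    clf.metadata["val_loss_trajectory"] = [float(v) for v in fit.val_loss]
    return clf


def referable_binarize(grade: int) -> bool:
    """True iff the grade is referable (moderate or worse, grade >= 2)."""
    grade = int(grade)
    if grade not in range(N_GRADES):
        raise ValueError(f"DR grade must be in 0..4, got {grade}")
    return grade >= REFERABLE_THRESHOLD


def _metrics_from_counts(counts: dict) -> dict:
    tp, fp, tn, fn = counts["tp"], counts["fp"], counts["tn"], counts["fn"]
    n_pos, n_neg = tp + fn, tn + fp
    out = {
        "acc2": (tp + tn) / (tp + tn + fp + fn),
        "sens2": tp / n_pos if n_pos > 0 else np.nan,
        "spec2": tn / n_neg if n_neg > 0 else np.nan,
    }
    return out


def subgroup_performance(
    f: TaskClassifier, dataset: LabeledDataset, attribute: str
) -> pd.DataFrame:
    """Per-subgroup performance table for one grouping attribute.

    Columns: subgroup, n, acc5 (5-grade accuracy), acc2/sens2/spec2 on the
    referable binarisation, plus the raw confusion counts tp/fp/tn/fn.  An
    "All" row pools every sample; sensitivity is NaN for subgroups with no
    referable cases (specificity likewise).  Category levels with zero
    members are omitted with a warning.
    """
    if attribute not in dataset.attrs.columns:
        raise ValueError(f"dataset has no attribute {attribute!r}")
    labels = dataset.attrs["dr_grade"].to_numpy(dtype=float)
    if np.isnan(labels).any():
        raise ValueError("dataset contains ungraded images; grade labels required")
    labels = labels.astype(int)
    preds = f.predict(dataset.images)
    ref_true = labels >= REFERABLE_THRESHOLD
    ref_pred = preds >= REFERABLE_THRESHOLD

    def row_for(mask: np.ndarray, name) -> dict:
        yt, yp = labels[mask], preds[mask]
        rt, rp = ref_true[mask], ref_pred[mask]
        counts = {
            "tp": int((rt & rp).sum()),
            "fp": int((~rt & rp).sum()),
            "tn": int((~rt & ~rp).sum()),
            "fn": int((rt & ~rp).sum()),
        }
        return {
            "subgroup": name,
            "n": int(mask.sum()),
            "acc5": float((yt == yp).mean()),
            **_metrics_from_counts(counts),
            **counts,
        }

    rows = [row_for(np.ones(len(labels), dtype=bool), "All")]
    values = dataset.attrs[attribute]
    for level in pd.unique(values):
        mask = (values == level).to_numpy()
        if not mask.any():
            warnings.warn(f"subgroup {level!r} is empty; omitting row", stacklevel=2)
            continue
        rows.append(row_for(mask, level))
    return pd.DataFrame(rows)
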