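"""Source/target sampling distributions and train/test fold assembly.

A shift is declared with a :class:`ShiftSpec` and realised as a pair of
:class:`DistributionSampler` objects over a backing dataset: the source
distribution P (uniform over the in-distribution pool) and a target
distribution Q obtained by filtering to a subgroup, re-weighting a subgroup
by a factor ``w``, or swapping in an out-of-distribution pool.  All draws
are i.i.d. with replacement; train/test disjointness is enforced by
partitioning image identifiers into a train pool and a test pool before any
sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthdata import LabeledDataset

__all__ = [
    "ShiftSpec",
    "DistributionSampler",
    "SplitPair",
    "null_sampler",
    "subgroup_filter_sampler",
    "oversample_sampler",
    "ood_sampler",
    "samplers_for_shift",
    "make_splits",
]

_SHIFT_KINDS = ("null", "subgroup_filter", "oversample", "ood")


@dataclass(frozen=True)
class ShiftSpec:
    """Declarative description of how the target distribution differs.

    kind:
        ``null`` (target equals source), ``subgroup_filter`` (target draws
        only from ``allowed_values`` of ``attribute``), ``oversample``
        (samples with ``attribute == target_value`` carry weight ``w``) or
        ``ood`` (target draws from a separate out-of-distribution pool).
    """

    kind: str
    attribute: str | None = None
    allowed_values: tuple = ()
    target_value: object = None
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _SHIFT_KINDS:
            raise ValueError(f"unknown shift kind {self.kind!r}")
        if self.kind == "subgroup_filter":
            if self.attribute is None or not self.allowed_values:
                raise ValueError(
                    "subgroup_filter requires attribute and allowed_values"
                )
        if self.kind == "oversample":
            if self.attribute is None or self.target_value is None:
                raise ValueError("oversample requires attribute and target_value")
            if self.w < 1:
                raise ValueError(f"oversample weight w must be >= 1, got {self.w}")
        if self.kind in ("null", "ood") and self.attribute is not None:
            raise ValueError(f"shift kind {self.kind!r} carries no attribute")

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftSpec":
        """Parse the YAML form, e.g.
        ``{kind: subgroup_filter, attribute: quality, allowed: [adequate]}``."""
        kind = d["kind"]
        return cls(
            kind=kind,
            attribute=d.get("attribute"),
            allowed_values=tuple(d.get("allowed", ())),
            target_value=d.get("value", d.get("target_value")),
            w=float(d.get("w", 1.0)),
        )


@dataclass
class DistributionSampler:
    """I.i.d.-with-replacement sampler over a backing dataset.

    ``weights`` is the (normalised) inclusion/weighting rule; entries of
    zero exclude a sample entirely.
    """

    dataset: LabeledDataset
    weights: np.ndarray
    role: str = "source"

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.dataset):
            raise ValueError("weights must match dataset length")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("sampler has no eligible samples")
        self.weights = np.asarray(self.weights, dtype=float) / total

    @property
    def eligible(self) -> np.ndarray:
        return np.flatnonzero(self.weights > 0)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` dataset indices with replacement."""
        return rng.choice(len(self.weights), size=n, replace=True, p=self.weights)


def null_sampler(dataset: LabeledDataset, role: str = "source") -> DistributionSampler:
    """Uniform sampler over the full dataset (the unshifted distribution)."""
    return DistributionSampler(dataset, np.ones(len(dataset)), role=role)


def subgroup_filter_sampler(
    dataset: LabeledDataset,
    attribute: str,
    allowed_values,
    role: str = "target",
) -> DistributionSampler:
    """Uniform draws restricted to samples whose attribute is allowed."""
    allowed = set(allowed_values)
    if not allowed:
        raise ValueError("allowed_values must be nonempty")
    values = _attribute_column(dataset, attribute)
    mask = np.isin(values, list(allowed))
    if not mask.any():
        raise ValueError(
            f"no samples with {attribute!r} in {sorted(map(str, allowed))}"
        )
    return DistributionSampler(dataset, mask.astype(float), role=role)


def oversample_sampler(
    dataset: LabeledDataset,
    attribute: str,
    target_value,
    w: float,
    role: str = "target",
) -> DistributionSampler:
    """Weight samples with ``attribute == target_value`` by a factor ``w``.

    ``w = 1`` leaves the distribution unchanged (P = Q); larger ``w``
    over-represents the subgroup.  If the subgroup is empty the sampler
    degenerates to uniform.
    """
    if w < 1:
        raise ValueError(f"oversampling factor w must be >= 1, got {w}")
    values = _attribute_column(dataset, attribute)
    weights = np.where(values == np.asarray(target_value), float(w), 1.0)
    return DistributionSampler(dataset, weights, role=role)


def ood_sampler(
    ood_dataset: LabeledDataset, role: str = "target"
) -> DistributionSampler:
    """Uniform sampler over an out-of-distribution (insufficient-quality) pool."""
    if len(ood_dataset) == 0:
        raise ValueError("OOD dataset is empty")
    quality = ood_dataset.attrs["quality"].to_numpy()
    bad = quality != "insufficient"
    if bad.any():
        raise ValueError(
            "OOD pool contains in-distribution samples "
            f"(qualities {sorted(set(quality[bad]))})"
        )
    return DistributionSampler(ood_dataset, np.ones(len(ood_dataset)), role=role)


def samplers_for_shift(
    dataset: LabeledDataset,
    shift: ShiftSpec,
    ood_dataset: LabeledDataset | None = None,
) -> tuple[DistributionSampler, DistributionSampler]:
    """Build the (source, target) sampler pair realising a shift spec."""
    source = null_sampler(dataset, role="source")
    if shift.kind == "null":
        target = null_sampler(dataset, role="target")
    elif shift.kind == "subgroup_filter":
        target = subgroup_filter_sampler(
            dataset, shift.attribute, shift.allowed_values, role="target"
        )
    elif shift.kind == "oversample":
        target = oversample_sampler(
            dataset, shift.attribute, shift.target_value, shift.w, role="target"
        )
    else:  # ood
        if ood_dataset is None:
            raise ValueError("ood shift requires an ood_dataset")
        target = ood_sampler(ood_dataset, role="target")
    return source, target


def _attribute_column(dataset: LabeledDataset, attribute: str) -> np.ndarray:
    if attribute not in dataset.attrs.columns:
        raise ValueError(f"dataset has no attribute {attribute!r}")
    col = dataset.attrs[attribute]
    if attribute == "dr_grade":
        return col.to_numpy(dtype="float")  # NaN for absent grades
    return col.to_numpy()


@dataclass
class SplitPair:
    """The four folds consumed by every two-sample test.

    Training folds of size ``n_train`` per side and test folds of size ``m``
    per side, with no image identifier shared between the training and test
    folds.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    ids: dict = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return len(self.x_train)

    @property
    def m(self) -> int:
        return len(self.x_test)


def make_splits(
    source: DistributionSampler,
    target: DistributionSampler,
    n_train: int,
    m: int,
    seed: int,
    train_fraction: float = 0.5,
) -> SplitPair:
    """Draw the four folds S_P^tr, S_Q^tr, S_P^te, S_Q^te.

    Image identifiers of each backing dataset are partitioned once into a
    train pool and a test pool (shared between source and target when they
    share a dataset), and each fold is then drawn with replacement from its
    sampler's rule restricted to the corresponding pool.  ``n_train = 0`` is
    allowed for detectors that train nothing.
    """
    if n_train < 0:
        raise ValueError("n_train must be >= 0")
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)

    partitions: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def partition_for(sampler: DistributionSampler) -> tuple[np.ndarray, np.ndarray]:
        key = id(sampler.dataset)
        if key not in partitions:
            n = len(sampler.dataset)
            if n < 2:
                raise ValueError(
                    "backing dataset too small for disjoint train/test pools: "
                    f"need at least 2 images, have {n}"
                )
            perm = rng.permutation(n)
            cut = int(round(train_fraction * n))
            cut = min(max(cut, 1), n - 1)
            partitions[key] = (perm[:cut], perm[cut:])
        return partitions[key]

    def draw_fold(sampler: DistributionSampler, pool: np.ndarray, size: int) -> np.ndarray:
        w = sampler.weights[pool]
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"no eligible {sampler.role} samples in the "
                "requested train/test pool; enlarge the backing dataset"
            )
        return pool[rng.choice(len(pool), size=size, replace=True, p=w / total)]

    folds_idx = {}
    for name, sampler, pool_ix, size in (
        ("x_train", source, 0, n_train),
        ("y_train", target, 0, n_train),
        ("x_test", source, 1, m),
        ("y_test", target, 1, m),
    ):
        pools = partition_for(sampler)
        folds_idx[name] = (
            draw_fold(sampler, pools[pool_ix], size)
            if size > 0
            else np.empty(0, dtype=int)
        )

    def gather(sampler: DistributionSampler, idx: np.ndarray):
        images = sampler.dataset.images[idx]
        ids = sampler.dataset.image_ids[idx]
        return images, ids

    x_tr, id_xtr = gather(source, folds_idx["x_train"])
    y_tr, id_ytr = gather(target, folds_idx["y_train"])
    x_te, id_xte = gather(source, folds_idx["x_test"])
    y_te, id_yte = gather(target, folds_idx["y_test"])
    return SplitPair(
        x_train=x_tr,
        y_train=y_tr,
        x_test=x_te,
        y_test=y_te,
        ids={
            "x_train": id_xtr,
            "y_train": id_ytr,
            "x_test": id_xte,
            "y_test": id_yte,
        },
    )


def equalize_folds(x: np.ndarray, y: np.ndarray, seed: int = 0):
    """Down-sample the larger of two folds so sizes match, with a warning."""
    if len(x) == len(y):
        return x, y
    warnings.warn(
        f"unequal fold sizes ({len(x)} vs {len(y)}); "
        "down-sampling the larger fold to match",
        stacklevel=2,
    )
    rng = np.random.default_rng(seed)
    m = min(len(x), len(y))
    if len(x) > m:
        x = x[rng.choice(len(x), size=m, replace=False)]
    else:
        y = y[rng.choice(len(y), size=m, replace=False)]
    return x, y
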