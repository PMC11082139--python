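"""Detection-rate (power) and type-I-error estimation by repeated sampling.

Each repetition draws a fresh four-fold split from the source and target
samplers with a seed derived from the master seed, retrains the detector
(where the method trains one) and records the reject decision.  Rates carry
95% Wilson confidence intervals.  A sweep evaluates a grid over methods,
shifts, fold sizes and oversampling strengths and returns a tidy table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._nn import TrainConfig
from .hypothesis import TestConfig, TwoSampleTestResult
from .shifts import (
    DistributionSampler,
    ShiftSpec,
    SplitPair,
    make_splits,
    samplers_for_shift,
)
from .synthdata import LabeledDataset

__all__ = [
    "PowerEstimate",
    "detection_rate",
    "type1_error",
    "sweep",
    "wilson_interval",
    "make_test_fn",
]

# test_fn contract: (splits, seed) -> TwoSampleTestResult
TestFn = Callable[[SplitPair, int], TwoSampleTestResult]


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


@dataclass
class PowerEstimate:
    """Rejection rate over repeated draws with binomial uncertainty."""

    n_reps: int
    n_rejections: int
    ci_low: float
    ci_high: float
    n_errors: int = 0
    failed: bool = False

    @property
    def rate(self) -> float:
        return self.n_rejections / self.n_reps if self.n_reps else float("nan")

    @classmethod
    def from_counts(
        cls, n_rejections: int, n_reps: int, n_errors: int = 0, failed: bool = False
    ) -> "PowerEstimate":
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if n_rejections > n_reps:
            raise ValueError("n_rejections cannot exceed n_reps")
        lo, hi = wilson_interval(n_rejections, n_reps)
        return cls(
            n_reps=n_reps,
            n_rejections=n_rejections,
            ci_low=lo,
            ci_high=hi,
            n_errors=n_errors,
            failed=failed,
        )


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def detection_rate(
    test_fn: TestFn,
    source: DistributionSampler,
    target: DistributionSampler,
    n_train: int,
    m: int,
    n_reps: int = 100,
    seed: int = 0,
    max_error_fraction: float = 0.1,
) -> PowerEstimate:
    """Rejection fraction over ``n_reps`` independent split-test repetitions.

    Fresh folds are drawn per repetition (so trainable detectors are
    retrained each time).  Repetition errors are recorded; the estimate is
    marked failed when more than ``max_error_fraction`` of repetitions
    error out.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = _child_seeds(seed, n_reps)
    n_reject = 0
    n_err = 0
    n_done = 0
    for rep_seed in seeds:
        try:
            splits = make_splits(source, target, n_train=n_train, m=m, seed=rep_seed)
            result = test_fn(splits, rep_seed)
            n_done += 1
            n_reject += bool(result.reject)
        except Exception as exc:  # noqa: BLE001 - cell failures are data
            n_err += 1
            warnings.warn(f"repetition failed: {exc}", stacklevel=2)
    failed = n_err > max_error_fraction * n_reps or n_done == 0
    if n_done == 0:
        return PowerEstimate(
            n_reps=0, n_rejections=0, ci_low=np.nan, ci_high=np.nan,
            n_errors=n_err, failed=True,
        )
    return PowerEstimate.from_counts(n_reject, n_done, n_errors=n_err, failed=failed)


def type1_error(
    test_fn: TestFn,
    source: DistributionSampler,
    n_train: int,
    m: int,
    n_reps: int = 500,
    seed: int = 0,
) -> PowerEstimate:
    """False-positive rate: detection_rate with the target equal to the source."""
    return detection_rate(
        test_fn, source, source, n_train=n_train, m=m, n_reps=n_reps, seed=seed
    )


def make_test_fn(
    method: str,
    alpha: float = 0.05,
    n_permutations: int = 100,
    backbone: str = "small",
    train_config: TrainConfig | None = None,
    task_model=None,
) -> TestFn:
    """Build a ``(splits, seed) -> result`` callable for one detector.

    ``muks`` requires a trained ``task_model`` and consumes only the test
    folds of each split (its n_train is always 0).
    """
    from . import c2st as _c2st
    from . import mmdd as _mmdd
    from . import muks as _muks

    if method == "c2st":

        def fn(splits: SplitPair, seed: int) -> TwoSampleTestResult:
            cfg = TestConfig(
                alpha=alpha, n_permutations=n_permutations, seed=seed,
                sidedness="two_sided_signed",
            )
            tc = train_config or TrainConfig(seed=seed)
            if tc.seed != seed:
                tc = TrainConfig(**{**tc.__dict__, "seed": seed})
            return _c2st.c2st_test(splits, cfg, tc, backbone=backbone)

    elif method == "mmdd":

        def fn(splits: SplitPair, seed: int) -> TwoSampleTestResult:
            cfg = TestConfig(
                alpha=alpha, n_permutations=n_permutations, seed=seed,
                sidedness="upper_tail",
            )
            tc = train_config or TrainConfig(batch_size=32, seed=seed)
            if tc.seed != seed:
                tc = TrainConfig(**{**tc.__dict__, "seed": seed})
            return _mmdd.mmdd_test(splits, cfg, tc)

    elif method == "muks":
        if task_model is None:
            raise ValueError("muks requires a trained task_model")

        def fn(splits: SplitPair, seed: int) -> TwoSampleTestResult:
            return _muks.muks_test(
                task_model, splits.x_test, splits.y_test, alpha=alpha, seed=seed
            )

    else:
        raise ValueError(f"unknown method {method!r}")
    return fn


DEFAULT_M_AXIS = (10, 30, 50, 100, 200, 500)
DEFAULT_W_AXIS = (1, 5, 10, 100)


@dataclass
class SweepGrid:
    """Axes of a power sweep; every cell is a full detection_rate run."""

    methods: Sequence[str] = ("c2st",)
    shifts: Sequence[ShiftSpec] = (ShiftSpec(kind="null"),)
    n_train_values: Sequence[int] = (200,)
    m_values: Sequence[int] = DEFAULT_M_AXIS
    n_reps: int = 100
    alpha: float = 0.05
    n_permutations: int = 100
    backbone: str = "small"


def sweep(
    grid: SweepGrid,
    dataset: LabeledDataset,
    seed: int = 0,
    ood_dataset: LabeledDataset | None = None,
    task_model=None,
    train_config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Evaluate every grid cell; returns a tidy table, one row per cell.

    Columns follow the external CSV contract: method, shift_kind,
    attribute, w, n_train, m, image_size, backbone, n_reps, n_reject,
    rate, ci_lo, ci_hi, seed, failed.  Per-cell failures are recorded and
    the sweep continues.
    """
    cells = [
        (method, shift, n_train, m)
        for method in grid.methods
        for shift in grid.shifts
        for n_train in grid.n_train_values
        for m in grid.m_values
    ]
    if not cells:
        raise ValueError("sweep grid is empty")
    cell_seeds = _child_seeds(seed, len(cells))
    image_size = dataset.images.shape[1]
    rows = []
    for (method, shift, n_train, m), cell_seed in zip(cells, cell_seeds):
        row = {
            "method": method,
            "shift_kind": shift.kind,
            "attribute": shift.attribute or "",
            "w": shift.w if shift.kind == "oversample" else np.nan,
            "n_train": 0 if method == "muks" else n_train,
            "m": m,
            "image_size": image_size,
            "backbone": grid.backbone if method == "c2st" else "",
            "seed": cell_seed,
        }
        try:
            source, target = samplers_for_shift(dataset, shift, ood_dataset)
            fn = make_test_fn(
                method,
                alpha=grid.alpha,
                n_permutations=grid.n_permutations,
                backbone=grid.backbone,
                train_config=train_config,
                task_model=task_model,
            )
            est = detection_rate(
                fn, source, target,
                n_train=row["n_train"], m=m, n_reps=grid.n_reps, seed=cell_seed,
            )
            row.update(
                n_reps=est.n_reps,
                n_reject=est.n_rejections,
                rate=est.rate,
                ci_lo=est.ci_low,
                ci_hi=est.ci_high,
                failed=est.failed,
            )
        except Exception as exc:  # noqa: BLE001 - mark the cell, keep sweeping
            warnings.warn(f"sweep cell failed: {exc}", stacklevel=2)
            row.update(
                n_reps=0, n_reject=0, rate=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                failed=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
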