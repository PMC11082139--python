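"""Shared permutation-test engine and decision rule.

All detectors reduce to the same scheme: compute a statistic t(X, Y) on two
equal-size held-out folds, build its null distribution by re-partitioning
the pooled folds at random, and reject H0: P = Q when the add-one
permutation p-value falls at or below the significance level alpha.
Permutations re-partition precomputed per-image quantities (logits, kernel
matrix rows); detectors are never retrained inside the permutation loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = ["TestConfig", "TwoSampleTestResult", "permutation_pvalue", "decide"]


@dataclass(frozen=True)
class TestConfig:
    """Test-level knobs shared by all detectors.

    alpha:
        Significance level, default 0.05.
    n_permutations:
        Number B of random re-partitions; the p-value resolution is
        1/(1+B), so the default B = 100 resolves decisions at alpha = 0.05.
    sidedness:
        ``two_sided_signed`` compares |t| (signed statistics such as the
        classifier logit difference); ``upper_tail`` compares t directly
        (nonnegative discrepancies such as MMD).
    """

    alpha: float = 0.05
    n_permutations: int = 100
    seed: int = 0
    sidedness: str = "two_sided_signed"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.sidedness not in ("two_sided_signed", "upper_tail"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class TwoSampleTestResult:
    """Outcome of one two-sample test."""

    method: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    m: int
    n_train: int
    seed: int | None = None
    per_class_p_values: list[float] | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject": self.reject,
            "m": self.m,
            "n_train": self.n_train,
            "seed": self.seed,
        }
        if self.per_class_p_values is not None:
            d["per_class_p_values"] = list(self.per_class_p_values)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def permutation_pvalue(
    t_obs: float,
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    X: np.ndarray,
    Y: np.ndarray,
    config: TestConfig,
) -> float:
    """Add-one permutation p-value for an observed statistic.

    Pools X and Y (equal sizes m), draws B random balanced re-partitions,
    recomputes the statistic on each and returns

        p = (1 + #{permuted t at least as extreme as t_obs}) / (1 + B).

    "At least as extreme" means |t| >= |t_obs| under ``two_sided_signed``
    and t >= t_obs under ``upper_tail``.  The add-one form guarantees
    p in [1/(1+B), 1] and validity P(p <= alpha) <= alpha under
    exchangeability.
    """
    if len(X) != len(Y):
        raise ValueError(f"fold sizes must match, got {len(X)} and {len(Y)}")
    if not np.isfinite(t_obs):
        raise ValueError(f"non-finite observed statistic: {t_obs}")
    m = len(X)
    pool = np.concatenate([np.asarray(X), np.asarray(Y)], axis=0)
    rng = np.random.default_rng(config.seed)
    # Numerical ties count as extreme (conservative: can only raise p);
    # re-partitions that reproduce t_obs up to summation order must not be
    # dropped by floating-point noise.
    tol = 1e-12 * max(1.0, abs(t_obs))
    count = 0
    for _ in range(config.n_permutations):
        perm = rng.permutation(2 * m)
        t_b = statistic_fn(pool[perm[:m]], pool[perm[m:]])
        if not np.isfinite(t_b):
            raise ValueError("non-finite permuted statistic")
        if config.sidedness == "two_sided_signed":
            extreme = abs(t_b) >= abs(t_obs) - tol
        else:
            extreme = t_b >= t_obs - tol
        count += bool(extreme)
    return (1 + count) / (1 + config.n_permutations)


def decide(p: float, alpha: float) -> bool:
    """Reject H0 iff p <= alpha (the boundary p = alpha rejects)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return p <= alpha
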