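"""Multiple univariate Kolmogorov-Smirnov tests on task-model softmax outputs.

MUKS monitors a deployed task classifier without requiring any training
data from the target distribution: the classifier's C-dimensional softmax
output is used as a low-dimensional representation, a two-sample KS test is
run per class on the class-c marginals of the two folds, and the family of
C tests is combined with a Bonferroni correction (reject H0 when any
per-class p-value is at or below alpha / C).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .hypothesis import TwoSampleTestResult
from .shifts import equalize_folds

__all__ = ["softmax_features", "ks_statistic", "ks_pvalue", "muks_test"]

_SIMPLEX_TOL = 1e-6


def softmax_features(f_task, X: np.ndarray) -> np.ndarray:
    """Per-image softmax vectors from a trained task classifier.

    ``f_task`` must expose ``predict_proba(images) -> (n, C)``; rows are
    validated to lie on the probability simplex within 1e-6.
    """
    if len(X) == 0:
        raise ValueError("X must be nonempty")
    if not getattr(f_task, "trained", True):
        raise ValueError("task classifier is not trained")
    probs = np.asarray(f_task.predict_proba(X), dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError("predict_proba must return an (n, C) array")
    if (probs < -_SIMPLEX_TOL).any() or np.abs(
        probs.sum(axis=1) - 1.0
    ).max() > _SIMPLEX_TOL:
        raise ValueError("softmax outputs do not lie on the probability simplex")
    return probs


def ks_statistic(u: np.ndarray, v: np.ndarray) -> float:
    """Two-sample KS statistic D = sup_t |F_u(t) - F_v(t)| in [0, 1].

    The supremum of the right-continuous empirical distribution functions
    is attained at a pooled data point; ties are handled by evaluating at
    pooled unique points, with no randomised tie-breaking.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) == 0 or len(v) == 0:
        raise ValueError("both samples must be nonempty")
    su, sv = np.sort(u), np.sort(v)
    grid = np.unique(np.concatenate([su, sv]))
    fu = np.searchsorted(su, grid, side="right") / len(su)
    fv = np.searchsorted(sv, grid, side="right") / len(sv)
    return float(np.abs(fu - fv).max())


def ks_pvalue(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(D, p) for the two-sample KS test.

    Exact small-sample computation when both sizes are at most 25,
    otherwise the asymptotic two-sample Kolmogorov distribution with the
    standard effective-size correction.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    method = "exact" if (len(u) <= 25 and len(v) <= 25) else "asymp"
    res = stats.ks_2samp(u, v, method=method)
    return float(res.statistic), float(res.pvalue)


def muks_test(
    f_task, X: np.ndarray, Y: np.ndarray, alpha: float = 0.05, seed: int = 0
) -> TwoSampleTestResult:
    """Bonferroni-combined per-class KS tests on softmax marginals.

    Consumes only the task model (trained on source data) and the two test
    folds; no detector training and hence no target-distribution training
    data (n_train = 0).  The reported overall p-value is the Bonferroni
    bound min(1, C * min_c p_c); the decision rule is min_c p_c <= alpha/C.
    """
    if len(X) < 2 or len(Y) < 2:
        raise ValueError("both folds need at least 2 samples")
    X, Y = equalize_folds(np.asarray(X), np.asarray(Y), seed=seed)
    sx = softmax_features(f_task, X)
    sy = softmax_features(f_task, Y)
    n_classes = sx.shape[1]
    if n_classes < 2:
        raise ValueError("task classifier must have at least 2 outputs")
    stats_p = [ks_pvalue(sx[:, c], sy[:, c]) for c in range(n_classes)]
    d_values = [d for d, _ in stats_p]
    p_values = [p for _, p in stats_p]
    p_min = min(p_values)
    reject = p_min <= alpha / n_classes
    return TwoSampleTestResult(
        method="muks",
        statistic=float(max(d_values)),
        p_value=float(min(1.0, n_classes * p_min)),
        alpha=alpha,
        reject=bool(reject),
        m=len(X),
        n_train=0,
        seed=seed,
        per_class_p_values=[float(p) for p in p_values],
    )
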