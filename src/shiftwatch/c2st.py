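"""Classifier two-sample test (C2ST).

A binary domain classifier is trained to separate source images (label 0)
from target images (label 1); on held-out folds the mean logit over the
source fold minus the mean logit over the target fold serves as the test
statistic, with a signed two-sided permutation test over the precomputed
per-image logits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._nn import MLP, TrainConfig, train_classifier
from .hypothesis import TestConfig, TwoSampleTestResult, decide, permutation_pvalue
from .shifts import SplitPair

__all__ = [
    "BACKBONES",
    "DomainClassifier",
    "train_domain_classifier",
    "c2st_statistic",
    "c2st_test",
]

# Hidden-layer widths per backbone tag.  "shallow" is a linear model;
# larger tags trade training time for discriminative capacity, mirroring
# the observation that a weaker domain classifier loses test power.
BACKBONES: dict[str, tuple[int, ...]] = {
    "shallow": (),
    "small": (32,),
    "large": (128, 64),
}


@dataclass
class DomainClassifier:
    """Trained source-vs-target discriminator with a scalar logit output."""

    net: MLP
    backbone: str
    image_shape: tuple[int, ...]

    def logits(self, images: np.ndarray) -> np.ndarray:
        """Per-image real-valued logit (log-odds of the target domain)."""
        z = self.net.forward(np.asarray(images, dtype=np.float32))
        return (z[:, 1] - z[:, 0]).astype(np.float64)

    def accuracy(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Held-out domain accuracy on a balanced (source, target) pair."""
        lx, ly = self.logits(X), self.logits(Y)
        return float(((lx <= 0).sum() + (ly > 0).sum()) / (len(lx) + len(ly)))


def train_domain_classifier(
    s_p_train: np.ndarray,
    s_q_train: np.ndarray,
    config: TrainConfig | None = None,
    backbone: str = "small",
) -> DomainClassifier:
    """Fit the domain classifier on the two training folds.

    Source images get label 0 and target images label 1; no task labels are
    consulted.  Class balance is exact by construction since fold sizes are
    equal.  Reproducible given the config seed.
    """
    if len(s_p_train) == 0 or len(s_q_train) == 0:
        raise ValueError("both training folds must be nonempty")
    if s_p_train.shape[1:] != s_q_train.shape[1:]:
        raise ValueError("source and target images must share a shape")
    if backbone not in BACKBONES:
        raise ValueError(f"unknown backbone {backbone!r}; choose from {sorted(BACKBONES)}")
    config = config or TrainConfig()
    d = int(np.prod(s_p_train.shape[1:]))
    net = MLP((d, *BACKBONES[backbone], 2), seed=config.seed)
    images = np.concatenate([s_p_train, s_q_train], axis=0)
    labels = np.concatenate(
        [np.zeros(len(s_p_train), dtype=int), np.ones(len(s_q_train), dtype=int)]
    )
    train_classifier(net, images, labels, config)
    return DomainClassifier(net=net, backbone=backbone, image_shape=s_p_train.shape[1:])


def c2st_statistic(f: DomainClassifier, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean logit over X minus mean logit over Y.

    Exactly antisymmetric: swapping the folds flips the sign.
    """
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("folds must be nonempty")
    if len(X) != len(Y):
        raise ValueError(f"fold sizes must match, got {len(X)} and {len(Y)}")
    return float(f.logits(X).mean() - f.logits(Y).mean())


def c2st_test(
    splits: SplitPair,
    config: TestConfig | None = None,
    train_config: TrainConfig | None = None,
    backbone: str = "small",
) -> TwoSampleTestResult:
    """Full C2ST: train on the training folds, test on the held-out folds.

    The permutation null re-partitions the precomputed per-image logits of
    the pooled test folds; the classifier is not retrained per permutation.
    """
    config = config or TestConfig()
    if config.sidedness != "two_sided_signed":
        config = replace(config, sidedness="two_sided_signed")
    if splits.n_train < 1:
        raise ValueError("C2ST requires n_train >= 1")
    if train_config is None:
        train_config = TrainConfig(seed=config.seed)
    clf = train_domain_classifier(
        splits.x_train, splits.y_train, train_config, backbone=backbone
    )
    logits_x = clf.logits(splits.x_test)
    logits_y = clf.logits(splits.y_test)
    t_obs = float(logits_x.mean() - logits_y.mean())
    p = permutation_pvalue(
        t_obs,
        lambda u, v: float(u.mean() - v.mean()),
        logits_x,
        logits_y,
        config,
    )
    return TwoSampleTestResult(
        method="c2st",
        statistic=t_obs,
        p_value=p,
        alpha=config.alpha,
        reject=decide(p, config.alpha),
        m=splits.m,
        n_train=splits.n_train,
        seed=config.seed,
    )
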