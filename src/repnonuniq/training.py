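"""Training protocols that produce similar-performing network pairs.

A *similar performing pair* is two networks with the same architecture,
different parameters, and closely matched test accuracy.  Two protocols
produce such pairs:

Scheme-1
    Train the same architecture twice from independent random
    initializations, minimizing softmax cross-entropy only.

Scheme-2
    Train the first network as in Scheme-1, then train the second with a
    combined loss: cross-entropy on its logits plus a Euclidean penalty
    pulling its penultimate activations toward the analytically
    constructed counterpart targets
    ``y = (W2^T W2)^+ W2^T (f(W1 S1(I) + b1) - b2)`` with
    ``f(x) = |x| x``.  The head (W2, b2) used inside the target formula is
    the second network's head *frozen at initialization* — fixed targets
    keep the Euclidean objective well-posed — while the live head receives
    gradients from the cross-entropy term only.

Everything is deterministic given the config seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from ._engine import SGDMomentum, softmax_cross_entropy
from .nets import (
    ClassifierHead,
    TrainedNetwork,
    accuracy,
    build_network,
    parse_architecture,
)
from .propositions import MonotoneTransform, apply_transform, get_transform, preimage_operator
from .synthdata import LabeledImageSet

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "PairResult",
    "train_single",
    "train_pair_scheme1",
    "compute_scheme2_targets",
    "train_scheme2",
    "is_similar_performing",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for one training run.

    Defaults are the package's scaled-down reference profile: SGD with
    momentum 0.9, learning rate 0.01 with cosine decay, 10 epochs,
    batches of 32.  ``scheme2_lambda`` weights the Euclidean penalty
    (averaged over batch and units) against the cross-entropy term.
    """

    architecture: tuple[str, ...]
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 0.01
    optimizer_name: str = "sgd_momentum"
    momentum: float = 0.9
    seed: int = 0
    scheme: int = 1
    scheme2_lambda: float = 1.0
    transform_name: str = "signed_square"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.scheme not in (1, 2):
            raise ValueError("scheme must be 1 or 2")
        if self.scheme2_lambda < 0:
            raise ValueError("scheme2_lambda must be >= 0")
        if self.optimizer_name != "sgd_momentum":
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")
        if self.scheme == 2:
            get_transform(self.transform_name)  # must be registered
        object.__setattr__(self, "architecture", tuple(self.architecture))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TrainingLog:
    """Per-epoch training diagnostics."""

    epoch_ce: list[float] = field(default_factory=list)
    epoch_euclid: list[float] = field(default_factory=list)
    batch_ce: list[list[float]] = field(default_factory=list)
    test_accuracy: float | None = None


@dataclass
class PairResult:
    """A trained pair with its accuracies and logs."""

    net1: TrainedNetwork
    net2: TrainedNetwork
    acc1: float
    acc2: float
    log1: TrainingLog
    log2: TrainingLog
    scheme: int = 1

    def accuracy_gap(self) -> float:
        return abs(self.acc1 - self.acc2)


def is_similar_performing(pair: PairResult, threshold: float = 0.05) -> bool:
    """Gate on matched performance: |acc1 - acc2| <= threshold."""
    return pair.accuracy_gap() <= threshold


def _evaluate(net: TrainedNetwork, test: LabeledImageSet) -> float:
    return accuracy(net.predict(test.images), test.labels)


def _run_training(
    config: TrainConfig,
    train: LabeledImageSet,
    test: LabeledImageSet,
    init_seed: int,
    targets: np.ndarray | None = None,
    lam: float = 0.0,
) -> tuple[TrainedNetwork, TrainingLog]:
    """Shared SGD loop; ``targets`` adds the Euclidean penultimate penalty.

    With ``targets=None`` or ``lam=0`` this is plain cross-entropy
    training; the RNG consumption is identical either way, so a lambda=0
    run reproduces the Scheme-1 batch losses exactly.
    """
    side = train.images.shape[1]
    spec = parse_architecture(
        config.architecture, (side, side, train.images.shape[3]), train.num_classes
    )
    net = build_network(spec, seed=init_seed)
    log = TrainingLog()
    if config.epochs == 0:
        acc = _evaluate(net, test)
        net.test_accuracy = log.test_accuracy = acc
        return net, log
    opt = SGDMomentum(net.layers, lr=config.learning_rate, momentum=config.momentum)
    shuffle_rng = np.random.default_rng([init_seed, 0x5EED])
    images, labels = train.images, train.labels
    n = len(labels)
    head_layer = net.layers[-1]
    for epoch in range(config.epochs):
        opt.set_cosine_lr(epoch, config.epochs)
        perm = shuffle_rng.permutation(n)
        ce_losses: list[float] = []
        euclid_losses: list[float] = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x = net._to_nchw(images[idx])
            for layer in net.layers[:-1]:
                x = layer.forward(x, train=True)
            penult = x
            logits = head_layer.forward(penult, train=True)
            loss_ce, dlogits = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss_ce):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss_ce}"
                )
            grad = head_layer.backward(dlogits)
            if targets is not None:
                diff = penult - targets[idx]
                euclid_losses.append(float(np.mean(diff**2)))
                if lam > 0:
                    grad = grad + lam * 2.0 * diff / diff.size
            for layer in reversed(net.layers[:-1]):
                grad = layer.backward(grad)
            opt.step()
            ce_losses.append(loss_ce)
        log.epoch_ce.append(float(np.mean(ce_losses)))
        log.batch_ce.append(ce_losses)
        if euclid_losses:
            log.epoch_euclid.append(float(np.mean(euclid_losses)))
    acc = _evaluate(net, test)
    net.test_accuracy = log.test_accuracy = acc
    return net, log


def train_single(
    config: TrainConfig, train: LabeledImageSet, test: LabeledImageSet
) -> tuple[TrainedNetwork, TrainingLog]:
    """Train one network by minimizing softmax cross-entropy only."""
    return _run_training(config, train, test, init_seed=config.seed)


def train_pair_scheme1(
    config: TrainConfig,
    train: LabeledImageSet,
    test: LabeledImageSet,
    seed1: int,
    seed2: int,
) -> PairResult:
    """Two independent random initializations of the same architecture."""
    if seed1 == seed2:
        raise ValueError("seed1 and seed2 must differ for an independent pair")
    net1, log1 = _run_training(config, train, test, init_seed=seed1)
    net2, log2 = _run_training(config, train, test, init_seed=seed2)
    return PairResult(
        net1=net1,
        net2=net2,
        acc1=net1.test_accuracy,
        acc2=net2.test_accuracy,
        log1=log1,
        log2=log2,
        scheme=1,
    )


def compute_scheme2_targets(
    net1: TrainedNetwork,
    head2: ClassifierHead,
    f: MonotoneTransform | str,
    images: np.ndarray,
) -> np.ndarray:
    """Counterpart penultimate targets for a batch of images.

    Pure function of (net1, head2, f, images): targets are
    ``(W2^T W2)^+ W2^T (f(net1 logits) - b2)`` per stimulus, so
    ``W2 y + b2 = f(x')`` exactly when head2 has full row rank.
    """
    if not head2.has_full_row_rank():
        raise ValueError("head2 must have full row rank")
    if head2.M <= head2.N:
        raise ValueError("head2 must satisfy M > N")
    x_logits = net1.logits(images)
    targets = apply_transform(f, x_logits)
    return (targets - head2.b) @ preimage_operator(head2).T


def train_scheme2(
    config: TrainConfig,
    train: LabeledImageSet,
    test: LabeledImageSet,
    net1: TrainedNetwork,
) -> PairResult:
    """Train the second network of a pair toward the constructed targets.

    ``net1`` must already be trained.  The second network is initialized
    from ``config.seed``; its initial head defines the Eq.-style targets,
    which stay fixed for the whole run.  The loss is cross-entropy plus
    ``scheme2_lambda`` times the mean squared penultimate error.
    """
    side = train.images.shape[1]
    spec = parse_architecture(
        config.architecture, (side, side, train.images.shape[3]), train.num_classes
    )
    init_net = build_network(spec, seed=config.seed)
    frozen_head = ClassifierHead(
        W=init_net.head.W.copy(), b=init_net.head.b.copy()
    )
    targets = compute_scheme2_targets(
        net1, frozen_head, config.transform_name, train.images
    )
    net2, log2 = _run_training(
        config,
        train,
        test,
        init_seed=config.seed,
        targets=targets,
        lam=config.scheme2_lambda,
    )
    log1 = TrainingLog(test_accuracy=net1.test_accuracy)
    acc1 = (
        net1.test_accuracy
        if net1.test_accuracy is not None
        else _evaluate(net1, test)
    )
    return PairResult(
        net1=net1,
        net2=net2,
        acc1=acc1,
        acc2=net2.test_accuracy,
        log1=log1,
        log2=log2,
        scheme=2,
    )
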