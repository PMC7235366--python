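"""Small convolutional classifiers built from a column-token grammar.

Architectures are written as ordered token lists, e.g.::

    ["Conv5-32", "Max-pool", "Conv5-32", "Max-pool",
     "Conv5-64", "Max-pool", "Fc-64", "Fc-10"]

Tokens: ``Conv<k>-<c>`` (k x k convolution, c channels), ``Conv<k>-bn-<c>``
(with batch normalization before the nonlinearity), ``Max-pool`` (2x2,
stride 2) and ``Fc-<u>``.  Kernel sizes are restricted to {3, 5}.  ReLU
follows every convolution and every hidden fully connected layer.  The
last token is the linear classification head ``Fc-N``; the *object
representation* of an image is the activation vector of the layer feeding
that head (width M), taken after its nonlinearity.  The head is the only
computation after the penultimate layer, so ``logits = W @ rep + b``
holds exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._engine import (
    BatchNorm2D,
    Conv2D,
    Dense,
    Flatten,
    Layer,
    MaxPool2,
    ReLU,
)

__all__ = [
    "ArchitectureSpec",
    "ClassifierHead",
    "TrainedNetwork",
    "ArchitectureError",
    "parse_architecture",
    "build_network",
    "forward_collect",
    "accuracy",
    "save_network",
    "load_network",
    "TABLE_ARCHITECTURES",
    "REFERENCE_TOKENS",
]

_CONV_RE = re.compile(r"^Conv(\d+)(-bn)?-(\d+)$")
_FC_RE = re.compile(r"^Fc-(\d+)$")


class ArchitectureError(ValueError):
    """Raised when a token list violates the architecture grammar."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """A validated architecture: tokens plus derived layer shapes.

    ``penultimate_width`` is M, the unit count of the layer feeding the
    final classification head; ``num_classes`` is N.
    """

    layer_tokens: tuple[str, ...]
    input_shape: tuple[int, int, int]  # (side, side, channels)
    num_classes: int
    penultimate_width: int
    layer_shapes: tuple[tuple[int, ...], ...] = field(default=(), repr=False)

    @property
    def M(self) -> int:
        return self.penultimate_width

    @property
    def N(self) -> int:
        return self.num_classes


@dataclass
class ClassifierHead:
    """Final fully connected layer: logits = W @ rep + b, W is N x M."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64).ravel()
        if self.W.ndim != 2 or self.W.shape[0] != self.b.shape[0]:
            raise ValueError("head shapes inconsistent: W is N x M, b is N")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]

    def min_singular_value(self) -> float:
        return float(np.linalg.svd(self.W, compute_uv=False)[-1])

    def has_full_row_rank(self, tol: float = 1e-8) -> bool:
        return self.min_singular_value() > tol


def parse_architecture(
    tokens: list[str] | tuple[str, ...],
    input_shape: tuple[int, int, int],
    num_classes: int,
    require_overcomplete: bool = False,
) -> ArchitectureSpec:
    """Validate a token list and compute the penultimate width M.

    ``require_overcomplete=True`` additionally enforces M > N, the
    admissibility precondition of the pseudo-inverse counterexample
    construction.
    """
    if not tokens:
        raise ArchitectureError("empty architecture")
    H, W, C = input_shape
    shapes: list[tuple[int, ...]] = [(H, W, C)]
    widths: list[int] = []
    in_fc_tail = False
    flat: int | None = None
    for tok in tokens:
        m = _CONV_RE.match(tok)
        if m:
            if in_fc_tail:
                raise ArchitectureError(
                    f"token {tok!r}: convolution after a fully connected layer"
                )
            k = int(m.group(1))
            if k not in (3, 5):
                raise ArchitectureError(
                    f"token {tok!r}: kernel size {k} outside grammar {{3, 5}}"
                )
            C = int(m.group(3))
            shapes.append((H, W, C))
            continue
        if tok == "Max-pool":
            if in_fc_tail:
                raise ArchitectureError(f"token {tok!r}: pooling after Fc")
            if H // 2 < 1 or W // 2 < 1:
                raise ArchitectureError(
                    f"token {tok!r}: pooling underflows spatial size {H}x{W}"
                )
            H, W = H // 2, W // 2
            shapes.append((H, W, C))
            continue
        m = _FC_RE.match(tok)
        if m:
            if not in_fc_tail:
                flat = H * W * C
                in_fc_tail = True
                widths.append(flat)
            u = int(m.group(1))
            widths.append(u)
            shapes.append((u,))
            continue
        raise ArchitectureError(f"unknown token {tok!r}")
    if not in_fc_tail:
        raise ArchitectureError("architecture must end with an Fc-<N> head")
    if widths[-1] != num_classes:
        raise ArchitectureError(
            f"last token Fc-{widths[-1]} does not match num_classes={num_classes}"
        )
    M = widths[-2]
    if require_overcomplete and M <= num_classes:
        raise ArchitectureError(
            f"penultimate width M={M} must exceed N={num_classes} for the "
            "pseudo-inverse construction"
        )
    return ArchitectureSpec(
        layer_tokens=tuple(tokens),
        input_shape=tuple(input_shape),
        num_classes=num_classes,
        penultimate_width=M,
        layer_shapes=tuple(shapes),
    )


@dataclass
class TrainedNetwork:
    """A feature extractor S(.) plus a linear classification head.

    ``layers`` hold the learned state; ``penultimate(images)`` returns the
    n x M object-representation matrix and ``logits`` applies the head on
    top of it.  Evaluation always runs the layers in inference mode
    (batch-norm running statistics frozen), so representations are a
    deterministic function of the parameters and the stimuli.
    """

    spec: ArchitectureSpec
    layers: list[Layer]
    seed: int = 0
    test_accuracy: float | None = None

    @property
    def head(self) -> ClassifierHead:
        final: Dense = self.layers[-1]  # type: ignore[assignment]
        return ClassifierHead(W=final.W, b=final.b)

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 4:
            raise ValueError("expected images of shape (n, side, side, channels)")
        side, _, ch = self.spec.input_shape
        if images.shape[1:] != (side, side, ch):
            raise ValueError(
                f"image shape {images.shape[1:]} does not match network input "
                f"{(side, side, ch)}"
            )
        return np.ascontiguousarray(images.transpose(0, 3, 1, 2))

    def forward(
        self, images: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the network; returns (penultimate n x M, logits n x N)."""
        x = self._to_nchw(images)
        for layer in self.layers[:-1]:
            x = layer.forward(x, train=train)
        penult = x
        logits = self.layers[-1].forward(penult, train=train)
        return penult, logits

    def penultimate(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self._batched(images, batch_size)[0]

    def logits(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self._batched(images, batch_size)[1]

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        # np.argmax breaks exact ties toward the lowest index.
        return np.argmax(self._batched(images, batch_size)[1], axis=1)

    def _batched(
        self, images: np.ndarray, batch_size: int = 256
    ) -> tuple[np.ndarray, np.ndarray]:
        reps, logits = [], []
        for i in range(0, len(images), batch_size):
            r, z = self.forward(images[i : i + batch_size], train=False)
            reps.append(r)
            logits.append(z)
        return np.concatenate(reps), np.concatenate(logits)


def build_network(spec: ArchitectureSpec, seed: int) -> TrainedNetwork:
    """Instantiate a network with fan-in-scaled Gaussian initialization."""
    rng = np.random.default_rng(seed)
    H, W, C = spec.input_shape
    layers: list[Layer] = []
    in_fc = False
    width = 0
    for i, tok in enumerate(spec.layer_tokens):
        m = _CONV_RE.match(tok)
        if m:
            k, bn, c = int(m.group(1)), m.group(2), int(m.group(3))
            layers.append(Conv2D(C, c, k, rng))
            if bn:
                layers.append(BatchNorm2D(c))
            layers.append(ReLU())
            C = c
        elif tok == "Max-pool":
            layers.append(MaxPool2())
            H, W = H // 2, W // 2
        else:  # Fc token; grammar already validated by parse_architecture
            u = int(_FC_RE.match(tok).group(1))
            if not in_fc:
                layers.append(Flatten())
                width = H * W * C
                in_fc = True
            layers.append(Dense(width, u, rng))
            if i < len(spec.layer_tokens) - 1:
                layers.append(ReLU())
            width = u
    return TrainedNetwork(spec=spec, layers=layers, seed=seed)


def forward_collect(net: TrainedNetwork, data) -> tuple["RepresentationMatrix", np.ndarray, np.ndarray]:
    """Collect representations, logits and predicted labels for a stimulus set.

    Rows align with stimulus order; the predicted label is the argmax of
    the logits with ties broken toward the lowest index.
    """
    from .equivalence import RepresentationMatrix

    reps, logits = net._batched(data.images)
    preds = np.argmax(logits, axis=1)
    rep = RepresentationMatrix(values=reps, stimulus_ids=np.arange(len(reps)))
    return rep, logits, preds


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {true.shape}"
        )
    return float(np.mean(predicted == true))


def save_network(net: TrainedNetwork, path: str | Path) -> None:
    """Serialize a network to one .npz checkpoint plus a JSON summary."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(net.layers):
        for j, p in enumerate(layer.params()):
            arrays[f"param_{i}_{j}"] = p
        if isinstance(layer, BatchNorm2D):
            arrays[f"bnmean_{i}"] = layer.running_mean
            arrays[f"bnvar_{i}"] = layer.running_var
    meta = {
        "layer_tokens": list(net.spec.layer_tokens),
        "input_shape": list(net.spec.input_shape),
        "num_classes": net.spec.num_classes,
        "M": net.spec.M,
        "seed": net.seed,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    summary = dict(meta, layer_shapes=[list(s) for s in net.spec.layer_shapes])
    Path(str(path) + ".json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def load_network(path: str | Path) -> TrainedNetwork:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        spec = parse_architecture(
            meta["layer_tokens"], tuple(meta["input_shape"]), meta["num_classes"]
        )
        net = build_network(spec, seed=meta["seed"])
        for i, layer in enumerate(net.layers):
            for j, p in enumerate(layer.params()):
                p[...] = data[f"param_{i}_{j}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = data[f"bnmean_{i}"]
                layer.running_var[...] = data[f"bnvar_{i}"]
    return net


#: The six published column configurations for 32 x 32 RGB inputs.
TABLE_ARCHITECTURES: dict[str, list[str]] = {
    "D1": [
        "Conv5-32", "Max-pool", "Conv5-32", "Max-pool", "Conv5-64",
        "Max-pool", "Fc-64", "Fc-10",
    ],
    "D2": [
        "Conv3-bn-32", "Conv3-bn-32", "Max-pool",
        "Conv3-bn-64", "Conv3-bn-64", "Max-pool",
        "Conv3-bn-128", "Conv3-bn-128", "Max-pool",
        "Conv3-bn-256", "Max-pool", "Fc-10",
    ],
    "D3": [
        "Conv3-bn-64", "Conv3-bn-64", "Max-pool",
        "Conv3-bn-128", "Conv3-bn-128", "Max-pool",
        "Conv3-bn-256", "Conv3-bn-256", "Max-pool",
        "Conv3-bn-512", "Max-pool", "Fc-10",
    ],
    "D4": [
        "Conv3-bn-128", "Conv3-bn-128", "Max-pool",
        "Conv3-bn-256", "Conv3-bn-256", "Max-pool",
        "Conv3-bn-512", "Conv3-bn-512", "Max-pool",
        "Conv3-bn-1024", "Max-pool", "Fc-100",
    ],
    "D5": [
        "Conv3-bn-32", "Conv3-bn-32", "Conv3-bn-32", "Conv3-bn-32", "Max-pool",
        "Conv3-bn-64", "Conv3-bn-64", "Conv3-bn-64", "Conv3-bn-64", "Max-pool",
        "Conv3-bn-128", "Conv3-bn-128", "Conv3-bn-128", "Conv3-bn-128",
        "Max-pool", "Conv3-bn-256", "Conv3-bn-256", "Max-pool", "Fc-10",
    ],
    "D6": [
        "Conv3-bn-64", "Max-pool", "Conv3-bn-128", "Max-pool",
        "Conv3-bn-256", "Conv3-bn-256", "Max-pool",
        "Conv3-bn-512", "Conv3-bn-512", "Max-pool",
        "Conv3-bn-512", "Conv3-bn-512", "Max-pool", "Fc-10",
    ],
}

#: Scaled-down default profile: D1-like at 16 x 16 input with channel
#: widths quartered, so a pair of networks trains in minutes on one CPU.
#: M = 16 > N = 10 keeps the counterexample construction admissible.
REFERENCE_TOKENS: list[str] = [
    "Conv5-8", "Max-pool", "Conv5-8", "Max-pool", "Conv5-16",
    "Max-pool", "Fc-16", "Fc-10",
]
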