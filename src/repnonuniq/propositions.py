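"""Analytic core: softmax argmax invariance and the pseudo-inverse counterexample.

Two facts drive everything in this package:

1. If the logits of a softmax classifier are passed through any strictly
   increasing elementwise map f, the Top-K categorization is unchanged —
   the probability vector changes, the ranking does not.

2. Because the classification head ``x' = W x + b`` has a wide weight
   matrix (N x M with M > N), any target logit vector is exactly
   attainable from the minimum-norm preimage
   ``y = (W^T W)^+ W^T (target - b)``.  Combining the two yields, for a
   trained network with representation x, a *constructed* counterpart
   representation

       y = (W2^T W2)^+ W2^T ( f(W1 S1(I) + b1) - b2 )

   whose categorization agrees with the original on every stimulus, yet
   which is not a linear transform of x whenever f is non-linear.  This
   module realizes that construction numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .nets import ClassifierHead, TrainedNetwork

__all__ = [
    "MonotoneTransform",
    "register_transform",
    "get_transform",
    "BUILTIN_TRANSFORMS",
    "softmax",
    "apply_transform",
    "categorization_agreement",
    "pinv_preimage",
    "preimage_operator",
    "random_full_row_rank_head",
    "construct_counterpart_representation",
]


@dataclass(frozen=True)
class MonotoneTransform:
    """A named scalar map, certified strictly increasing at registration."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.fn(np.asarray(x, dtype=np.float64))


_REGISTRY: dict[str, MonotoneTransform] = {}


def register_transform(
    name: str,
    fn: Callable[[np.ndarray], np.ndarray],
    check_range: tuple[float, float] = (-20.0, 20.0),
    grid_points: int = 10_001,
) -> MonotoneTransform:
    """Register a scalar map after verifying it is strictly increasing.

    Monotonicity is checked empirically on a dense grid spanning
    ``check_range`` widened by 20%; any non-increase rejects the map.
    """
    lo, hi = check_range
    span = hi - lo
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, grid_points)
    vals = np.asarray(fn(grid), dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"transform {name!r}: non-finite values on the check grid")
    if not np.all(np.diff(vals) > 0):
        raise ValueError(f"transform {name!r} is not strictly increasing")
    t = MonotoneTransform(name=name, fn=fn)
    _REGISTRY[name] = t
    return t


def get_transform(name: str) -> MonotoneTransform:
    if name not in _REGISTRY:
        raise KeyError(
            f"transform {name!r} is not registered; known: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def _builtin() -> dict[str, MonotoneTransform]:
    out = {}
    out["identity"] = register_transform("identity", lambda x: x)
    # Signed square |x| * x: the non-linear increasing map used when a
    # second network is explicitly pulled toward the constructed targets.
    out["signed_square"] = register_transform("signed_square", lambda x: np.abs(x) * x)
    out["cube"] = register_transform("cube", lambda x: x**3)
    out["exp"] = register_transform("exp", np.exp, check_range=(-20.0, 20.0))
    out["affine"] = register_transform("affine", lambda x: 2.0 * x + 1.0)
    return out


BUILTIN_TRANSFORMS = _builtin()


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax; rows sum to 1."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax input must be finite")
    z = v - v.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def apply_transform(f: MonotoneTransform | str, v: np.ndarray) -> np.ndarray:
    """Elementwise application of a registered monotone transform."""
    if isinstance(f, str):
        f = get_transform(f)
    elif f.name not in _REGISTRY:
        raise ValueError(f"transform {f.name!r} is not registered")
    return f(v)


def _topk_set(v: np.ndarray, k: int) -> set[int]:
    # Deterministic under exact ties: stable sort on (-value, index).
    order = np.lexsort((np.arange(len(v)), -v))
    return set(order[:k].tolist())


def categorization_agreement(x: np.ndarray, y: np.ndarray, k: int = 1) -> bool:
    """True iff the Top-k index sets of softmax(x) and softmax(y) coincide.

    For k = 1 this is argmax equality (ties broken toward the lowest
    index).  The category ranking is defined on the softmax probability
    vectors; softmax is strictly increasing, so that ranking is identical
    to the ranking of the raw logits, and the comparison is evaluated on
    the logits — exponentiation would underflow well-separated small
    logits to equal probabilities and manufacture spurious ties.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("logit vectors must be finite")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.shape[-1]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < {n}, got k={k}")
    return _topk_set(x, k) == _topk_set(y, k)


def preimage_operator(head: ClassifierHead, rcond: float = 1e-10) -> np.ndarray:
    """The M x N operator P = (W^T W)^+ W^T of the minimum-norm preimage.

    The pseudo-inverse is computed by SVD with a relative singular-value
    cutoff ``rcond * sigma_max`` — (W^T W) is rank-deficient by
    construction when M > N, so a stable cutoff is required.
    """
    W = head.W
    return np.linalg.pinv(W.T @ W, rcond=rcond) @ W.T


def pinv_preimage(
    head: ClassifierHead,
    target_logits: np.ndarray,
    rcond: float = 1e-10,
    rank_tol: float = 1e-8,
) -> tuple[np.ndarray, float, list[str]]:
    """Minimum-norm representation v with ``W v + b = target`` when attainable.

    Returns ``(v, residual, warnings)`` where ``residual`` is the sup-norm
    of ``W v + b - target``.  The residual vanishes (to ~1e-8) whenever W
    has full row rank; near rank deficiency attaches a warning but the
    residual is still reported.
    """
    N, M = head.W.shape
    if M <= N:
        raise ValueError(
            f"pseudo-inverse preimage requires M > N, got M={M}, N={N}"
        )
    warnings: list[str] = []
    if head.min_singular_value() <= rank_tol:
        warnings.append(
            "head is near rank-deficient; target logits may be unattainable"
        )
    target = np.asarray(target_logits, dtype=np.float64)
    v = preimage_operator(head, rcond=rcond) @ (target - head.b)
    residual = float(np.max(np.abs(head.W @ v + head.b - target)))
    return v, residual, warnings


def random_full_row_rank_head(
    M: int,
    N: int,
    rng: np.random.Generator | int,
    sigma_min_tol: float = 1e-3,
    max_tries: int = 100,
) -> ClassifierHead:
    """A fresh Gaussian head (entries ~ N(0, 1/M)) with sigma_min above tol.

    Any full-row-rank head suffices for the counterexample construction;
    re-sampling until the smallest singular value clears the tolerance
    keeps the preimage well-conditioned.
    """
    if M <= N:
        raise ValueError(f"need M > N, got M={M}, N={N}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for _ in range(max_tries):
        W = rng.normal(0.0, 1.0 / np.sqrt(M), size=(N, M))
        b = rng.normal(0.0, 1.0 / np.sqrt(M), size=N)
        head = ClassifierHead(W=W, b=b)
        if head.min_singular_value() > sigma_min_tol:
            return head
    raise RuntimeError("could not draw a well-conditioned head")  # pragma: no cover


def construct_counterpart_representation(
    net1: TrainedNetwork,
    f: MonotoneTransform | str,
    head2: ClassifierHead,
    data,
) -> tuple["RepresentationMatrix", np.ndarray, np.ndarray]:
    """Build the counterpart representation y for every stimulus in ``data``.

    For each image I with logits ``x' = W1 S1(I) + b1``, the counterpart
    is ``y = (W2^T W2)^+ W2^T (f(x') - b2)``, so that ``y' = W2 y + b2``
    equals ``f(x')`` exactly (full-row-rank ``head2``) and the predicted
    labels agree with net1 on every stimulus — while y is, for non-linear
    f, not a linear transform of net1's representation x.

    Returns ``(y as RepresentationMatrix, y' logits, predicted labels)``.
    """
    from .equivalence import RepresentationMatrix

    if isinstance(f, str):
        f = get_transform(f)
    N, M2 = head2.W.shape
    if M2 <= N:
        raise ValueError(f"head2 must be N x M with M > N, got {head2.W.shape}")
    if not head2.has_full_row_rank():
        raise ValueError("head2 must have full row rank")
    if net1.spec.N != N:
        raise ValueError("head2 class count differs from net1")
    x_logits = net1.logits(data.images)  # n x N
    targets = apply_transform(f, x_logits)  # f(x'), elementwise
    P = preimage_operator(head2)  # M x N
    Y = (targets - head2.b) @ P.T  # n x M
    y_logits = Y @ head2.W.T + head2.b
    preds = np.argmax(y_logits, axis=1)
    rep = RepresentationMatrix(values=Y, stimulus_ids=np.arange(len(Y)))
    return rep, y_logits, preds
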