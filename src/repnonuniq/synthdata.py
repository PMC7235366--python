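"""Synthetic labeled image sets emulating small natural-image benchmarks.

The generator produces K balanced classes of small square RGB images in
[0, 1].  Each class is defined by a deterministic low-frequency template
(a seeded random Fourier pattern), and individual images are the template
plus optional integer-pixel translation jitter and i.i.d. Gaussian pixel
noise.  With high template contrast and low noise the classes are easily
separable, so small convolutional classifiers reach high test accuracy in
a few epochs — which is what every downstream analysis here needs.

Stimulus manipulations used by the analyses (additive Gaussian noise at a
grid of sigmas, uniform subsampling without replacement) live here too.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SyntheticImageConfig",
    "LabeledImageSet",
    "class_templates",
    "generate_dataset",
    "generate_train_test",
    "add_gaussian_noise",
    "choose_subsample_indices",
    "subsample_stimuli",
    "save_labeled_set",
    "load_labeled_set",
]


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Parameters of the synthetic image generator.

    Attributes
    ----------
    image_side:
        Side length of the square images, in pixels.
    channels:
        Number of color channels (3 for RGB).
    num_classes:
        Number of object categories K (>= 2).
    per_class_count:
        Images generated per class for one split.
    template_contrast:
        Amplitude of the class template around mid-gray, in (0, 1].
        At 1.0 templates span the full [0, 1] range.
    pixel_noise_sd:
        Standard deviation of i.i.d. Gaussian pixel noise added at
        generation time (images are clipped back to [0, 1] afterwards).
    jitter_pixels:
        Maximum absolute integer translation applied to the template,
        drawn uniformly per image and axis.
    seed:
        Seed controlling templates, jitter and noise.  Identical configs
        produce byte-identical datasets.
    """

    image_side: int = 16
    channels: int = 3
    num_classes: int = 10
    per_class_count: int = 100
    template_contrast: float = 1.0
    pixel_noise_sd: float = 0.05
    jitter_pixels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.per_class_count < 1:
            raise ValueError(
                f"per_class_count must be >= 1, got {self.per_class_count}"
            )
        if self.image_side < 1 or self.channels < 1:
            raise ValueError("image_side and channels must be positive")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if self.jitter_pixels < 0:
            raise ValueError("jitter_pixels must be >= 0")
        if not (0 < self.template_contrast <= 1):
            raise ValueError("template_contrast must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticImageConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class LabeledImageSet:
    """n small RGB images in [0, 1] with integer class labels.

    ``images`` has shape (n, side, side, channels); ``labels`` holds
    integers in [0, K-1].  ``split_name`` tags the split the set belongs
    to ("train", "test", ...).
    """

    images: np.ndarray
    labels: np.ndarray
    split_name: str = "full"
    seed: int = 0
    num_classes: int = field(default=0)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError("images must be (n, side, side, channels)")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels lengths differ")
        if self.num_classes == 0:
            self.num_classes = int(self.labels.max()) + 1 if len(self.labels) else 0

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)


def _split_seed(seed: int, split_name: str) -> int:
    """Derive a per-split seed; stable across runs and platforms."""
    return (seed + zlib.crc32(split_name.encode())) % (2**31)


def class_templates(config: SyntheticImageConfig) -> np.ndarray:
    """Deterministic class templates, shape (K, side, side, channels).

    Each template is a sum of a few low-frequency cosine gratings with
    seeded random orientations, phases and channel weights, rescaled to
    mid-gray +/- template_contrast/2.  Low frequencies keep the patterns
    smooth, so small translations leave classes recognizable.
    """
    rng = np.random.default_rng(config.seed)
    side, ch, K = config.image_side, config.channels, config.num_classes
    yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    templates = np.empty((K, side, side, ch))
    n_components = 4
    for k in range(K):
        pattern = np.zeros((side, side, ch))
        for _ in range(n_components):
            fy, fx = rng.integers(0, 3, size=2)  # cycles over the image, low-freq
            if fy == 0 and fx == 0:
                fx = 1
            phase = rng.uniform(0, 2 * np.pi)
            weights = rng.uniform(0.2, 1.0, size=ch)
            grating = np.cos(2 * np.pi * (fy * yy + fx * xx) / side + phase)
            pattern += grating[:, :, None] * weights[None, None, :]
        lo, hi = pattern.min(), pattern.max()
        unit = (pattern - lo) / (hi - lo)  # -> [0, 1]
        templates[k] = 0.5 + config.template_contrast * (unit - 0.5)
    return templates


def generate_dataset(
    config: SyntheticImageConfig, split_name: str = "train"
) -> LabeledImageSet:
    """Generate one balanced split of synthetic labeled images.

    Deterministic in (config, split_name).  Templates are shared across
    splits of the same config; per-image jitter and noise use a stream
    derived from (seed, split_name), so different splits are disjoint
    with probability 1 whenever noise or jitter is nonzero.
    """
    templates = class_templates(config)
    rng = np.random.default_rng(_split_seed(config.seed, split_name))
    K, m = config.num_classes, config.per_class_count
    side, ch = config.image_side, config.channels
    n = K * m
    images = np.empty((n, side, side, ch))
    labels = np.repeat(np.arange(K), m)
    j = config.jitter_pixels
    for i, lab in enumerate(labels):
        img = templates[lab]
        if j > 0:
            dy, dx = rng.integers(-j, j + 1, size=2)
            img = np.roll(img, (dy, dx), axis=(0, 1))
        if config.pixel_noise_sd > 0:
            img = img + rng.normal(0.0, config.pixel_noise_sd, size=img.shape)
        images[i] = img
    np.clip(images, 0.0, 1.0, out=images)
    return LabeledImageSet(
        images=images,
        labels=labels,
        split_name=split_name,
        seed=config.seed,
        num_classes=K,
    )


def generate_train_test(
    config: SyntheticImageConfig, test_per_class: int | None = None
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Convenience: disjoint balanced train and test splits.

    ``test_per_class`` defaults to half the train per-class count.
    """
    if test_per_class is None:
        test_per_class = max(1, config.per_class_count // 2)
    train = generate_dataset(config, "train")
    test = generate_dataset(replace(config, per_class_count=test_per_class), "test")
    return train, test


def add_gaussian_noise(
    data: LabeledImageSet, sigma: float, seed: int
) -> LabeledImageSet:
    """Add i.i.d. Gaussian(0, sigma^2) noise to every pixel.

    The perturbed images are NOT re-clipped to [0, 1]: clipping would
    truncate the noise distribution and the perturbation is meant to be
    exactly Gaussian.  Labels are unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    noisy = data.images + rng.normal(0.0, sigma, size=data.images.shape)
    return LabeledImageSet(
        images=noisy,
        labels=data.labels.copy(),
        split_name=f"{data.split_name}+noise{sigma:g}",
        seed=seed,
        num_classes=data.num_classes,
    )


def choose_subsample_indices(pool: np.ndarray, size: int, seed: int) -> np.ndarray:
    """Uniform draw of ``size`` indices from ``pool`` without replacement.

    Returned ascending; deterministic given seed.  Shared by
    :func:`subsample_stimuli` and the resampling experiment so both select
    identical stimulus subsets for a given seed.
    """
    pool = np.asarray(pool)
    if size > len(pool):
        raise ValueError(f"size {size} exceeds pool of {len(pool)}")
    if size < 0:
        raise ValueError("size must be >= 0")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=size, replace=False))


def subsample_stimuli(
    data: LabeledImageSet,
    size: int,
    seed: int,
    restrict_to: np.ndarray | None = None,
) -> LabeledImageSet:
    """Uniform subsample of ``size`` stimuli without replacement.

    ``restrict_to`` limits the pool to the given stimulus indices.  The
    chosen indices are returned in ascending order (the draw is uniform
    over index SETS); at ``size == pool size`` the result is therefore
    exactly the pool in its original order.
    """
    pool = np.arange(data.n) if restrict_to is None else np.asarray(restrict_to)
    chosen = choose_subsample_indices(pool, size, seed)
    return LabeledImageSet(
        images=data.images[chosen],
        labels=data.labels[chosen],
        split_name=f"{data.split_name}+sub{size}",
        seed=seed,
        num_classes=data.num_classes,
    )


def save_labeled_set(data: LabeledImageSet, out_dir: str | Path) -> None:
    """Write the set as PNG images plus a CSV manifest and JSON sidecar.

    Pixel values are clipped to [0, 1] and quantized to 8 bit for the
    PNGs; use this for inspection/interchange, not for bit-exact
    round-trips of noisy (out-of-range) images.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(data.images, data.labels)):
        name = f"img_{i:05d}.png"
        arr = np.clip(img, 0, 1)
        Image.fromarray((arr * 255).round().astype(np.uint8)).save(out / name)
        rows.append((name, int(lab), data.split_name))
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "split"])
        w.writerows(rows)
    meta = {
        "n": data.n,
        "shape": list(data.images.shape[1:]),
        "num_classes": data.num_classes,
        "seed": data.seed,
        "split_name": data.split_name,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_labeled_set(in_dir: str | Path) -> LabeledImageSet:
    """Read a PNG + CSV manifest directory written by :func:`save_labeled_set`."""
    from PIL import Image

    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    images, labels = [], []
    with open(src / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(src / row["filename"]), dtype=np.float64)
            images.append(arr / 255.0)
            labels.append(int(row["label"]))
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.array(labels),
        split_name=meta["split_name"],
        seed=meta["seed"],
        num_classes=meta["num_classes"],
    )
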