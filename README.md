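# repnonuniq

Non-uniqueness of object representations in categorization-trained
convolutional networks.

## The problem

A popular modeling strategy in visual neuroscience treats a deep
convolutional network trained *only* to categorize images as a model of
the primate ventral stream: the activations of the penultimate layer are
read out as the model's "object representation" and regressed against
cortical responses. This presumes that optimizing categorization pins
down the representation. It does not. Two networks can have **identical
categorization behavior** while their penultimate representations are
**not related by any linear transformation** — the representation
obtained by the goal-driven recipe is inherently non-unique.

`repnonuniq` makes that statement concrete and testable at desk scale:
it constructs such network pairs both analytically and by training, and
quantifies how far two representations are from linear equivalence.

## The core argument

Let a network compute logits `x' = W₁x + b₁` from its penultimate
representation `x ∈ ℝᴹ`, with `W₁ ∈ ℝᴺˣᴹ`, `M > N`, classified through a
softmax. Two facts:

1. **Monotone invariance.** For any strictly increasing scalar `f`, the
   logits `y' = f(x')` (elementwise) give the same Top-K categorization
   as `x'` for every input: softmax preserves order, and only order
   determines the decision.
2. **Exact preimages.** Because `W₂` is wide (`M > N`) and full row
   rank, any target logit vector is exactly attainable from the
   minimum-norm representation
   `y = (W₂ᵀW₂)⁺W₂ᵀ(y' − b₂)`.

Combining them, for a trained network `S₁` and any full-row-rank head
`(W₂, b₂)`:

```
y = (W₂ᵀW₂)⁺ W₂ᵀ ( f(W₁ S₁(I) + b₁) − b₂ )
```

is a representation with *identical* categorization on every stimulus —
and for non-linear `f` (the package uses `f(x) = |x|x` by default),
`y` is not a linear transform of `x`.

Equivalence is measured by **explained variance (EV)**: fit an affine
map between the two representation matrices on half the stimuli, score
per target neuron on the held-out half, `EV_j = 1 − SS_res/SS_tot`,
average over neurons and both fit directions. EV = 1 iff the relation
is affine on the evaluated stimuli; independent representations score
near 0.

## What is in the package

- `synthdata` — a seeded generator of CIFAR-like balanced labeled image
  sets (10 classes of 16×16 RGB images by default) plus the stimulus
  manipulations used by the analyses (Gaussian pixel noise, subsampling).
- `nets` — small convolutional classifiers described by a column-token
  grammar (`Conv5-32`, `Conv3-bn-64`, `Max-pool`, `Fc-64`, `Fc-10`),
  with the six published column configurations built in and a
  scaled-down reference profile that trains in seconds on one CPU.
  Runs on a self-contained numpy compute engine.
- `propositions` — softmax, registered monotone transforms,
  Top-K agreement, pseudo-inverse preimages and the counterpart
  construction above.
- `training` — Scheme-1 (two random initializations) and Scheme-2
  (cross-entropy plus a Euclidean pull toward the counterpart targets).
- `equivalence` — held-out, symmetrized EV; kurtosis-based neuron
  selectivity profiles.
- `experiments` — the four analyses (standard EV incl. correct-only
  stimuli, noise grid, stimulus-set-size resampling, selectivity
  stratification), emitting reproducible CSV/JSON reports.

## Worked example

`examples/03_analytic_counterpart.py` trains the reference classifier
and builds its behavioral twin:

```
trained network test accuracy: 1.000
label agreement with original: 100.0%
max |y' - f(x')|: 1.08e-12
explained variance between x and y: 0.945
```

The twin agrees with the original on every one of the 500 test stimuli
and reproduces `f(x')` to machine precision, yet the best affine map
between the representations leaves ~5% of held-out variance unexplained
— no behavioral test can distinguish the networks, but their
representations are not equivalent.

`examples/04_scheme1_pair_experiments.py` does the empirical version:
two random initializations of the same architecture reach matched
accuracy (1.000 / 1.000) with headline EV 0.854; the EV barely moves
under pixel noise up to sd 0.1 (0.854 → 0.841), stabilizes once a few
hundred stimuli are used, and drops sharply when only the most selective
(high-kurtosis) neurons are compared (EV 0.15 at the top 10%).
`examples/05_scheme2_training.py` shows that a small Euclidean pull
toward the counterpart targets leaves accuracy at ceiling while driving
EV to −1.09.

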