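# Methods

This note records the models, conventions and numerical choices behind
`repnonuniq`, in the order data flows through the pipeline.

## Synthetic stimuli

The generator emulates the structure of small natural-image benchmarks
(K balanced classes of small square RGB images, pixel values in [0, 1])
without shipping or downloading any data. Each class is a deterministic
template: a sum of four low-frequency cosine gratings with seeded random
orientation, phase and per-channel weights, rescaled to mid-gray ±
`template_contrast/2`. An image is its class template, optionally
translated by an integer jitter (uniform in ±`jitter_pixels` per axis)
and perturbed by i.i.d. Gaussian pixel noise, then clipped to [0, 1].

Reference conditions (the defaults): 10 classes, 16×16×3 images, 100
train / 50 test images per class, contrast 1.0, generation noise sd
0.05, jitter ±1 px, seed-determined everything. These were chosen so
that (a) a nearest-template classifier is at ceiling, (b) the reference
CNN reaches ≥ 90% test accuracy inside 10 epochs on one CPU, and (c) the
whole experiment suite runs in about a minute. Problem sizes throughout
(500 test stimuli, M = 16 penultimate units, 10 resamples per condition)
are the package's desk-scale profile; the full-scale column
architectures remain available through the same grammar.

What the generator does *not* emulate: natural-image statistics,
within-class shape variation, occlusion, or any category-orthogonal
nuisance beyond translation. Consequences worth keeping in mind:

- the reference task is easy enough that trained networks sit at 100%
  test accuracy with saturated logits (|x'| up to ~30);
- pixel noise up to sd 0.1 does not dent accuracy at these conditions,
  so the noise analysis here demonstrates EV *stability* under noise
  rather than the accuracy/EV dissociation visible on harder data;
- passing tests show the measurement machinery is correct and the
  non-uniqueness constructions behave as the theory says; they do not
  certify anything about networks trained on natural images.

**Stimulus manipulations.** Added evaluation noise is *not* re-clipped
to [0, 1]: clipping would truncate the distribution, and the point is an
exactly Gaussian perturbation of normalized images. Subsampling is
uniform without replacement; the chosen indices are returned in
ascending order (the draw is a uniform index *set*), which makes the
full-pool draw the identity and lets degenerate grid points reproduce
the baseline analysis bitwise.

## Networks

Architectures are token lists (`Conv<k>-<c>`, `Conv<k>-bn-<c>`,
`Max-pool`, `Fc-<u>`; kernels in {3, 5}) ending in the linear head
`Fc-N`. Unstated architectural details are fixed as: ReLU after every
convolution and hidden fully connected layer; batch normalization (when
present) between convolution and ReLU; 2×2/stride-2 max pooling; "same"
convolution padding so only pooling shrinks the spatial map. The object
representation is the post-ReLU activation vector of the layer feeding
the head (width M), so `logits = W·rep + b` holds exactly by
construction. Argmax ties (measure zero in practice) break toward the
lowest index everywhere, making agreement checks deterministic.

The reference profile is the 5-layer column at 16×16 input with channel
widths quartered (`Conv5-8 ×2, Conv5-16, Fc-16, Fc-10`), keeping
M = 16 > N = 10 so the preimage construction stays admissible.

The layers run on the package's own numpy engine (im2col convolution,
explicit backward passes, float64); every layer's gradients are verified
against central finite differences in the test suite. Initialization is
fan-in-scaled Gaussian (std √(2/fan_in), biases zero), fully controlled
by seeds.

## The counterpart construction

Given a trained network with head `(W₁, b₁)` and a registered strictly
increasing transform f, the counterpart representation for stimulus I is

    y = (W₂ᵀW₂)⁺ W₂ᵀ ( f(W₁S₁(I) + b₁) − b₂ )

for any full-row-rank `(W₂, b₂)` with M > N. Numerical choices:

- the pseudo-inverse uses SVD with relative cutoff 1e−10·σ_max —
  `W₂ᵀW₂` is rank-deficient by construction (rank N < M), so a stable
  cutoff is required, and the default head is re-sampled (Gaussian,
  scale 1/√M) until σ_min > 1e−3 to keep the preimage well-conditioned;
- transform monotonicity is certified at registration on a 10,001-point
  grid spanning the operating range widened by 20%; non-increasing maps
  are rejected. One global f per construction; per-stimulus transforms
  would work identically but are not implemented;
- Top-K agreement is evaluated on logits, not on softmax outputs.
  Softmax is strictly increasing, so the rankings agree mathematically;
  numerically, exponentiating well-separated logits can underflow
  distinct probabilities to equal floats and manufacture ties, which
  the logit comparison avoids.

## Training schemes

Both schemes minimize softmax cross-entropy with SGD (momentum 0.9,
lr 0.01 with cosine decay, batch 32, 10 epochs by default; all
overridable). Scheme-1 trains the same architecture from two seeds.
Scheme-2 trains the second network with an added Euclidean penalty
`λ · mean((rep₂ − y_target)²)` pulling its penultimate layer toward the
counterpart targets (f(x) = |x|x).

Two points in Scheme-2 were genuinely open and are fixed as follows.
The head `(W₂, b₂)` inside the target formula is the second network's
head *frozen at initialization*: fixed targets make the Euclidean
objective well-posed, whereas a concurrently-trained head would chase
its own targets. The penalty is averaged (not summed) over batch and
units, which only rescales λ. With λ = 0 the loop is bitwise identical
to Scheme-1 training (verified per batch). Batch-norm statistics are
frozen in evaluation mode whenever representations are extracted.

A caveat at desk scale: the reference net1 is at ceiling with saturated
logits, so the |x|x targets have magnitudes ~10³ and at λ = 1 the
Euclidean term dominates, driving the second network's accuracy to
chance even as the residual falls. A small weight (λ ≈ 1e−3) keeps the
pair at matched ceiling accuracy while pushing headline EV far below
the Scheme-1 level (to ≈ −1.1 in the shipped example) — the intended
construction, at a λ suited to saturated logits. λ stays 1.0 by default;
`examples/05_scheme2_training.py` shows both regimes.

## Explained variance

For aligned representation matrices X (n×M₁) and Y (n×M₂): one seeded
50/50 stimulus split serves both directions; an affine map (intercept
column, ordinary least squares, minimum-norm when underdetermined;
optional ridge, default 0, recorded in every report) is fit on the fit
split; per target neuron on the held-out split,
`EV_j = 1 − SS_res,j / SS_tot,j` with SS_tot about the held-out mean.
Negative per-neuron EVs are retained. The directional mean excludes
neurons with (near-)zero variance on *either* split, with the count
logged: zero eval variance makes EV_j undefined, and zero fit variance
makes the neuron unfittable — typically a ReLU unit silent on every fit
stimulus that fires on a few held-out ones, whose unbounded negative
EV_j would otherwise corrupt even the self-comparison EV(X, X). The
headline number is the mean of the two directional means.

The held-out split is essential: with M comparable to n, in-sample EV
approaches 1 for any pair. Calibration (tested): EV(X, X) = 1 to 1e−9;
EV(X, XA + c) = 1 to 1e−6 for full-rank A; independent Gaussian
matrices at n = 5000 score |EV| < 0.05. Invariance: the directional EV
*from* a representation is invariant under any full-rank affine
re-expression of it (the map composes with the fit), and the full
headline is invariant under per-neuron gain/offset changes. The
headline is *not* invariant under full-rank mixing of the target side —
per-neuron normalization is not basis-free — which is inherent to the
per-neuron EV convention, not a defect of the implementation.

**Selectivity.** Neuron selectivity is the Pearson kurtosis (m₄/m₂²,
Gaussian = 3; excess available by flag) of the response distribution
over stimuli, following the sparseness literature; either convention
ranks neurons identically. Zero-variance neurons have undefined
selectivity and rank last.

## Experiment drivers

All four analyses share one EV split seed, evaluate both networks on
identical stimuli (one noisy dataset per σ; one subsample per draw), and
gate on the similar-performance criterion |acc₁ − acc₂| ≤ 0.05 before
any EV is computed. "Correctly categorized" means correct by *both*
networks (so both representations are evaluated on a common stimulus
set); correct-by-either or by one network are available by flag. The
size grid defaults to ten equal steps up to the pool size, and the
selectivity grid to the top 10%…100% in steps of 10 (selected indices
sorted ascending). Degenerate grid points — σ = 0, 100% of neurons,
the full-pool size — therefore traverse byte-identical code paths and
reproduce the standard all-inputs EV exactly, which the tests assert
bitwise. Reports serialize as CSV plus a provenance JSON (configs,
seeds, parameter and data checksums) sufficient to reproduce every row;
plots are best-effort and never fail a run.

Resamples per size default to 10. The sd of EV across resamples is
itself an estimate with visible noise at this resample count; the
stabilization property is accordingly checked at the endpoints (largest
vs smallest size, with at most one intermediate excursion), not as
pairwise monotonicity of the sd sequence.

## Interfaces

The package is a library: the importable API plus the narrated scripts
under `examples/` are the intended interface, and `scripts/acceptance.py`
re-runs the full pipeline headlessly. Datasets interchange as PNG
directories with a CSV manifest and JSON sidecar; networks checkpoint to
a single `.npz` with the architecture and seed embedded plus a JSON
summary; configs round-trip through YAML.

## Known limitations

- The engine is CPU/numpy only; the full-scale column architectures
  parse and run but training them to convergence is out of desk scope.
- Exact run-to-run reproducibility is guaranteed on a fixed platform;
  across BLAS implementations, floating-point sums may differ in the
  last bits.
- The generator's easy class structure keeps accuracies at ceiling, so
  behavioral *similarity* gates are trivially passed at reference
  conditions; harder conditions (lower contrast, higher noise) are one
  config away but not part of the shipped defaults.
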