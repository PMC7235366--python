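"""Linear-map equivalence between representations, measured by explained variance.

Two representations of the same stimuli count as *the same* when one is an
affine transform of the other.  The working measure is explained variance
(EV): fit an affine map from source to target on half the stimuli, then on
the held-out half score, per target neuron,

    EV_j = 1 - SS_res,j / SS_tot,j

with SS_tot about the held-out mean.  EV = 1 iff the relation is affine on
the evaluated stimuli; independent representations score near 0.  The map
is fit in both directions and the headline number is the average of the
two directional means — the fitted direction is an arbitrary choice, the
symmetrized mean is not.

The held-out split matters: with M comparable to n, in-sample EV tends to
1 for *any* pair, which would make the measure vacuous.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RepresentationMatrix",
    "LinearMapFit",
    "EVReport",
    "fit_linear_map",
    "explained_variance",
    "ev_between_neuron_subsets",
    "selectivity_profile",
    "rank_by_selectivity",
    "top_fraction_indices",
]

_ZERO_VAR_TOL = 1e-12


@dataclass
class RepresentationMatrix:
    """n x M matrix of penultimate activations for an ordered stimulus set."""

    values: np.ndarray
    stimulus_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_stimuli, n_neurons) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("representation contains non-finite entries")
        if self.stimulus_ids is None:
            self.stimulus_ids = np.arange(len(self.values))
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if len(self.stimulus_ids) != len(self.values):
            raise ValueError("stimulus_ids length must match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def subset_neurons(self, idx: np.ndarray) -> "RepresentationMatrix":
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError("neuron subset must be non-empty")
        return RepresentationMatrix(
            values=self.values[:, idx], stimulus_ids=self.stimulus_ids
        )


@dataclass
class LinearMapFit:
    """An affine map (M_s + 1) x M_t with the stimulus split used to fit it."""

    coef: np.ndarray  # M_s x M_t
    intercept: np.ndarray  # M_t
    fit_idx: np.ndarray
    eval_idx: np.ndarray
    ridge: float
    warnings: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


@dataclass
class EVReport:
    """Explained variance between two representations.

    ``headline_mean_ev`` is the average of the two directional mean EVs;
    per-neuron values are held-out EVs of the *target* side of each
    direction, with zero-variance evaluation neurons excluded from the
    means (their count is logged).
    """

    per_neuron_ev_src_to_tgt: np.ndarray
    per_neuron_ev_tgt_to_src: np.ndarray
    mean_ev_src_to_tgt: float
    mean_ev_tgt_to_src: float
    headline_mean_ev: float
    fit_fraction: float
    ridge: float
    n_stimuli: int
    seed: int
    excluded_zero_variance: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "headline_mean_ev": self.headline_mean_ev,
            "mean_ev_src_to_tgt": self.mean_ev_src_to_tgt,
            "mean_ev_tgt_to_src": self.mean_ev_tgt_to_src,
            "fit_fraction": self.fit_fraction,
            "ridge": self.ridge,
            "n_stimuli": self.n_stimuli,
            "seed": self.seed,
            "excluded_zero_variance": self.excluded_zero_variance,
        }


def _check_aligned(source: RepresentationMatrix, target: RepresentationMatrix) -> None:
    if source.n != target.n or not np.array_equal(
        source.stimulus_ids, target.stimulus_ids
    ):
        raise ValueError("source and target stimulus_ids are not aligned")


def _split(n: int, fit_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_fit = int(round(n * fit_fraction))
    n_fit = min(max(n_fit, 1), n - 1)
    return np.sort(perm[:n_fit]), np.sort(perm[n_fit:])


def _solve_affine(
    X: np.ndarray, Y: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine map X -> Y; minimum-norm when underdetermined."""
    Xa = np.hstack([X, np.ones((len(X), 1))])
    if ridge > 0:
        # Intercept column left unpenalized.
        A = Xa.T @ Xa + ridge * np.diag([1.0] * X.shape[1] + [0.0])
        B = np.linalg.solve(A, Xa.T @ Y)
    else:
        B, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
    return B[:-1], B[-1]


def fit_linear_map(
    source: RepresentationMatrix,
    target: RepresentationMatrix,
    fit_fraction: float = 0.5,
    ridge: float = 0.0,
    seed: int = 0,
) -> LinearMapFit:
    """Fit an affine map from source to target on a seeded stimulus split.

    The fit minimizes squared error on the fit split (minimum-norm
    solution when underdetermined); a warning is attached when the fit
    split is smaller than M_s + 1, where the in-sample solution is exact
    and held-out evaluation is the only meaningful score.
    """
    _check_aligned(source, target)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    fit_idx, eval_idx = _split(source.n, fit_fraction, seed)
    warns: list[str] = []
    if len(fit_idx) < source.M + 1:
        warns.append(
            f"underdetermined fit: {len(fit_idx)} fit stimuli for "
            f"{source.M} source neurons; returning the minimum-norm map"
        )
        _warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
    coef, intercept = _solve_affine(
        source.values[fit_idx], target.values[fit_idx], ridge
    )
    return LinearMapFit(
        coef=coef,
        intercept=intercept,
        fit_idx=fit_idx,
        eval_idx=eval_idx,
        ridge=ridge,
        warnings=warns,
    )


def _directional_ev(
    source: RepresentationMatrix,
    target: RepresentationMatrix,
    fit_idx: np.ndarray,
    eval_idx: np.ndarray,
    ridge: float,
) -> tuple[np.ndarray, float, int]:
    coef, intercept = _solve_affine(
        source.values[fit_idx], target.values[fit_idx], ridge
    )
    Yhat = source.values[eval_idx] @ coef + intercept
    Y = target.values[eval_idx]
    ss_res = ((Y - Yhat) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    ev = np.full(Y.shape[1], np.nan)
    # Target neurons silent on either split are excluded from the mean:
    # zero eval variance makes EV undefined, and zero fit variance makes
    # the neuron unfittable (typically a ReLU unit dead on the fit split
    # that fires on a handful of held-out stimuli).
    fit_var = target.values[fit_idx].var(axis=0)
    ok = (ss_tot > _ZERO_VAR_TOL) & (fit_var > _ZERO_VAR_TOL)
    ev[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    n_excluded = int((~ok).sum())
    mean_ev = float(ev[ok].mean()) if ok.any() else np.nan
    return ev, mean_ev, n_excluded


def explained_variance(
    source: RepresentationMatrix,
    target: RepresentationMatrix,
    fit_fraction: float = 0.5,
    ridge: float = 0.0,
    seed: int = 0,
) -> EVReport:
    """Symmetrized held-out explained variance between two representations.

    One seeded stimulus split serves both directions.  Negative per-neuron
    EVs (fits worse than the held-out mean) are retained, not clipped.
    Raises if fewer than 3 stimuli land in the evaluation split.
    """
    _check_aligned(source, target)
    fit_idx, eval_idx = _split(source.n, fit_fraction, seed)
    if len(eval_idx) < 3:
        raise ValueError(
            f"only {len(eval_idx)} evaluation stimuli; need at least 3"
        )
    warns: list[str] = []
    if len(fit_idx) < source.M + 1 or len(fit_idx) < target.M + 1:
        warns.append(
            f"underdetermined fit: {len(fit_idx)} fit stimuli for "
            f"{max(source.M, target.M)} neurons"
        )
    ev_st, mean_st, exc_st = _directional_ev(source, target, fit_idx, eval_idx, ridge)
    ev_ts, mean_ts, exc_ts = _directional_ev(target, source, fit_idx, eval_idx, ridge)
    return EVReport(
        per_neuron_ev_src_to_tgt=ev_st,
        per_neuron_ev_tgt_to_src=ev_ts,
        mean_ev_src_to_tgt=mean_st,
        mean_ev_tgt_to_src=mean_ts,
        headline_mean_ev=float((mean_st + mean_ts) / 2.0),
        fit_fraction=fit_fraction,
        ridge=ridge,
        n_stimuli=source.n,
        seed=seed,
        excluded_zero_variance=exc_st + exc_ts,
        warnings=warns,
    )


def ev_between_neuron_subsets(
    source: RepresentationMatrix,
    target: RepresentationMatrix,
    idx_source: np.ndarray,
    idx_target: np.ndarray,
    fit_fraction: float = 0.5,
    ridge: float = 0.0,
    seed: int = 0,
) -> EVReport:
    """Explained variance restricted to chosen neuron columns on each side."""
    return explained_variance(
        source.subset_neurons(idx_source),
        target.subset_neurons(idx_target),
        fit_fraction=fit_fraction,
        ridge=ridge,
        seed=seed,
    )


def selectivity_profile(
    rep: RepresentationMatrix, excess: bool = False
) -> np.ndarray:
    """Per-neuron kurtosis of the response distribution over stimuli.

    Pearson convention by default (m4 / m2^2; Gaussian responses score 3),
    following the sparseness literature; ``excess=True`` subtracts 3.
    Zero-variance neurons get NaN (selectivity undefined) and rank last.
    Requires at least 4 stimuli.
    """
    if rep.n < 4:
        raise ValueError(f"kurtosis needs n >= 4 stimuli, got {rep.n}")
    var = rep.values.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant neurons are flagged explicitly below; suppress the
        # precision-loss warning their zero variance triggers
        _warnings.simplefilter("ignore", RuntimeWarning)
        kurt = stats.kurtosis(rep.values, axis=0, fisher=excess, bias=True)
    kurt = np.asarray(kurt, dtype=np.float64)
    kurt[var <= _ZERO_VAR_TOL] = np.nan
    return kurt


def rank_by_selectivity(kurtosis_values: np.ndarray) -> np.ndarray:
    """Neuron indices sorted most- to least-selective; NaNs last.

    Ties and the NaN tail are ordered by neuron index, so the ranking is
    deterministic.
    """
    k = np.asarray(kurtosis_values, dtype=np.float64)
    key = np.where(np.isnan(k), -np.inf, k)
    return np.lexsort((np.arange(len(k)), -key))


def top_fraction_indices(kurtosis_values: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the top-``fraction`` most selective neurons, ascending.

    The count is ``ceil(fraction * M)`` so every non-zero fraction selects
    at least one neuron.  Indices are returned sorted ascending: column
    order carries no meaning for the EV computation, and a sorted full
    selection is exactly the identity.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    order = rank_by_selectivity(kurtosis_values)
    count = int(np.ceil(fraction * len(order)))
    return np.sort(order[:count])
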