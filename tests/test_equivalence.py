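"""Calibration and null behavior of the explained-variance measure."""

import numpy as np
import pytest

from repnonuniq.equivalence import (
    RepresentationMatrix,
    ev_between_neuron_subsets,
    explained_variance,
    fit_linear_map,
    rank_by_selectivity,
    selectivity_profile,
    top_fraction_indices,
)


def _gauss(n, m, seed):
    return RepresentationMatrix(np.random.default_rng(seed).normal(size=(n, m)))


class TestFitLinearMap:
    def test_identity_recovery(self):
        X = _gauss(400, 16, 0)
        fit = fit_linear_map(X, X, seed=1)
        np.testing.assert_allclose(fit.coef, np.eye(16), atol=1e-8)
        np.testing.assert_allclose(fit.intercept, 0, atol=1e-8)

    def test_exact_affine_relation(self):
        rng = np.random.default_rng(2)
        X = _gauss(400, 16, 0)
        A, c = rng.normal(size=(16, 16)), rng.normal(size=16)
        Y = RepresentationMatrix(X.values @ A + c)
        fit = fit_linear_map(X, Y, seed=1)
        resid = np.abs(fit.predict(X.values[fit.eval_idx]) - Y.values[fit.eval_idx])
        assert resid.max() < 1e-6 * np.abs(Y.values).max()

    def test_underdetermined_warns_and_returns_min_norm(self):
        X = _gauss(20, 64, 3)
        with pytest.warns(RuntimeWarning, match="underdetermined"):
            fit = fit_linear_map(X, X, seed=0)
        assert fit.warnings
        # minimum-norm fit is still exact on the fit split
        resid = fit.predict(X.values[fit.fit_idx]) - X.values[fit.fit_idx]
        assert np.abs(resid).max() < 1e-8

    def test_misaligned_ids_rejected(self):
        X = _gauss(50, 4, 0)
        Y = RepresentationMatrix(X.values.copy(), stimulus_ids=np.arange(50) + 1)
        with pytest.raises(ValueError, match="aligned"):
            fit_linear_map(X, Y)


class TestExplainedVariance:
    def test_self_ev_is_one(self):
        X = _gauss(500, 16, 4)
        ev = explained_variance(X, X, seed=0)
        assert abs(ev.headline_mean_ev - 1.0) < 1e-9

    def test_affine_image_ev_is_one(self):
        rng = np.random.default_rng(5)
        X = _gauss(500, 16, 4)
        Y = RepresentationMatrix(X.values @ rng.normal(size=(16, 16)) + rng.normal(size=16))
        ev = explained_variance(X, Y, seed=0)
        assert abs(ev.headline_mean_ev - 1.0) < 1e-6

    def test_independent_null_near_zero(self):
        evs = [
            explained_variance(
                _gauss(5000, 64, 2 * s), _gauss(5000, 64, 2 * s + 1), seed=s
            ).headline_mean_ev
            for s in range(10)
        ]
        assert max(abs(v) for v in evs) < 0.05

    def test_null_concentrates_with_stimulus_count(self):
        """Held-out EV between independent matrices is biased negative at
        small n (few eval stimuli per predictor) and shrinks toward 0 as
        the stimulus count grows."""
        def null_ev(n, s):
            return explained_variance(
                _gauss(n, 64, 30 + 2 * s), _gauss(n, 64, 31 + 2 * s), seed=s
            ).headline_mean_ev

        small = np.mean([abs(null_ev(500, s)) for s in range(3)])
        large = np.mean([abs(null_ev(5000, s)) for s in range(3)])
        assert large < small

    def test_nonlinear_relation_below_one(self):
        rng = np.random.default_rng(6)
        X = _gauss(2000, 16, 7)
        Y = RepresentationMatrix(np.tanh(X.values @ rng.normal(size=(16, 16))))
        ev = explained_variance(X, Y, seed=0)
        assert ev.headline_mean_ev < 0.99

    def test_source_side_invariance_under_full_rank_mixing(self):
        """The directional EV onto a fixed target is unchanged when the
        source is replaced by any full-rank affine image of itself (the
        affine map composes with the fitted map)."""
        rng = np.random.default_rng(8)
        X, Y = _gauss(1000, 12, 9), _gauss(1000, 12, 10)
        B, c = rng.normal(size=(12, 12)), rng.normal(size=12)
        ev1 = explained_variance(X, Y, seed=3).mean_ev_src_to_tgt
        ev2 = explained_variance(
            RepresentationMatrix(X.values @ B + c), Y, seed=3
        ).mean_ev_src_to_tgt
        assert abs(ev1 - ev2) < 1e-6

    def test_headline_invariance_under_neuron_gain_offset(self):
        """Re-expressing either representation in different per-neuron
        units (gain + baseline shift) leaves the headline EV unchanged:
        per-neuron SS ratios are scale-free."""
        rng = np.random.default_rng(28)
        X, Y = _gauss(1000, 12, 9), _gauss(1000, 12, 10)
        gains = rng.uniform(0.1, 5.0, size=12) * rng.choice([-1, 1], size=12)
        offsets = rng.normal(size=12)
        ev1 = explained_variance(X, Y, seed=3).headline_mean_ev
        ev2 = explained_variance(
            RepresentationMatrix(X.values * gains + offsets), Y, seed=3
        ).headline_mean_ev
        assert abs(ev1 - ev2) < 1e-6

    def test_headline_is_mean_of_directions(self):
        X, Y = _gauss(300, 8, 11), _gauss(300, 8, 12)
        ev = explained_variance(X, Y, seed=0)
        assert ev.headline_mean_ev == pytest.approx(
            (ev.mean_ev_src_to_tgt + ev.mean_ev_tgt_to_src) / 2, abs=1e-15
        )
        assert np.nanmax(ev.per_neuron_ev_src_to_tgt) <= 1 + 1e-9

    def test_zero_variance_neurons_excluded(self):
        X = _gauss(200, 6, 13)
        vals = X.values.copy()
        vals[:, 2] = 7.0  # constant neuron
        ev = explained_variance(X, RepresentationMatrix(vals), seed=0)
        assert ev.excluded_zero_variance >= 1
        assert np.isnan(ev.per_neuron_ev_src_to_tgt[2])

    def test_too_few_eval_stimuli_rejected(self):
        X = _gauss(4, 3, 14)
        with pytest.raises(ValueError, match="at least 3"):
            explained_variance(X, X, fit_fraction=0.75, seed=0)

    def test_ridge_recorded(self):
        X = _gauss(100, 4, 15)
        ev = explained_variance(X, X, ridge=0.5, seed=0)
        assert ev.ridge == 0.5


class TestNeuronSubsets:
    def test_full_subsets_reproduce_explained_variance(self):
        X, Y = _gauss(400, 10, 16), _gauss(400, 10, 17)
        full = explained_variance(X, Y, seed=1)
        sub = ev_between_neuron_subsets(
            X, Y, np.arange(10), np.arange(10), seed=1
        )
        assert sub.headline_mean_ev == full.headline_mean_ev

    def test_single_neuron_subsets(self):
        X, Y = _gauss(200, 5, 18), _gauss(200, 5, 19)
        sub = ev_between_neuron_subsets(X, Y, np.array([2]), np.array([4]), seed=0)
        assert len(sub.per_neuron_ev_src_to_tgt) == 1
        assert len(sub.per_neuron_ev_tgt_to_src) == 1

    def test_disjoint_null_subsets_near_zero(self):
        X, Y = _gauss(5000, 40, 20), _gauss(5000, 40, 21)
        sub = ev_between_neuron_subsets(
            X, Y, np.arange(4), np.arange(4, 8), seed=0
        )
        assert abs(sub.headline_mean_ev) < 0.1

    def test_empty_subset_rejected(self):
        X = _gauss(50, 4, 22)
        with pytest.raises(ValueError, match="non-empty"):
            ev_between_neuron_subsets(X, X, np.array([], dtype=int), np.arange(4))


class TestSelectivity:
    def test_gaussian_kurtosis_near_three(self):
        rep = _gauss(100_000, 5, 23)
        k = selectivity_profile(rep)
        assert np.all(np.abs(k - 3.0) < 0.1)

    def test_excess_convention(self):
        rep = _gauss(100_000, 3, 24)
        np.testing.assert_allclose(
            selectivity_profile(rep, excess=True), selectivity_profile(rep) - 3
        )

    def test_constant_neuron_undefined_and_ranked_last(self):
        vals = np.random.default_rng(25).normal(size=(100, 4))
        vals[:, 1] = 2.0
        k = selectivity_profile(RepresentationMatrix(vals))
        assert np.isnan(k[1])
        assert rank_by_selectivity(k)[-1] == 1

    def test_sparse_spike_matches_direct_formula(self):
        """99 zeros + one spike of 10: compare against the raw moment ratio."""
        v = np.zeros(100)
        v[0] = 10.0
        m2 = np.mean((v - v.mean()) ** 2)
        m4 = np.mean((v - v.mean()) ** 4)
        expected = m4 / m2**2
        rep = RepresentationMatrix(np.tile(v[:, None], (1, 2)))
        np.testing.assert_allclose(selectivity_profile(rep), expected)

    def test_minimum_stimulus_count(self):
        with pytest.raises(ValueError, match="n >= 4"):
            selectivity_profile(_gauss(3, 2, 26))

    def test_top_fraction_selection(self):
        k = np.array([1.0, 5.0, 3.0, np.nan])
        assert list(top_fraction_indices(k, 0.5)) == [1, 2]
        assert list(top_fraction_indices(k, 1.0)) == [0, 1, 2, 3]
        with pytest.raises(ValueError):
            top_fraction_indices(k, 0.0)
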