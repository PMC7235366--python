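"""Monotone-transform invariance and the pseudo-inverse counterexample."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repnonuniq.nets import ClassifierHead, build_network, parse_architecture
from repnonuniq.propositions import (
    apply_transform,
    categorization_agreement,
    construct_counterpart_representation,
    get_transform,
    pinv_preimage,
    random_full_row_rank_head,
    register_transform,
    softmax,
)
from repnonuniq.synthdata import LabeledImageSet

finite_logits = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=2, max_size=12
)


class TestSoftmax:
    def test_uniform_on_equal_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(4)), 0.25)

    def test_closed_form(self):
        np.testing.assert_allclose(
            softmax(np.array([np.log(2), 0.0])), [2 / 3, 1 / 3], atol=1e-12
        )

    @given(finite_logits, st.floats(-100, 100, allow_nan=False))
    def test_shift_invariance(self, v, c):
        v = np.array(v)
        np.testing.assert_allclose(softmax(v + c), softmax(v), atol=1e-12)
        assert abs(softmax(v).sum() - 1) < 1e-12

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.inf, 0.0]))


class TestTransforms:
    def test_signed_square_values(self):
        out = apply_transform("signed_square", np.array([2.0, -2.0, 0.0]))
        np.testing.assert_array_equal(out, [4.0, -4.0, 0.0])

    def test_identity(self):
        v = np.array([1.0, -3.0, 2.5])
        np.testing.assert_array_equal(apply_transform("identity", v), v)

    def test_decreasing_map_rejected(self):
        with pytest.raises(ValueError, match="not strictly increasing"):
            register_transform("neg", lambda x: -x)

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError, match="not strictly increasing"):
            register_transform("square", lambda x: x**2)

    def test_unregistered_lookup_fails(self):
        with pytest.raises(KeyError):
            get_transform("no_such_map")


class TestAgreement:
    def test_cube_preserves_argmax(self):
        assert categorization_agreement([3, 1, 2], [27, 1, 8], k=1)

    def test_negation_moves_argmax(self):
        assert not categorization_agreement([3, 1, 2], [-3, -1, -2], k=1)

    def test_topk_bounds(self):
        with pytest.raises(ValueError):
            categorization_agreement([1, 2], [1, 2], k=2)

    @given(
        # well-separated logits: distinct on a 0.1 grid, so no transform
        # can collapse two of them to the same float
        st.lists(
            st.integers(-300, 300), min_size=4, max_size=10, unique=True
        ),
        st.sampled_from(["signed_square", "cube", "exp", "affine"]),
        st.sampled_from([1, 3]),
    )
    def test_monotone_maps_preserve_topk(self, v, fname, k):
        """Any registered increasing map leaves every Top-K set unchanged."""
        x = np.array(v) / 10.0
        y = apply_transform(fname, x)
        assert categorization_agreement(x, y, k=k)

    def test_randomized_exhaustive_all_sizes(self):
        rng = np.random.default_rng(7)
        for N in (2, 10, 100):
            X = rng.normal(size=(500, N)) * 3
            for fname in ("signed_square", "cube", "exp"):
                Y = apply_transform(fname, X)
                for k in (1, 3):
                    if k >= N:
                        continue
                    assert all(
                        categorization_agreement(x, y, k)
                        for x, y in zip(X, Y)
                    )


class TestPinvPreimage:
    def test_minimum_norm_closed_form(self):
        head = ClassifierHead(W=np.array([[1.0, 0.0]]), b=np.array([0.0]))
        v, res, warns = pinv_preimage(head, np.array([5.0]))
        np.testing.assert_allclose(v, [5.0, 0.0], atol=1e-12)
        assert res < 1e-12 and not warns

    def test_exactness_vs_lstsq_oracle(self):
        """Minimum-norm preimage matches a generic least-squares solve."""
        worst_res, worst_gap = 0.0, 0.0
        for s in range(50):
            head = random_full_row_rank_head(64, 10, rng=s)
            t = np.random.default_rng(1000 + s).normal(size=10) * 5
            v, res, _ = pinv_preimage(head, t)
            oracle, *_ = np.linalg.lstsq(head.W, t - head.b, rcond=None)
            worst_res = max(worst_res, res)
            worst_gap = max(worst_gap, float(np.abs(v - oracle).max()))
        assert worst_res < 1e-8
        assert worst_gap < 1e-8

    def test_zero_row_unreachable(self):
        W = np.zeros((2, 4))
        W[0, 0] = 1.0  # second row dead: logit 2 unreachable
        head = ClassifierHead(W=W, b=np.zeros(2))
        v, res, warns = pinv_preimage(head, np.array([1.0, 3.0]))
        assert res > 1.0
        assert warns  # near-rank-deficiency warning attached

    def test_requires_wide_head(self):
        head = ClassifierHead(W=np.eye(3), b=np.zeros(3))
        with pytest.raises(ValueError, match="M > N"):
            pinv_preimage(head, np.zeros(3))


@pytest.fixture(scope="module")
def tiny_net():
    spec = parse_architecture(["Fc-3", "Fc-2"], (2, 2, 1), 2)
    return build_network(spec, seed=0)


class TestCounterpart:

    def _stimuli(self, n=100, seed=1):
        rng = np.random.default_rng(seed)
        return LabeledImageSet(
            images=rng.uniform(size=(n, 2, 2, 1)),
            labels=rng.integers(0, 2, size=n),
            num_classes=2,
        )

    def test_head_output_matches_transformed_logits(self, tiny_net):
        """y' = f(x') to near machine precision for N=2, M=3."""
        head2 = random_full_row_rank_head(3, 2, rng=5)
        data = self._stimuli()
        _, ylog, _ = construct_counterpart_representation(
            tiny_net, "cube", head2, data
        )
        xlog = tiny_net.logits(data.images)
        assert np.max(np.abs(ylog - xlog**3)) < 1e-9

    def test_label_agreement_is_total(self, tiny_net):
        head2 = random_full_row_rank_head(3, 2, rng=6)
        data = self._stimuli(seed=2)
        _, _, preds_y = construct_counterpart_representation(
            tiny_net, "signed_square", head2, data
        )
        assert np.array_equal(preds_y, tiny_net.predict(data.images))

    def test_identity_transform_same_head_is_projection(self, tiny_net):
        """f = id, head2 = head1: y is the row-space projection of x."""
        head1 = tiny_net.head
        data = self._stimuli(seed=3)
        rep_y, _, _ = construct_counterpart_representation(
            tiny_net, "identity", head1, data
        )
        X = tiny_net.penultimate(data.images)
        P = np.linalg.pinv(head1.W) @ head1.W  # projection onto row space
        np.testing.assert_allclose(rep_y.values, X @ P.T, atol=1e-9)
        # a representation already in the row space is reproduced exactly
        X_in = X @ P.T
        Y2 = (
            apply_transform("identity", X_in @ head1.W.T + head1.b) - head1.b
        ) @ (np.linalg.pinv(head1.W.T @ head1.W) @ head1.W.T).T
        np.testing.assert_allclose(Y2, X_in, atol=1e-9)

    def test_rank_and_shape_preconditions(self, tiny_net):
        data = self._stimuli(seed=4)
        bad = ClassifierHead(W=np.zeros((2, 3)), b=np.zeros(2))
        with pytest.raises(ValueError, match="row rank"):
            construct_counterpart_representation(tiny_net, "cube", bad, data)
        narrow = ClassifierHead(W=np.eye(2), b=np.zeros(2))
        with pytest.raises(ValueError, match="M > N"):
            construct_counterpart_representation(tiny_net, "cube", narrow, data)
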