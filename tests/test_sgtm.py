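"""Core successive-geometric-transformations model: both modes."""

import numpy as np
import pytest

from sgtm_cascade import (
    InvalidInputError,
    NotFittedError,
    ShapeError,
    fit_supervised,
    fit_unsupervised,
    predict,
    reconstruct,
    transform,
)


def naive_pivoted_gram_schmidt(X, max_steps):
    """Independent row-by-row reference implementation (no vectorised projection)."""
    R = [row.astype(float).copy() for row in X]
    bases = []
    for _ in range(max_steps):
        norms = [np.sqrt(sum(v * v for v in row)) for row in R]
        b = int(np.argmax(norms))
        if norms[b] <= 1e-10 * max(np.linalg.norm(np.asarray(X), axis=1).max(), 1e-300):
            break
        d = R[b] / norms[b]
        bases.append(d)
        for i in range(len(R)):
            k = float(sum(R[i][j] * d[j] for j in range(len(d))))
            R[i] = R[i] - k * d
    return np.array(bases), np.array(R)


class TestUnsupervised:
    def test_orthogonal_rows_decompose_exactly(self):
        X = np.array([[3.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        model = fit_unsupervised(X, m="full", center=False)
        assert model.m == 2
        np.testing.assert_allclose(model.steps[0].base_direction, [1, 0], atol=1e-12)
        assert model.steps[0].base_norm == pytest.approx(3.0)
        np.testing.assert_allclose(model.steps[1].base_direction, [0, 1], atol=1e-12)
        assert model.steps[1].base_norm == pytest.approx(2.0)
        K = transform(model, X)
        np.testing.assert_allclose(reconstruct(model, K), X, atol=1e-12)

    def test_max_norm_tie_goes_to_lowest_row_index(self):
        model = fit_unsupervised(np.eye(2), m="full", center=False)
        assert model.steps[0].base_row_index == 0

    def test_full_rank_matrix_residual_vanishes(self, rng):
        X = rng.normal(size=(20, 5))
        model = fit_unsupervised(X, m="full")
        K = transform(model, X)
        np.testing.assert_allclose(reconstruct(model, K), X, atol=1e-9)

    def test_matches_naive_gram_schmidt_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        Xc = X - X.mean(axis=0)
        bases, residual = naive_pivoted_gram_schmidt(Xc, 5)
        model = fit_unsupervised(X, m="full")
        assert model.m == len(bases)
        for step, d_ref in zip(model.steps, bases):
            assert abs(step.base_direction @ d_ref) == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(residual)) <= 1e-9

    def test_transform_parseval_on_axis_aligned_model(self):
        model = fit_unsupervised(
            np.array([[3.0, 0.0], [0.0, 2.0], [0.0, 0.0]]), m="full", center=False
        )
        K = transform(model, np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(K, [[3.0, 4.0]])
        assert np.sum(K**2) == pytest.approx(25.0)

    def test_transform_reproduces_training_coefficients(self, rng):
        X = rng.normal(size=(12, 4))
        model = fit_unsupervised(X, m="full")
        K = transform(model, X)
        # step S of row base_row_index has coefficient equal to its base_norm
        for s, step in enumerate(model.steps):
            assert K[step.base_row_index, s] == pytest.approx(step.base_norm)

    def test_bessel_inequality_on_truncated_model(self, rng):
        X = rng.normal(size=(30, 6))
        model = fit_unsupervised(X, m=3)
        Y = rng.normal(size=(10, 6))
        K = transform(model, Y)
        lhs = np.sum(K**2, axis=1)
        rhs = np.sum((Y - model.input_means) ** 2, axis=1)
        assert np.all(lhs <= rhs + 1e-9)

    def test_reconstruct_zero_coefficients_gives_means(self, rng):
        X = rng.normal(size=(8, 3))
        model = fit_unsupervised(X, m="full")
        out = reconstruct(model, np.zeros((4, model.m)))
        np.testing.assert_allclose(out, np.tile(model.input_means, (4, 1)))

    def test_rank_deficient_matrix_records_fewer_steps(self, rng):
        base = rng.normal(size=(10, 2))
        X = base @ rng.normal(size=(2, 5))  # rank 2 in 5 columns
        model = fit_unsupervised(X, m="full")
        assert model.m == 2

    @pytest.mark.parametrize(
        "bad", [np.empty((0, 3)), np.array([[1.0, np.nan]]), np.array([[np.inf, 1.0]])]
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            fit_unsupervised(bad)

    def test_transform_shape_mismatch(self, rng):
        model = fit_unsupervised(rng.normal(size=(5, 3)))
        with pytest.raises(ShapeError):
            transform(model, rng.normal(size=(2, 4)))


class TestModelInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_orthonormal_directions_and_monotone_norms(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        for model in (fit_unsupervised(X, m="full"), fit_supervised(X, y, m="full")):
            D = model.directions
            G = D @ D.T
            np.testing.assert_allclose(np.diag(G), 1.0, atol=1e-12)
            off = G - np.diag(np.diag(G))
            assert np.max(np.abs(off)) <= 1e-8
            norms = [s.base_norm for s in model.steps]
            assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_fit_is_deterministic(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=30)
        m1 = fit_supervised(X, y)
        m2 = fit_supervised(X, y)
        assert len(m1.steps) == len(m2.steps)
        for a, b in zip(m1.steps, m2.steps):
            assert np.array_equal(a.base_direction, b.base_direction)
            assert a.alpha == b.alpha
            assert a.base_row_index == b.base_row_index


class TestSupervised:
    def test_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(20, 3))
        model = fit_supervised(X, np.full(20, 4.25))
        pred = predict(model, rng.normal(size=(7, 3)))
        np.testing.assert_allclose(pred, 4.25, atol=1e-10)

    def test_zero_steps_is_mean_predictor(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit_supervised(X, y, m=0)
        pred = predict(model, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(pred, np.mean(y), atol=1e-12)

    def test_zero_variance_augmented_matrix_gives_mean_model(self):
        X = np.ones((6, 2))
        y = np.full(6, 3.0)
        model = fit_supervised(X, y)
        assert model.m == 0
        np.testing.assert_allclose(predict(model, np.ones((2, 2))), 3.0)

    def test_noiseless_linear_target_recovered_exactly(self, rng):
        X = rng.uniform(-1, 1, size=(500, 5))
        w = rng.normal(size=5)
        y = X @ w + 1.7
        model = fit_supervised(X, y, m="full")
        Xt = rng.uniform(-1, 1, size=(200, 5))
        pred = predict(model, Xt)[:, 0]
        truth = Xt @ w + 1.7
        ss_res = np.sum((pred - truth) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999
        np.testing.assert_allclose(pred, truth, atol=1e-9)

    def test_noisy_linear_matches_ols_oracle(self, rng):
        X = rng.uniform(-1, 1, size=(500, 5))
        w = rng.normal(size=5)
        y = X @ w + rng.normal(0, 0.1, size=500)
        Xt = rng.uniform(-1, 1, size=(200, 5))
        yt = Xt @ w + rng.normal(0, 0.1, size=200)
        model = fit_supervised(X, y, m="full")
        rmse = np.sqrt(np.mean((predict(model, Xt)[:, 0] - yt) ** 2))
        A = np.column_stack([X, np.ones(500)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_rmse = np.sqrt(
            np.mean((np.column_stack([Xt, np.ones(200)]) @ beta - yt) ** 2)
        )
        assert rmse <= 1.10 * ols_rmse

    def test_predict_matches_naive_hand_trace(self, rng):
        X = rng.uniform(-1, 1, size=(60, 4))
        y = X @ rng.normal(size=4) + 0.3 * X[:, 0] ** 2 + rng.normal(0, 0.05, 60)
        model = fit_supervised(X, y, m="full")
        for row in rng.uniform(-1, 1, size=(3, 4)):
            r = row - model.input_means
            acc = float(model.output_means[0])
            for step in model.steps:
                din = step.base_direction[:4]
                nin = float(din @ din)
                if nin <= 1e-12:
                    continue
                kin = float(r @ din) / nin
                acc += step.alpha * kin * float(step.base_direction[4])
                r = r - kin * din
            got = predict(model, row[None, :])[0, 0]
            assert got == pytest.approx(acc, abs=1e-12)

    def test_output_orthogonal_step_contributes_nothing(self, rng):
        # a direction with zero output part cannot move the prediction
        X = rng.normal(size=(15, 3))
        y = np.full(15, 2.0)  # constant: every direction has zero output part
        model = fit_supervised(X, y, m="full")
        for step in model.steps:
            assert abs(step.base_direction[-1]) < 1e-12
        np.testing.assert_allclose(predict(model, X), 2.0, atol=1e-10)

    def test_errors(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(InvalidInputError):
            fit_supervised(X, np.array([np.nan] * 10))
        with pytest.raises(ShapeError):
            fit_supervised(X, np.zeros(7))
        model = fit_unsupervised(X)
        with pytest.raises(NotFittedError):
            predict(model, X)
        sup = fit_supervised(X, rng.normal(size=10))
        with pytest.raises(ShapeError):
            predict(sup, rng.normal(size=(2, 5)))
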