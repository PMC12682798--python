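"""Graph operators, Chebyshev filters, losses, normalizations, training.

The backward pass has no autodiff engine behind it, so the parameter and input
gradients are checked against central finite differences, and the Chebyshev
recursion against an explicit matrix-polynomial oracle built from the
polynomial coefficients of numpy.polynomial.chebyshev.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial import chebyshev as npcheb

from gradconn import (
    ChebNetRegressor,
    GCNConfig,
    TrainingBatch,
    build_graph_operator,
    chebyshev_features,
    inverse_minmax_iq,
    minmax_iq,
    precompute_graphs,
    siamese_loss,
    total_loss,
    train_model,
    zscore_by_hemisphere,
)
from gradconn.connectome import ConnectomeMatrix, ParcellationInfo
from gradconn.gcn import GCNError, _loss_grad, chebyshev_basis

from conftest import random_connected_adjacency


def explicit_chebyshev_matrix(lt: np.ndarray, k: int) -> np.ndarray:
    """T_k(Ltilde) via the monomial coefficients of the k-th Chebyshev basis."""
    coeffs = npcheb.cheb2poly([0] * k + [1])
    out = np.zeros_like(lt)
    power = np.eye(lt.shape[0])
    for c in coeffs:
        out += c * power
        power = power @ lt
    return out


class TestGraphOperator:
    def test_two_node_hand_example(self):
        op = build_graph_operator(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(op.laplacian, [[1.0, -1.0], [-1.0, 1.0]])
        assert op.lambda_max == pytest.approx(2.0)
        np.testing.assert_allclose(
            op.scaled_laplacian, [[0.0, -1.0], [-1.0, 0.0]], atol=1e-12
        )
        evals = np.linalg.eigvalsh(op.laplacian)
        np.testing.assert_allclose(np.sort(evals), [0.0, 2.0], atol=1e-12)

    def test_complete_graph_nullspace_is_constant(self):
        a = np.ones((5, 5)) - np.eye(5)
        op = build_graph_operator(a)
        evals, evecs = np.linalg.eigh(op.laplacian)
        assert evals[0] == pytest.approx(0.0, abs=1e-12)
        v = evecs[:, 0]
        np.testing.assert_allclose(v / v[0], np.ones(5), atol=1e-10)

    def test_spectra_bounds_on_random_graphs(self, rng):
        for _ in range(5):
            a = random_connected_adjacency(rng, 8)
            op = build_graph_operator(a)
            lap_evals = np.linalg.eigvalsh(op.laplacian)
            scaled_evals = np.linalg.eigvalsh(op.scaled_laplacian)
            assert lap_evals.min() >= -1e-10 and lap_evals.max() <= 2 + 1e-10
            assert scaled_evals.min() >= -1 - 1e-10
            assert scaled_evals.max() <= 1 + 1e-10

    def test_zero_degree_node_error_names_region(self):
        parc = ParcellationInfo(
            region_ids=("L_x", "L_dead", "R_x", "R_y"),
            hemisphere=("L", "L", "R", "R"),
        )
        a = np.ones((4, 4)) - np.eye(4)
        a[1, :] = 0.0
        a[:, 1] = 0.0
        conn = ConnectomeMatrix(values=a, parcellation=parc)
        with pytest.raises(GCNError, match="L_dead"):
            build_graph_operator(conn)


class TestChebyshevFeatures:
    def test_order_zero_is_identity(self, rng):
        h = rng.normal(size=(6, 2))
        lt = np.zeros((6, 6))
        out = chebyshev_features(lt, h, 0)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0], h)

    def test_order_two_matches_explicit_polynomial(self, rng):
        a = random_connected_adjacency(rng, 4)
        lt = build_graph_operator(a).scaled_laplacian
        h = rng.normal(size=(4, 2))
        out = chebyshev_features(lt, h, 2)
        np.testing.assert_allclose(
            out[2], (2 * lt @ lt - np.eye(4)) @ h, atol=1e-12
        )

    def test_identity_laplacian_fixes_features(self, rng):
        h = rng.normal(size=(5, 3))
        out = chebyshev_features(np.eye(5), h, 4)
        for t in out:
            np.testing.assert_allclose(t, h, atol=1e-12)  # T_k(1) = 1

    def test_recursion_matches_matrix_polynomial_oracle(self, rng):
        for n, kmax in ((6, 5), (10, 4)):
            a = random_connected_adjacency(rng, n)
            lt = build_graph_operator(a).scaled_laplacian
            h = rng.normal(size=(n, 3))
            out = chebyshev_features(lt, h, kmax)
            for k in range(kmax + 1):
                np.testing.assert_allclose(
                    out[k], explicit_chebyshev_matrix(lt, k) @ h, atol=1e-8
                )

    def test_stacked_basis_consistent_with_features(self, rng):
        a = random_connected_adjacency(rng, 5)
        lt = build_graph_operator(a).scaled_laplacian
        basis = chebyshev_basis(lt, 3)
        h = rng.normal(size=(5, 2))
        stacked = basis @ h
        feats = chebyshev_features(lt, h, 3)
        for k in range(4):
            np.testing.assert_allclose(stacked[5 * k : 5 * (k + 1)], feats[k])


class TestLosses:
    def test_siamese_toy_value(self):
        assert siamese_loss([1.0, 2.0], [1.0, 3.0]) == pytest.approx(2.0)

    def test_siamese_matches_double_loop_oracle(self, rng):
        y = rng.normal(size=5)
        f = rng.normal(size=5)
        brute = 0.0
        for i in range(5):
            for j in range(5):
                if i != j:
                    brute += ((y[i] - y[j]) - (f[i] - f[j])) ** 2
        assert siamese_loss(y, f) == pytest.approx(brute)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        st.floats(-100, 100),
    )
    def test_siamese_shift_invariance(self, y, c):
        f = [v + 1.0 for v in y]
        assert siamese_loss(y, f) == pytest.approx(0.0, abs=1e-8)
        f2 = [v * 0.5 + 2.0 for v in y]
        assert siamese_loss(y, f2) == pytest.approx(
            siamese_loss(y, [v + c for v in f2]), rel=1e-6, abs=1e-6
        )

    def test_siamese_zero_iff_constant_residual(self, rng):
        y = rng.normal(size=4)
        assert siamese_loss(y, y + 3.3) == pytest.approx(0.0, abs=1e-10)
        f = y.copy()
        f[0] += 0.1
        assert siamese_loss(y, f) > 0

    def test_siamese_single_subject_warns_zero(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert siamese_loss([1.0], [5.0]) == 0.0

    def test_total_loss_components(self):
        assert total_loss([1.0, 2.0], [1.0, 2.0], 10.0) == 0.0
        assert total_loss([1.0, 2.0], [1.0, 3.0], 10.0) == pytest.approx(21.0)
        y, f = [1.0, 2.0, 4.0], [1.5, 1.0, 3.0]
        sse = sum((a - b) ** 2 for a, b in zip(y, f))
        assert total_loss(y, f, 0.0) == pytest.approx(sse)

    def test_negative_weight_rejected(self):
        with pytest.raises(GCNError, match="nonnegative"):
            total_loss([1.0, 2.0], [1.0, 2.0], -1.0)

    def test_loss_gradient_matches_finite_differences(self, rng):
        y = rng.normal(size=6)
        f = rng.normal(size=6)
        g = _loss_grad(y, f, 10.0)
        for i in range(6):
            fp = f.copy()
            fp[i] += 1e-7
            fm = f.copy()
            fm[i] -= 1e-7
            fd = (total_loss(y, fp, 10.0) - total_loss(y, fm, 10.0)) / 2e-7
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestNormalizations:
    def test_zscore_definition(self, rng):
        hemis = np.array(["L"] * 5 + ["R"] * 7)
        x = rng.normal(2.0, 3.0, size=(12, 4))
        z = zscore_by_hemisphere(x, hemis)
        for label in ("L", "R"):
            block = z[hemis == label]
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-10)
            np.testing.assert_allclose(block.std(axis=0), 1.0, atol=1e-10)

    def test_zscore_affine_invariance(self, rng):
        hemis = np.array(["L"] * 6 + ["R"] * 6)
        x = rng.normal(size=(12, 2))
        z1 = zscore_by_hemisphere(x, hemis)
        z2 = zscore_by_hemisphere(3.7 * x + 11.0, hemis)
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_zscore_hand_example(self):
        hemis = np.array(["L", "L", "R", "R"])
        x = np.array([[1.0], [3.0], [10.0], [20.0]])
        z = zscore_by_hemisphere(x, hemis)
        np.testing.assert_allclose(z[:, 0], [-1.0, 1.0, -1.0, 1.0])

    def test_zscore_zero_variance_rejected(self):
        hemis = np.array(["L", "L", "R", "R"])
        x = np.array([[1.0], [1.0], [2.0], [3.0]])
        with pytest.raises(GCNError, match="zero within-hemisphere variance"):
            zscore_by_hemisphere(x, hemis)

    def test_minmax_values_and_endpoints(self):
        np.testing.assert_allclose(minmax_iq([100.0]), [0.5])
        np.testing.assert_allclose(minmax_iq([50.0, 150.0]), [0.0, 1.0])

    def test_minmax_round_trip(self, rng):
        x = rng.uniform(55, 145, size=20)
        np.testing.assert_allclose(inverse_minmax_iq(minmax_iq(x)), x, atol=1e-12)

    def test_minmax_out_of_range_warns_linear(self):
        with pytest.warns(UserWarning, match="outside"):
            out = minmax_iq([160.0])
        assert out[0] == pytest.approx(1.1)


def _toy_problem(rng, n=6, nreg=8, d=2):
    a = random_connected_adjacency(rng, nreg, n)
    x = rng.normal(size=(n, nreg, d))
    y = rng.random(n)
    return x, a, y


class TestForward:
    def test_zero_weights_predict_final_bias(self, rng):
        x, a, y = _toy_problem(rng)
        est = ChebNetRegressor(epochs=1, dtype="float64")
        est.fit(x, y, adjacency=a)
        for k in est.params_:
            est.params_[k] = np.zeros_like(est.params_[k])
        est.params_["mlp_b1"] = np.array([0.73])
        np.testing.assert_allclose(
            est.predict(x, adjacency=a), 0.73, atol=1e-12
        )

    def test_reduced_linear_form_matches_hand_computation(self, rng):
        # K=1 with Ltilde entering only via T_1; choose a single GCN channel
        # and no hidden MLP so the model is an explicit linear map for
        # positive pre-activations
        nreg = 5
        a = random_connected_adjacency(rng, nreg)
        lt = build_graph_operator(a).scaled_laplacian
        x = np.abs(rng.normal(size=(1, nreg, 1))) + 5.0  # keep relu linear
        est = ChebNetRegressor(
            K=1, hidden=(1,), mlp_hidden=(), epochs=1, dtype="float64"
        )
        est.fit(
            np.concatenate([x, x]), np.array([0.4, 0.6]), adjacency=np.stack([a, a])
        )
        w0, w1 = 1.0, 0.2
        est.params_["gcn_W0"] = np.array([[w0], [w1]])
        v = rng.normal(size=(nreg, 1))
        est.params_["mlp_W0"] = v
        est.params_["mlp_b0"] = np.array([0.1])
        h = w0 * x[0] + w1 * (lt @ x[0])
        assert np.all(h > 0), "pre-activation must stay positive for linearity"
        expected = float(h[:, 0] @ v[:, 0] + 0.1)
        got = est.predict(x, adjacency=a[None])[0]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_permutation_consistency(self, rng):
        x, a, y = _toy_problem(rng, n=3)
        est = ChebNetRegressor(epochs=2, dtype="float64", hidden=(4, 4), mlp_hidden=(5,))
        est.fit(x, y, adjacency=a)
        perm = rng.permutation(x.shape[1])
        xp = x[:, perm, :]
        ap = a[:, perm][:, :, perm]
        est_p = ChebNetRegressor(epochs=2, dtype="float64", hidden=(4, 4), mlp_hidden=(5,))
        est_p.fit(x, y, adjacency=a)  # same weights as est (same seed)
        # permute the readout rows consistently with the region relabeling
        w = est_p.params_["mlp_W0"].reshape(x.shape[1], -1, est_p.params_["mlp_W0"].shape[1])
        est_p.params_["mlp_W0"] = w[perm].reshape(-1, w.shape[2])
        np.testing.assert_allclose(
            est_p.predict(xp, adjacency=ap),
            est.predict(x, adjacency=a),
            atol=1e-9,
        )

    def test_forward_deterministic(self, rng):
        x, a, y = _toy_problem(rng)
        est = ChebNetRegressor(epochs=3, dtype="float64")
        est.fit(x, y, adjacency=a)
        p1 = est.predict(x, adjacency=a)
        p2 = est.predict(x, adjacency=a)
        np.testing.assert_array_equal(p1, p2)


class TestGradients:
    def test_parameter_gradients_match_finite_differences(self, rng):
        x, a, y = _toy_problem(rng, n=5, nreg=7)
        est = ChebNetRegressor(
            K=3, hidden=(4, 3), mlp_hidden=(5,), epochs=1,
            dtype="float64", w_siamese=10.0,
        )
        est.fit(x, y, adjacency=a)
        params, lt, u0 = est._f64_setup(x, a)
        f, caches = est._forward(params, lt, u0, cache=True)
        grads, _ = est._backward(params, lt, caches, _loss_grad(y, f, 10.0))
        for key, p in params.items():
            flat_idx = [0, p.size // 2, p.size - 1]
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                pp = {k: v.copy() for k, v in params.items()}
                pp[key][idx] += 1e-6
                lp = total_loss(y, est._forward(pp, lt, u0), 10.0)
                pp[key][idx] -= 2e-6
                lm = total_loss(y, est._forward(pp, lt, u0), 10.0)
                fd = (lp - lm) / 2e-6
                assert grads[key][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), key

    def test_input_gradients_match_finite_differences(self, rng):
        x, a, y = _toy_problem(rng, n=3, nreg=6)
        est = ChebNetRegressor(epochs=5, dtype="float64")
        est.fit(x, y, adjacency=a)
        grad = est.input_gradients(x, adjacency=a)
        for (i, r, c) in [(0, 0, 0), (1, 3, 1), (2, 5, 0)]:
            xp = x.copy()
            xp[i, r, c] += 1e-6
            xm = x.copy()
            xm[i, r, c] -= 1e-6
            fd = (
                est.decision_function_f64(xp, adjacency=a)[i]
                - est.decision_function_f64(xm, adjacency=a)[i]
            ) / 2e-6
            assert grad[i, r, c] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_same_seed_gives_bit_identical_trajectory(self, rng):
        x, a, y = _toy_problem(rng, n=12, nreg=10)
        runs = []
        for _ in range(2):
            est = ChebNetRegressor(epochs=25, random_state=11)
            est.fit(x, y, adjacency=a)
            runs.append(est.loss_history_)
        assert runs[0] == runs[1]

    def test_final_loss_not_above_first_epoch(self, rng):
        x, a, y = _toy_problem(rng, n=20, nreg=12)
        # give y structure the model can reduce loss on
        y = minmax_iq(100 + 15 * x[:, :3, 0].mean(axis=1))
        est = ChebNetRegressor(epochs=60, random_state=0)
        est.fit(x, y, adjacency=a)
        assert est.train_loss_final_ <= est.train_loss_first_epoch_

    def test_planted_linear_signal_recovered_on_training_set(self, rng):
        from scipy.stats import spearmanr

        n, nreg = 90, 30
        a = random_connected_adjacency(rng, nreg, n)
        x = rng.normal(size=(n, nreg, 2))
        signal = x[:, [2, 7, 11, 19, 23], 0].mean(axis=1)
        signal = (signal - signal.mean()) / signal.std()
        y01 = minmax_iq(100 + 15 * (0.9 * signal + 0.45 * rng.normal(size=n)))
        batch = TrainingBatch(x=x, adjacency=a, y=y01)
        est = train_model(batch, GCNConfig(seed=1))
        rho = spearmanr(est.predict(x, adjacency=a), y01).statistic
        assert rho >= 0.8

    def test_null_targets_give_near_zero_held_out_correlation(self, rng):
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, nreg = 40, 16
            a = random_connected_adjacency(r, nreg, n)
            x = r.normal(size=(n, nreg, 2))
            y = r.random(n)  # targets independent of features
            est = ChebNetRegressor(epochs=80, random_state=seed)
            est.fit(x[:28], y[:28], adjacency=a[:28])
            pred = est.predict(x[28:], adjacency=a[28:])
            rhos.append(spearmanr(pred, y[28:]).statistic)
        assert abs(np.mean(rhos)) < 0.15

    def test_precomputed_graphs_equal_raw_adjacency(self, rng):
        x, a, y = _toy_problem(rng, n=8, nreg=9)
        graphs = precompute_graphs(a)
        est1 = ChebNetRegressor(epochs=10, random_state=3)
        est1.fit(x, y, adjacency=a)
        est2 = ChebNetRegressor(epochs=10, random_state=3)
        est2.fit(x, y, adjacency=graphs)
        np.testing.assert_array_equal(
            est1.predict(x, adjacency=a), est2.predict(x, adjacency=graphs)
        )

    def test_divergent_learning_rate_aborts_with_diagnostics(self, rng):
        x, a, y = _toy_problem(rng, n=6, nreg=8)
        x = x * 1e150  # force overflow in the first forward pass
        est = ChebNetRegressor(epochs=5, learning_rate=0.005)
        with np.errstate(all="ignore"), pytest.raises(
            FloatingPointError, match="learning rate"
        ):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est.fit(x, y, adjacency=a)

    def test_too_few_subjects_rejected(self, rng):
        x, a, y = _toy_problem(rng, n=1)
        with pytest.raises(GCNError, match="at least 2"):
            ChebNetRegressor().fit(x, y, adjacency=a)
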