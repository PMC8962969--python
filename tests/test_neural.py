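import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fedhar import neural
from fedhar.ingest import ValidationError, Window
from fedhar.neural import (
    BiLSTMParams,
    TrainingConfig,
    bilstm_forward,
    dropout,
    gaussian_noise,
    init_bilstm,
    lstm_cell_step,
    sparsemax,
    sparsemax_loss,
    train_local,
)


def simplex_projection_bruteforce(z):
    """Independent oracle: enumerate every support set and test its KKT system.

    The Euclidean projection onto the simplex is unique; for support S it is
    p_i = z_i - tau with tau = (sum_S z - 1)/|S|, valid iff p > 0 on S and
    z_j - tau <= 0 off S.
    """
    K = len(z)
    for r in range(K, 0, -1):
        for S in itertools.combinations(range(K), r):
            tau = (sum(z[i] for i in S) - 1.0) / r
            p = np.zeros(K)
            ok = True
            for i in S:
                p[i] = z[i] - tau
                if p[i] <= 0:
                    ok = False
                    break
            if not ok:
                continue
            if all(z[j] - tau <= 1e-15 for j in range(K) if j not in S):
                return p
    raise AssertionError("no valid support found")


def grad_check_error(analytic: dict, numeric: dict) -> float:
    """Norm-ratio gradient-check error across parameter blocks."""
    worst = 0.0
    for k in analytic:
        a, n = analytic[k].ravel(), numeric[k].ravel()
        denom = np.linalg.norm(a) + np.linalg.norm(n)
        if denom < 1e-12:
            continue
        worst = max(worst, np.linalg.norm(a - n) / denom)
    return worst


def numeric_grads(params, X, extra, y, eps=1e-6):
    out = {}
    for k, arr in params.arrays.items():
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            lp, _ = neural.batch_loss_and_grads(params, X, extra, y)
            arr[i] = orig - eps
            lm, _ = neural.batch_loss_and_grads(params, X, extra, y)
            arr[i] = orig
            num[i] = (lp - lm) / (2 * eps)
        out[k] = num
    return out


class TestLSTMCell:
    def _zero_params(self, hidden, inputs):
        u = hidden + inputs
        return {
            **{f"W{g}": np.zeros((hidden, u)) for g in "fico"},
            **{f"b{g}": np.zeros(hidden) for g in "fico"},
        }

    def test_zero_weights_give_half_gates(self):
        p = self._zero_params(3, 2)
        s = lstm_cell_step(p, np.zeros(2), np.zeros(3), np.zeros(3))
        assert np.allclose(s.f, 0.5) and np.allclose(s.i, 0.5) and np.allclose(s.o, 0.5)
        assert np.allclose(s.candidate, 0.0)
        assert np.allclose(s.cell, 0.0) and np.allclose(s.hidden, 0.0)

    def test_saturated_forget_gate_is_pure_memory(self):
        p = self._zero_params(2, 1)
        p["bf"] = np.full(2, 50.0)
        s = lstm_cell_step(p, np.zeros(1), np.zeros(2), np.array([0.3, -0.7]))
        assert np.allclose(s.f, 1.0, atol=1e-9)
        assert np.allclose(s.cell, [0.3, -0.7], atol=1e-9)

    def test_matches_scalar_recomputation(self, rng):
        # independent oracle: scalar-by-scalar evaluation of the gate equations
        H, C = 3, 2
        p = {
            **{f"W{g}": rng.normal(size=(H, H + C)) for g in "fico"},
            **{f"b{g}": rng.normal(size=H) for g in "fico"},
        }
        x, h0, c0 = rng.normal(size=C), rng.normal(size=H), rng.normal(size=H)
        s = lstm_cell_step(p, x, h0, c0)
        u = list(h0) + list(x)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        for j in range(H):
            f = sig(sum(p["Wf"][j][k] * u[k] for k in range(H + C)) + p["bf"][j])
            i = sig(sum(p["Wi"][j][k] * u[k] for k in range(H + C)) + p["bi"][j])
            g = np.tanh(sum(p["Wc"][j][k] * u[k] for k in range(H + C)) + p["bc"][j])
            o = sig(sum(p["Wo"][j][k] * u[k] for k in range(H + C)) + p["bo"][j])
            c1 = f * c0[j] + i * g
            assert s.cell[j] == pytest.approx(c1, rel=1e-12)
            assert s.hidden[j] == pytest.approx(o * np.tanh(c1), rel=1e-12)

    def test_gate_bounds_and_cell_growth(self, rng):
        # gates in (0,1); |cell| after t steps bounded by t for the recurrence
        H, C = 4, 3
        p = {
            **{f"W{g}": rng.normal(size=(H, H + C)) for g in "fico"},
            **{f"b{g}": rng.normal(size=H) for g in "fico"},
        }
        h, c = np.zeros(H), np.zeros(H)
        for t in range(1, 20):
            s = lstm_cell_step(p, rng.normal(size=C), h, c)
            assert np.all((s.f > 0) & (s.f < 1))
            assert np.all((s.i > 0) & (s.i < 1))
            assert np.all((s.o > 0) & (s.o < 1))
            assert np.all(np.abs(s.candidate) < 1)
            assert np.all(np.abs(s.cell) <= t)
            h, c = s.hidden, s.cell

    def test_shape_mismatch(self):
        p = self._zero_params(3, 2)
        with pytest.raises(ValidationError):
            lstm_cell_step(p, np.zeros(5), np.zeros(3), np.zeros(3))


class TestBiLSTMForward:
    def test_palindrome_with_shared_params(self, rng):
        params = init_bilstm(n_inputs=2, hidden=4, n_classes=3, seed=0, scale=0.2)
        for g in neural.GATES:
            params.arrays[f"b/{g}"] = params.arrays[f"f/{g}"].copy()
        seq = rng.normal(size=(4, 2))
        pal = np.vstack([seq, seq[::-1]])
        hf, _, _ = neural._direction_forward(params.direction("f"), pal[None])
        hb, _, _ = neural._direction_forward(params.direction("b"), pal[None, ::-1, :])
        assert np.allclose(hf, hb)

    def test_zero_params_zero_scores(self, rng):
        params = init_bilstm(n_inputs=2, hidden=3, n_classes=4, seed=0)
        for k in params.arrays:
            params.arrays[k][:] = 0.0
        assert np.allclose(bilstm_forward(params, rng.normal(size=(6, 2))), 0.0)

    def test_matches_unrolled_oracle(self, rng):
        # oracle: unroll both directions step by step with lstm_cell_step
        params = init_bilstm(n_inputs=2, hidden=3, n_classes=3, seed=3, scale=0.4)
        seq = rng.normal(size=(5, 2))
        h = np.zeros(3)
        c = np.zeros(3)
        for t in range(5):
            s = lstm_cell_step(params.direction("f"), seq[t], h, c)
            h, c = s.hidden, s.cell
        hf = h
        h = np.zeros(3)
        c = np.zeros(3)
        for t in range(4, -1, -1):
            s = lstm_cell_step(params.direction("b"), seq[t], h, c)
            h, c = s.hidden, s.cell
        hb = h
        expected = params.arrays["out/W"] @ np.concatenate([hf, hb]) + params.arrays["out/b"]
        assert np.allclose(bilstm_forward(params, seq), expected)

    def test_empty_sequence_rejected(self):
        params = init_bilstm(n_inputs=2, hidden=3, n_classes=2, seed=0)
        with pytest.raises(ValidationError):
            bilstm_forward(params, np.zeros((0, 2)))


class TestSparsemax:
    def test_uniform_scores(self):
        assert np.allclose(sparsemax(np.array([2.0, 2.0, 2.0])), 1 / 3)

    @given(
        z=hnp.arrays(
            np.float64,
            st.integers(2, 8),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        c=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_shift_invariance_and_simplex(self, z, c):
        p = sparsemax(z)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(sparsemax(z + c), p, atol=1e-9)

    def test_matches_bruteforce_projection(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            k = int(rng.integers(2, 11))
            z = rng.normal(0, 3, size=k)
            assert np.abs(sparsemax(z) - simplex_projection_bruteforce(z)).max() < 1e-9

    def test_temperature_sharpening_shrinks_support(self, rng):
        z = rng.normal(size=6)
        supports = [int((sparsemax(z * s) > 0).sum()) for s in (0.1, 1.0, 10.0, 1000.0)]
        assert supports == sorted(supports, reverse=True)
        assert supports[-1] == 1  # one-hot limit

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            sparsemax(np.array([1.0, np.inf]))


class TestSparsemaxLoss:
    def test_zero_when_projection_is_onehot(self):
        z = np.array([5.0, 0.0, -1.0])
        assert np.allclose(sparsemax(z), [1, 0, 0])
        loss, grad = sparsemax_loss(z, 0)
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(grad, 0.0)

    def test_uniform_gradient(self):
        loss, grad = sparsemax_loss(np.zeros(3), 1)
        assert np.allclose(grad, np.array([1 / 3, 1 / 3 - 1, 1 / 3]))

    def test_loss_nonnegative(self, rng):
        for _ in range(200):
            z = rng.normal(0, 2, size=int(rng.integers(2, 8)))
            y = int(rng.integers(0, z.size))
            loss, _ = sparsemax_loss(z, y)
            assert loss >= -1e-12

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        eps = 1e-6
        for _ in range(100):
            z = rng.normal(0, 2, size=int(rng.integers(2, 8)))
            y = int(rng.integers(0, z.size))
            _, grad = sparsemax_loss(z, y)
            num = np.zeros_like(z)
            for i in range(z.size):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                num[i] = (sparsemax_loss(zp, y)[0] - sparsemax_loss(zm, y)[0]) / (2 * eps)
            denom = np.linalg.norm(grad) + np.linalg.norm(num)
            if denom > 1e-6:  # below: flat optimum, numeric noise only
                assert np.linalg.norm(grad - num) / denom < 1e-5

    def test_invalid_class_index(self):
        with pytest.raises(ValidationError):
            sparsemax_loss(np.zeros(3), 3)


class TestStochasticLayers:
    def test_inference_mode_identity(self, rng):
        x = rng.normal(size=(5, 4))
        assert np.array_equal(gaussian_noise(x, 0.5, training=False), x)
        assert np.array_equal(dropout(x, 0.32, training=False), x)
        assert np.array_equal(dropout(x, 0.0, training=True), x)

    def test_dropout_rate_and_scale(self):
        x = np.ones(10**6)
        out = dropout(x, 0.32, training=True, seed=9)
        zeroed = np.mean(out == 0.0)
        assert abs(zeroed - 0.32) < 0.002
        survivors = out[out != 0]
        assert np.allclose(survivors, 1 / 0.68)

    def test_noise_statistics(self):
        x = np.zeros(10**6)
        out = gaussian_noise(x, 0.5, training=True, seed=9)
        assert abs(out.std() - 0.5) < 0.002

    def test_bad_args(self):
        with pytest.raises(ValidationError):
            dropout(np.ones(3), 1.0, True)
        with pytest.raises(ValidationError):
            gaussian_noise(np.ones(3), -0.1, True)


def _labeled_windows(rng, n, T=6, C=2, classes=("a", "b")):
    out = []
    for i in range(n):
        lab = classes[i % len(classes)]
        shift = 2.0 if lab == "a" else -2.0
        out.append(
            Window(
                window_id=f"s00|arm|{i * T}",
                subject_id="s00",
                position="arm",
                samples=rng.normal(size=(T, C)) + shift,
                features=rng.normal(size=3),
                label=lab,
                label_provenance="ground_truth",
            )
        )
    return out


class TestTrainLocal:
    def test_zero_learning_rate_keeps_params(self, rng):
        windows = _labeled_windows(rng, 6)
        params = init_bilstm(2, 3, 2, extra_dim=3, seed=0, classes=("a", "b"))
        cfg = TrainingConfig(learning_rate=0.0, dropout_rate=0.0, noise_std=0.0, iterations=2, seed=1)
        new, loss = train_local(params, windows, cfg)
        for k in params.arrays:
            assert np.array_equal(new.arrays[k], params.arrays[k])
        assert np.isfinite(loss)

    def test_full_batch_gradient_matches_finite_differences(self, rng):
        windows = _labeled_windows(rng, 3, T=4)
        params = init_bilstm(2, 2, 2, extra_dim=3, seed=2, scale=0.3, classes=("a", "b"))
        X, extra, y = neural._stack_windows(windows, ("a", "b"))
        _, analytic = neural.batch_loss_and_grads(params, X, extra, y)
        numeric = numeric_grads(params, X, extra, y)
        assert grad_check_error(analytic, numeric) < 1e-4

    def test_separable_two_class_convergence(self, rng):
        windows = _labeled_windows(rng, 20)
        params = init_bilstm(2, 4, 2, extra_dim=3, seed=3, classes=("a", "b"))
        cfg = TrainingConfig(
            learning_rate=0.06, dropout_rate=0.0, noise_std=0.0,
            batch_size=8, iterations=200, seed=4,
        )
        trained, loss = train_local(params, windows, cfg)
        preds = neural.predict_labels(trained, windows)
        assert preds == [w.label for w in windows]

    def test_deterministic_given_seed(self, rng):
        windows = _labeled_windows(rng, 8)
        params = init_bilstm(2, 3, 2, extra_dim=3, seed=5, classes=("a", "b"))
        cfg = TrainingConfig(iterations=3, seed=6)
        a, la = train_local(params, windows, cfg)
        b, lb = train_local(params, windows, cfg)
        assert la == lb
        for k in a.arrays:
            assert np.array_equal(a.arrays[k], b.arrays[k])

    def test_no_labeled_windows_error(self, rng):
        w = _labeled_windows(rng, 2)
        for win in w:
            win.label = None
            win.label_provenance = "none"
        params = init_bilstm(2, 3, 2, extra_dim=3, seed=0)
        with pytest.raises(ValidationError):
            train_local(params, w, TrainingConfig())


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        params = init_bilstm(3, 4, 5, extra_dim=2, seed=8, classes=("a", "b", "c", "d", "e"))
        path = tmp_path / "model.h5"
        neural.save_checkpoint(params, path, meta={"note": "fixture"})
        loaded = neural.load_checkpoint(path)
        assert loaded.classes == params.classes
        assert loaded.hidden == params.hidden
        assert set(loaded.arrays) == set(params.arrays)
        for k in params.arrays:
            assert np.array_equal(loaded.arrays[k], params.arrays[k])
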