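"""Conv/BiLSTM forward passes vs brute-force oracles, gradients, training."""

import numpy as np
import pytest

from ecgwaves import BeatMorphology, generate_beat
from ecgwaves.delineator import (
    ConvBiLSTMDelineator, DelineationResult, DelineatorSpec,
    bilstm_labels, conv_features, wave_runs,
)
from ecgwaves.synthetic import QRS


def _single_stage_spec(filters=1, kernel=3):
    return DelineatorSpec(conv_stages=((filters, kernel, 1),),
                          sequence_length=8)


class TestConvFeatures:
    def test_zero_weights_give_zero_map(self):
        spec = DelineatorSpec()
        weights, cin = [], 1
        for filters, kernel, _ in spec.conv_stages:
            weights.append((np.zeros((kernel * cin, filters)), np.zeros(filters)))
            cin = filters
        out = conv_features(spec, np.random.default_rng(0).standard_normal(370),
                            weights)
        assert out.shape == (370, 64)
        assert np.all(out == 0.0)

    def test_delta_kernel_is_identity_on_nonnegative_input(self):
        spec = _single_stage_spec()
        W = np.array([[0.0], [1.0], [0.0]])  # centre tap only
        x = np.abs(np.random.default_rng(1).standard_normal(8))
        out = conv_features(spec, x, [(W, np.zeros(1))])
        assert np.allclose(out[:, 0], x)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("kernel", [1, 2, 3])
    def test_matches_sliding_window_oracle(self, seed, kernel):
        """Brute-force zero-padded convolution on short sequences."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(4, 11))
        filters = int(rng.integers(1, 4))
        spec = DelineatorSpec(conv_stages=((filters, kernel, 1),),
                              sequence_length=length)
        W = rng.standard_normal((kernel, filters))
        b = rng.standard_normal(filters)
        x = rng.standard_normal(length)
        pl = (kernel - 1) // 2
        expected = np.zeros((length, filters))
        for j in range(length):
            for m in range(filters):
                acc = b[m]
                for k in range(kernel):
                    src = j + k - pl
                    if 0 <= src < length:
                        acc += W[k, m] * x[src]
                expected[j, m] = max(acc, 0.0)
        out = conv_features(spec, x, [(W, b)])
        assert np.max(np.abs(out - expected)) < 1e-10

    def test_weight_shape_mismatch_rejected(self):
        spec = _single_stage_spec()
        with pytest.raises(ValueError):
            conv_features(spec, np.zeros(8), [(np.zeros((5, 1)), np.zeros(1))])


def _bilstm_weights(rng, c, h, n_classes=5, zero=False):
    def mk(shape):
        return np.zeros(shape) if zero else rng.standard_normal(shape) * 0.3
    w = {}
    for d in ("f", "b"):
        w[f"lstm_{d}_Wx"] = mk((c, 4 * h))
        w[f"lstm_{d}_Wh"] = mk((h, 4 * h))
        w[f"lstm_{d}_b"] = mk(4 * h)
    w["out_W"] = mk((2 * h, n_classes))
    w["out_b"] = mk(n_classes)
    return w


class TestBilstm:
    def test_zero_weights_give_uniform_probabilities(self):
        rng = np.random.default_rng(0)
        w = _bilstm_weights(rng, 4, 3, zero=True)
        res = bilstm_labels(rng.standard_normal((6, 4)), w, 3)
        assert np.allclose(res.probabilities, 0.2)

    def test_rows_sum_to_one_for_random_weights(self):
        rng = np.random.default_rng(1)
        w = _bilstm_weights(rng, 4, 5)
        res = bilstm_labels(rng.standard_normal((10, 4)), w, 5)
        assert np.allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_direction_swap_symmetry(self):
        """Reversing the input and swapping the forward/backward weight
        blocks reverses the output probabilities."""
        rng = np.random.default_rng(2)
        feats = rng.standard_normal((6, 4))
        w = _bilstm_weights(rng, 4, 3)
        swapped = dict(w)
        for name in ("Wx", "Wh", "b"):
            swapped[f"lstm_f_{name}"] = w[f"lstm_b_{name}"]
            swapped[f"lstm_b_{name}"] = w[f"lstm_f_{name}"]
        h = 3
        # swapping directions also swaps the two halves of the output head
        swapped["out_W"] = np.vstack([w["out_W"][h:], w["out_W"][:h]])
        a = bilstm_labels(feats, w, h).probabilities
        b = bilstm_labels(feats[::-1], swapped, h).probabilities
        assert np.allclose(a, b[::-1], atol=1e-12)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full conv+BiLSTM+softmax stack."""
        rng = np.random.default_rng(0)
        est = ConvBiLSTMDelineator(conv_filters=(3, 4), kernel_size=3,
                                   hidden_size=4, n_classes=3)
        n, t = 2, 6
        X = rng.standard_normal((n, t))
        y = rng.integers(0, 3, size=(n, t))
        onehot = np.eye(3)[y]
        w = est._init_weights(rng)

        def loss_fn():
            probs, _ = est._forward(X, w, want_cache=False)
            p_true = np.clip((probs * onehot).sum(axis=2), 1e-12, None)
            return float(-np.mean(np.log(p_true)))

        probs, extras = est._forward(X, w, want_cache=True)
        grads = est._backward(X, onehot, probs, extras, w)
        eps = 1e-6
        rng2 = np.random.default_rng(1)
        for key in w:
            flat = w[key].reshape(-1)
            g_flat = grads[key].reshape(-1)
            # spot-check a handful of coordinates per parameter
            for idx in rng2.choice(flat.size, size=min(5, flat.size),
                                   replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_fn()
                flat[idx] = orig - eps
                lm = loss_fn()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g_flat[idx], abs=1e-7), key


class TestTrainingMechanics:
    def _tiny(self, **kw):
        kw.setdefault("conv_filters", (2, 3))
        kw.setdefault("hidden_size", 4)
        kw.setdefault("epochs", 2)
        kw.setdefault("learning_rate", 1e-3)
        return ConvBiLSTMDelineator(**kw)

    def _data(self, n=10, seed=0):
        frames = [generate_beat(BeatMorphology()) for _ in range(n)]
        X = np.stack([f.samples for f in frames])
        y = np.stack([f.labels for f in frames])
        return X, y

    def test_same_seed_gives_identical_loss(self):
        X, y = self._data()
        a = self._tiny(seed=5).fit(X, y)
        b = self._tiny(seed=5).fit(X, y)
        assert a.loss_history_ == b.loss_history_

    def test_loss_decreases(self):
        X, y = self._data()
        est = self._tiny(epochs=5, seed=1).fit(X, y)
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_predict_shapes_and_probability_rows(self):
        X, y = self._data()
        est = self._tiny(seed=2).fit(X, y)
        probs = est.predict_proba(X[:3])
        assert probs.shape == (3, 370, 5)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        assert est.predict(X[:3]).shape == (3, 370)

    def test_save_load_round_trip(self, tmp_path):
        X, y = self._data()
        est = self._tiny(seed=3).fit(X, y)
        est.save(tmp_path / "delin.npz")
        back = ConvBiLSTMDelineator.load(tmp_path / "delin.npz")
        assert np.allclose(est.predict_proba(X[:2]), back.predict_proba(X[:2]))


class TestRunExtraction:
    def test_short_runs_are_discarded(self):
        labels = np.array([3, 3, 3, 0, 0, 0, 0, 3, 1, 3, 3])
        runs = wave_runs(labels, min_run_length=3)
        assert runs[0] == [(3, 7)]
        assert 1 not in runs  # single-sample run dropped as noise

    def test_all_pad_prediction_has_no_wave_runs(self):
        probs = np.zeros((370, 5))
        probs[:, 4] = 1.0
        res = DelineationResult(probabilities=probs, labels=probs.argmax(axis=1))
        assert res.onsets_offsets() == {"PAD": [(0, 369)]}
        assert res.r_peak(np.zeros(370)) is None

    def test_inconsistent_result_rejected(self):
        probs = np.full((4, 5), 0.2)
        with pytest.raises(ValueError):
            DelineationResult(probabilities=probs, labels=np.array([1, 1, 1, 1]))
        bad = np.zeros((4, 5))
        with pytest.raises(ValueError):
            DelineationResult(probabilities=bad, labels=np.zeros(4, dtype=int))


class TestTrainedDelineation:
    def test_qrs_onset_within_20ms_of_ground_truth(self, trained_delineator):
        """Derived QRS onsets fall within the standard +/-5 sample (20 ms at
        250 Hz) scoring window on held-out beats."""
        est, held_frames, X, y = trained_delineator
        errors = []
        for frame in held_frames[:25]:
            res = est.delineate(frame)
            runs = res.wave_runs().get(QRS, [])
            true_on = int(np.argmax(frame.labels == QRS))
            assert runs, "no QRS run predicted"
            errors.append(abs(runs[0][0] - true_on))
        errors = np.asarray(errors)
        assert np.median(errors) <= 2
        assert np.mean(errors <= 5) >= 0.8

    def test_r_peak_recovered_on_held_out_beats(self, trained_delineator):
        est, held_frames, X, y = trained_delineator
        for frame in held_frames[:10]:
            res = est.delineate(frame)
            r = res.r_peak(frame.samples)
            true_r = int(np.argmax(frame.samples))
            assert r is not None and abs(r - true_r) <= 2
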