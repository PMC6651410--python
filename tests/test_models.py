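"""Training and prediction behaviour of the two estimators."""

import numpy as np
import pytest

from comcop.models import FfannSpec, LstmSpec, TrainedModel, predict, train_ffann, train_lstm
from comcop.preprocessing import ScaleParams


def _identity_scales():
    x_scale = ScaleParams(np.full(9, -1.0), np.full(9, 1.0))
    y_scale = ScaleParams(np.full(2, -1.0), np.full(2, 1.0))
    return x_scale, y_scale


class TestFfann:
    def test_recovers_linear_map(self, rng):
        x = rng.uniform(-1, 1, (800, 9))
        y = np.column_stack([0.8 * x[:, 0], -0.5 * x[:, 3]])
        xs, ys = _identity_scales()
        model = train_ffann(x[:600], y[:600], x[600:700], y[600:700],
                           spec=FfannSpec(seed=2), x_scale=xs, y_scale=ys)
        pred = predict(model, x[700:], in_degrees=False)
        rmse = np.sqrt(np.mean((pred - y[700:]) ** 2))
        assert rmse < 0.02

    def test_constant_target(self, rng):
        x = rng.uniform(-1, 1, (300, 9))
        y = np.full((300, 2), 0.3)
        xs, ys = _identity_scales()
        model = train_ffann(x[:200], y[:200], x[200:250], y[200:250],
                           spec=FfannSpec(seed=2), x_scale=xs, y_scale=ys)
        pred = predict(model, x[250:], in_degrees=False)
        assert np.max(np.abs(pred - 0.3)) < 0.02

    def test_seeded_training_is_reproducible(self, rng):
        x = rng.uniform(-1, 1, (200, 9))
        y = x[:, :2] * 0.5
        xs, ys = _identity_scales()
        a = train_ffann(x[:150], y[:150], x[150:], y[150:],
                        spec=FfannSpec(seed=5), x_scale=xs, y_scale=ys)
        b = train_ffann(x[:150], y[:150], x[150:], y[150:],
                        spec=FfannSpec(seed=5), x_scale=xs, y_scale=ys)
        assert a.training_log == b.training_log
        assert np.array_equal(a.weights, b.weights)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_ffann(np.zeros((0, 9)), np.zeros((0, 2)),
                        np.zeros((5, 9)), np.zeros((5, 2)))


class TestLstm:
    @staticmethod
    def _running_mean_task(rng, n_seq):
        # band-limited inputs (sensor-like); target is a pure function of the
        # input history, unreachable for any frame-wise map
        from scipy.signal import butter, filtfilt
        b, a = butter(2, 0.1)
        x = filtfilt(b, a, rng.normal(0, 1, (n_seq, 100, 9)), axis=1)
        x /= np.abs(x).max()
        cum = np.cumsum(x[:, :, 0], axis=1) / np.arange(1, 101)
        y = np.stack([cum, -cum], axis=2)
        return x, y

    def test_learns_temporal_running_mean(self, rng):
        """A purely temporal target is recoverable only with state."""
        x, y = self._running_mean_task(rng, 60)
        xs, ys = _identity_scales()
        spec = LstmSpec(cells_per_layer=64, epochs=30, seed=3)
        model = train_lstm((x[:45], y[:45]), (x[45:50], y[45:50]),
                           spec=spec, x_scale=xs, y_scale=ys)
        pred = predict(model, x[50:], in_degrees=False)
        # skip the 10-frame cold start where the state carries no history yet
        rmse = np.sqrt(np.mean((pred[:, 10:] - y[50:, 10:]) ** 2))
        assert rmse < 0.05

    def test_constant_target_under_noise_inputs(self, rng):
        x = rng.normal(0, 0.5, (30, 100, 9))
        y = np.full((30, 100, 2), 0.25)
        xs, ys = _identity_scales()
        spec = LstmSpec(cells_per_layer=16, epochs=10, seed=4)
        model = train_lstm((x[:24], y[:24]), (x[24:27], y[24:27]),
                           spec=spec, x_scale=xs, y_scale=ys)
        pred = predict(model, x[27:], in_degrees=False)
        assert np.max(np.abs(pred - 0.25)) < 0.05

    def test_seeded_training_is_reproducible(self, rng):
        x = rng.uniform(-1, 1, (12, 100, 9))
        y = x[:, :, :2] * 0.3
        xs, ys = _identity_scales()
        spec = LstmSpec(cells_per_layer=8, epochs=5, seed=9)
        a = train_lstm((x[:10], y[:10]), (x[10:], y[10:]), spec=spec,
                       x_scale=xs, y_scale=ys)
        b = train_lstm((x[:10], y[:10]), (x[10:], y[10:]), spec=spec,
                       x_scale=xs, y_scale=ys)
        assert a.training_log[-1]["train_mse"] == b.training_log[-1]["train_mse"]
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_wrong_sequence_length_rejected(self, rng):
        x = rng.normal(0, 1, (4, 50, 9))
        with pytest.raises(ValueError, match="sequences"):
            train_lstm((x, x[:, :, :2]), None, spec=LstmSpec(cells_per_layer=4))


class TestPredict:
    def test_shape_contract_and_inverse_scaling(self, rng):
        x = rng.uniform(-1, 1, (200, 9))
        y = x[:, :2] * 0.5
        x_scale = ScaleParams(np.full(9, -1.0), np.full(9, 1.0))
        y_scale = ScaleParams(np.array([-20.0, -10.0]), np.array([20.0, 10.0]))
        model = train_ffann(x[:150], y[:150], x[150:], y[150:],
                            spec=FfannSpec(seed=0), x_scale=x_scale, y_scale=y_scale)
        cycle = rng.uniform(-1, 1, (100, 9))
        out_deg = predict(model, cycle)
        assert out_deg.shape == (100, 2)
        out_scaled = predict(model, cycle, in_degrees=False)
        assert np.max(np.abs(y_scale.transform(out_deg) - out_scaled)) < 1e-9

    def test_channel_count_enforced(self, rng):
        x = rng.uniform(-1, 1, (100, 9))
        y = x[:, :2]
        xs, ys = _identity_scales()
        model = train_ffann(x[:80], y[:80], x[80:], y[80:],
                            spec=FfannSpec(seed=0), x_scale=xs, y_scale=ys)
        with pytest.raises(ValueError, match="9 input channels"):
            predict(model, rng.normal(0, 1, (10, 8)))

    def test_save_load_round_trip(self, rng, tmp_path):
        x = rng.uniform(-1, 1, (8, 100, 9))
        y = x[:, :, :2] * 0.4
        xs, ys = _identity_scales()
        model = train_lstm((x[:6], y[:6]), (x[6:], y[6:]),
                           spec=LstmSpec(cells_per_layer=8, epochs=3, seed=1),
                           x_scale=xs, y_scale=ys)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.kind == "lstm"
        a = predict(model, x[6:])
        b = predict(loaded, x[6:])
        assert np.allclose(a, b, atol=1e-12)
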