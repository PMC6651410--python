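"""The two COM-COP IA estimators and their seeded training loops.

* FFANN: one hidden layer of 10 log-sigmoid units mapping a single scaled
  sensor frame (9 channels) to the two scaled inclination angles, trained
  full-batch with scaled conjugate gradients, early-stopped when the
  validation MSE fails to improve for 6 consecutive epochs (max 1000).
* LSTM: two stacked layers (512 cells at full scale, reducible for desk-scale
  runs) consuming one 100-frame cycle as one sequence, linear readout, Adam
  (lr 0.001), minibatches of 10 sequences, L2 weight penalty 0.0025, fixed
  epoch budget.

Both trainers are pure functions of (data, spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from comcop.nn import Adam, FfannParams, LstmNetwork, ffann_forward, ffann_loss_grad, scg_minimize
from comcop.preprocessing import ScaleParams


@dataclass(frozen=True)
class FfannSpec:
    """Feed-forward estimator hyperparameters."""

    hidden_units: int = 10
    hidden_activation: str = "logsig"
    output_activation: str = "linear"  # log-sigmoid hidden, linear output (see docs)
    max_epochs: int = 1000
    patience: int = 6
    stopping: str = "val_mse"          # or "grad_norm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.patience < 1:
            raise ValueError("hidden_units and patience must be >= 1")
        if self.max_epochs < self.patience:
            raise ValueError("max_epochs must be >= patience")


@dataclass(frozen=True)
class LstmSpec:
    """LSTM estimator hyperparameters."""

    layers: int = 2
    cells_per_layer: int = 512
    learning_rate: float = 0.001
    minibatch: int = 10
    weight_penalty: float = 0.0025
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1 or self.cells_per_layer < 1:
            raise ValueError("layers and cells_per_layer must be >= 1")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 30) -> "LstmSpec":
        """Reduced profile (2 x 64 cells) for laptop-scale experiments."""
        return cls(cells_per_layer=64, epochs=epochs, seed=seed)


@dataclass
class TrainedModel:
    """A fitted estimator with its spec, training log and scale parameters."""

    kind: str                     # "ffann" | "lstm"
    spec: FfannSpec | LstmSpec
    weights: np.ndarray | dict
    training_log: list = field(default_factory=list)
    x_scale: ScaleParams | None = None
    y_scale: ScaleParams | None = None

    def __post_init__(self) -> None:
        if not self.training_log:
            raise ValueError("training_log must be non-empty")

    def save(self, path) -> None:
        arrays = ({"w": self.weights} if self.kind == "ffann" else dict(self.weights))
        meta = {
            "kind": self.kind,
            "spec": asdict(self.spec),
            "training_log": self.training_log,
            "x_lo": list(self.x_scale.lo), "x_hi": list(self.x_scale.hi),
            "y_lo": list(self.y_scale.lo), "y_hi": list(self.y_scale.hi),
        }
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        spec = (FfannSpec(**meta["spec"]) if meta["kind"] == "ffann"
                else LstmSpec(**meta["spec"]))
        weights = (data["w"] if meta["kind"] == "ffann"
                   else {k: data[k] for k in data.files if k != "__meta__"})
        return cls(
            kind=meta["kind"], spec=spec, weights=weights,
            training_log=meta["training_log"],
            x_scale=ScaleParams(np.array(meta["x_lo"]), np.array(meta["x_hi"])),
            y_scale=ScaleParams(np.array(meta["y_lo"]), np.array(meta["y_hi"])),
        )


def train_ffann(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    spec: FfannSpec | None = None,
    x_scale: ScaleParams | None = None,
    y_scale: ScaleParams | None = None,
) -> TrainedModel:
    """Fit the frame-wise feed-forward estimator.

    Inputs are scaled frames (n, 9) and targets scaled angles (n, 2).  The
    network minimizing the validation criterion is returned (best epoch, not
    the last one).
    """
    spec = spec or FfannSpec()
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation partitions must be non-empty")

    params = FfannParams(x_train.shape[1], spec.hidden_units, y_train.shape[1])
    rng = np.random.default_rng(spec.seed)
    w0 = params.init(rng)

    log: list[dict] = []
    state = {"best_val": np.inf, "best_w": w0.copy(), "since": 0,
             "prev_grad": np.inf, "last_w": None}

    def fun(w):
        loss, _ = ffann_loss_grad(params, w, x_train, y_train, spec.output_activation)
        return loss

    def grad(w):
        _, g = ffann_loss_grad(params, w, x_train, y_train, spec.output_activation)
        return g

    def callback(epoch, w, f_w):
        val_pred = ffann_forward(params, w, x_val, spec.output_activation)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        log.append({"epoch": epoch, "train_mse": float(f_w), "val_mse": val_mse})
        # iterations where SCG rejected the step leave the weights unchanged
        # and carry no new stopping evidence
        if state["last_w"] is not None and np.array_equal(w, state["last_w"]):
            return False
        state["last_w"] = w.copy()
        if spec.stopping == "grad_norm":
            g_norm = float(np.linalg.norm(grad(w)))
            improved = g_norm < state["prev_grad"] * (1 - 1e-6)
            state["prev_grad"] = min(state["prev_grad"], g_norm)
            state["best_w"] = w.copy()
        else:
            improved = val_mse < state["best_val"] - 1e-12
            if improved:
                state["best_val"] = val_mse
                state["best_w"] = w.copy()
        state["since"] = 0 if improved else state["since"] + 1
        return state["since"] >= spec.patience

    scg_minimize(fun, grad, w0, max_epochs=spec.max_epochs, callback=callback)
    return TrainedModel(
        kind="ffann", spec=spec, weights=state["best_w"], training_log=log,
        x_scale=x_scale, y_scale=y_scale,
    )


def train_lstm(
    train_sequences: tuple[np.ndarray, np.ndarray],
    val_sequences: tuple[np.ndarray, np.ndarray] | None,
    spec: LstmSpec | None = None,
    x_scale: ScaleParams | None = None,
    y_scale: ScaleParams | None = None,
    expected_frames: int = 100,
) -> TrainedModel:
    """Fit the sequence-to-sequence LSTM estimator.

    ``train_sequences`` is (X, Y) with X of shape (n_cycles, frames, 9) and Y
    (n_cycles, frames, 2), both in scaled units; every cycle is one
    independent sequence (state reset between cycles).
    """
    spec = spec or LstmSpec()
    X, Y = (np.asarray(a, dtype=float) for a in train_sequences)
    if X.ndim != 3 or X.shape[1] != expected_frames:
        raise ValueError(
            f"sequences must be (n, {expected_frames}, channels), got {X.shape}"
        )
    if len(X) == 0:
        raise ValueError("training partition must be non-empty")

    rng = np.random.default_rng(spec.seed)
    net = LstmNetwork(X.shape[2], spec.cells_per_layer, spec.layers, Y.shape[2], rng)
    # Echo-state-style initialization: solve the ridge-regularized linear
    # readout on the untrained recurrent features, then fine-tune everything.
    # Greatly reduces the burn-in portion of a fixed epoch budget.
    hidden = net.forward(X, want_cache=True)[1][1]  # (frames, cycles, cells)
    hf = hidden.transpose(1, 0, 2).reshape(-1, spec.cells_per_layer)
    design = np.column_stack([hf, np.ones(len(hf))])
    ridge = 1e-3 * np.eye(design.shape[1])
    ridge[-1, -1] = 0.0  # no penalty on the bias
    sol = np.linalg.solve(design.T @ design + ridge, design.T @ Y.reshape(-1, Y.shape[2]))
    net.params["Wy"], net.params["by"] = sol[:-1], sol[-1]
    opt = Adam(net.params, lr=spec.learning_rate, weight_decay=spec.weight_penalty)

    has_val = val_sequences is not None and len(val_sequences[0])
    if has_val:
        Xv, Yv = (np.asarray(a, dtype=float) for a in val_sequences)
    log: list[dict] = []
    n = len(X)
    batch = min(spec.minibatch, n)
    # Stochastic weight averaging over the trailing epochs: removes the
    # minibatch-induced jitter of the final iterate at a fixed epoch budget.
    tail = min(5, spec.epochs)
    tail_sum: dict | None = None
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            loss, grads = net.loss_grad(X[idx], Y[idx])
            opt.step(net.params, grads)
            epoch_loss += loss * len(idx)
        entry = {"epoch": epoch, "train_mse": epoch_loss / n}
        if has_val:
            pred = net.forward(Xv)
            entry["val_mse"] = float(np.mean((pred - Yv) ** 2))
        log.append(entry)
        if epoch > spec.epochs - tail:
            if tail_sum is None:
                tail_sum = {k: v.copy() for k, v in net.params.items()}
            else:
                for k in tail_sum:
                    tail_sum[k] += net.params[k]
    weights = {k: v / tail for k, v in tail_sum.items()}
    return TrainedModel(
        kind="lstm", spec=spec, weights=weights, training_log=log,
        x_scale=x_scale, y_scale=y_scale,
    )


def predict(model: TrainedModel, inputs: np.ndarray, in_degrees: bool = True) -> np.ndarray:
    """Predict inclination angles for scaled inputs.

    FFANN accepts (n, 9) frames; LSTM accepts (n_cycles, frames, 9) cycles.
    With ``in_degrees=True`` (default) predictions are inverse-transformed
    through the model's stored output scale parameters.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape[-1] != 9:
        raise ValueError(f"expected 9 input channels, got {inputs.shape[-1]}")
    if model.kind == "ffann":
        flat = inputs.reshape(-1, 9)
        params = FfannParams(9, model.spec.hidden_units, 2)
        out = ffann_forward(params, model.weights, flat, model.spec.output_activation)
        out = out.reshape(inputs.shape[:-1] + (2,))
    elif model.kind == "lstm":
        if inputs.ndim == 2:
            inputs = inputs[None]
        net = LstmNetwork(9, model.spec.cells_per_layer, model.spec.layers, 2,
                          np.random.default_rng(0))
        net.params = {k: np.asarray(v, dtype=float) for k, v in model.weights.items()}
        out = net.forward(inputs)
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    if in_degrees:
        if model.y_scale is None:
            raise ValueError("model has no stored scale parameters")
        out = model.y_scale.inverse(out)
    return out
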