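"""Numerical kernels for the two estimators: SCG, a one-hidden-layer
feed-forward network, and a stacked LSTM with backpropagation through time.

Everything is plain numpy in float64.  The scaled conjugate gradient
implementation follows Moller's algorithm (second-order information from a
finite-difference Hessian-vector product, Levenberg-Marquardt style scaling,
no line search), the classical trainer for small feed-forward networks.  The
LSTM uses the standard gate formulation (input/forget/output sigmoid gates,
tanh candidate and state activation) trained with Adam.

All gradients are exercised against central finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# Scaled conjugate gradient (Moller 1993)
# ---------------------------------------------------------------------------

def scg_minimize(
    fun,
    grad,
    w0: np.ndarray,
    max_epochs: int = 1000,
    callback=None,
    grad_tol: float = 1e-10,
    sigma0: float = 5e-5,
):
    """Minimize ``fun`` by scaled conjugate gradients.

    ``callback(epoch, w, f)`` is invoked once per iteration ("epoch"); if it
    returns True the optimization stops (used for early stopping).  Returns
    the final weight vector.
    """
    w = np.asarray(w0, dtype=float).copy()
    n = len(w)
    lam, lam_bar = 5e-7, 0.0
    f_w = fun(w)
    g = grad(w)
    r = -g
    p = r.copy()
    success = True
    delta = 1.0
    for k in range(1, max_epochs + 1):
        p_sq = p @ p
        if p_sq == 0.0:
            break
        p_norm = np.sqrt(p_sq)
        if success:
            sigma = sigma0 / p_norm
            s = (grad(w + sigma * p) - g) / sigma
            delta = p @ s
        delta_k = delta + (lam - lam_bar) * p_sq
        if delta_k <= 0:  # make the Hessian surrogate positive definite
            lam_bar = 2.0 * (lam - delta_k / p_sq)
            delta_k = -delta_k + lam * p_sq
            lam = lam_bar
        mu = p @ r
        alpha = mu / delta_k
        f_new = fun(w + alpha * p)
        comparison = 2.0 * delta_k * (f_w - f_new) / mu**2
        if comparison >= 0:
            w = w + alpha * p
            f_w = f_new
            g = grad(w)
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta = (r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta_k * (1.0 - comparison) / p_sq
        lam = min(lam, 1e15)
        if callback is not None and callback(k, w, f_w):
            break
        if np.sqrt(r @ r) < grad_tol:
            break
    return w


# ---------------------------------------------------------------------------
# Feed-forward network: 9 -> hidden (log-sigmoid) -> 2 (linear)
# ---------------------------------------------------------------------------

@dataclass
class FfannParams:
    """Weight shapes of the one-hidden-layer network."""

    n_in: int
    n_hidden: int
    n_out: int

    @property
    def size(self) -> int:
        return (self.n_in + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_out

    def init(self, rng: np.random.Generator) -> np.ndarray:
        lim1 = np.sqrt(6.0 / (self.n_in + self.n_hidden))
        lim2 = np.sqrt(6.0 / (self.n_hidden + self.n_out))
        w1 = rng.uniform(-lim1, lim1, (self.n_in, self.n_hidden))
        b1 = np.zeros(self.n_hidden)
        w2 = rng.uniform(-lim2, lim2, (self.n_hidden, self.n_out))
        b2 = np.zeros(self.n_out)
        return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])

    def unpack(self, w: np.ndarray):
        i = self.n_in * self.n_hidden
        w1 = w[:i].reshape(self.n_in, self.n_hidden)
        b1 = w[i:i + self.n_hidden]
        j = i + self.n_hidden
        w2 = w[j:j + self.n_hidden * self.n_out].reshape(self.n_hidden, self.n_out)
        b2 = w[j + self.n_hidden * self.n_out:]
        return w1, b1, w2, b2


def ffann_forward(params: FfannParams, w: np.ndarray, x: np.ndarray,
                  output_activation: str = "linear") -> np.ndarray:
    w1, b1, w2, b2 = params.unpack(w)
    h = _sigmoid(x @ w1 + b1)
    z = h @ w2 + b2
    return _sigmoid(z) if output_activation == "sigmoid" else z


def ffann_loss_grad(params: FfannParams, w: np.ndarray, x: np.ndarray, y: np.ndarray,
                    output_activation: str = "linear"):
    """Mean-squared error and its gradient via backprop."""
    w1, b1, w2, b2 = params.unpack(w)
    h = _sigmoid(x @ w1 + b1)
    z = h @ w2 + b2
    yhat = _sigmoid(z) if output_activation == "sigmoid" else z
    err = yhat - y
    loss = float(np.mean(err**2))
    dz = 2.0 * err / err.size
    if output_activation == "sigmoid":
        dz = dz * yhat * (1.0 - yhat)
    dw2 = h.T @ dz
    db2 = dz.sum(axis=0)
    dh = dz @ w2.T
    da = dh * h * (1.0 - h)
    dw1 = x.T @ da
    db1 = da.sum(axis=0)
    return loss, np.concatenate([dw1.ravel(), db1, dw2.ravel(), db2])


# ---------------------------------------------------------------------------
# Stacked LSTM with a linear readout
# ---------------------------------------------------------------------------

class LstmNetwork:
    """Stacked LSTM (tanh state activation, sigmoid gates) + linear output.

    Parameters per layer l: ``Wx`` (in, 4H), ``Wh`` (H, 4H), ``b`` (4H) with
    gate order input, forget, candidate, output; readout ``Wy`` (H, n_out),
    ``by``.  Forget-gate biases start at 1.  State is reset between
    sequences (each normalized gait cycle is independent).
    """

    def __init__(self, n_in: int, n_hidden: int, n_layers: int, n_out: int,
                 rng: np.random.Generator):
        self.n_in, self.n_hidden, self.n_layers, self.n_out = n_in, n_hidden, n_layers, n_out
        self.params: dict[str, np.ndarray] = {}
        for layer in range(n_layers):
            d_in = n_in if layer == 0 else n_hidden
            lim = np.sqrt(6.0 / (d_in + n_hidden))
            self.params[f"Wx{layer}"] = rng.uniform(-lim, lim, (d_in, 4 * n_hidden))
            # Orthogonal recurrent kernels (one per gate) for healthy
            # gradient propagation through time.
            blocks = []
            for _ in range(4):
                a = rng.normal(0.0, 1.0, (n_hidden, n_hidden))
                q, r = np.linalg.qr(a)
                blocks.append(q * np.sign(np.diag(r)))
            self.params[f"Wh{layer}"] = np.hstack(blocks)
            b = np.zeros(4 * n_hidden)
            b[n_hidden:2 * n_hidden] = 1.0  # forget gate bias
            self.params[f"b{layer}"] = b
        lim = np.sqrt(6.0 / (n_hidden + n_out))
        self.params["Wy"] = rng.uniform(-lim, lim, (n_hidden, n_out))
        self.params["by"] = np.zeros(n_out)

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, T, n_in) -> predictions (B, T, n_out)."""
        B, T, _ = x.shape
        H = self.n_hidden
        inp = np.ascontiguousarray(x.transpose(1, 0, 2))  # (T, B, in)
        caches = []
        for layer in range(self.n_layers):
            Wx, Wh, b = (self.params[f"Wx{layer}"], self.params[f"Wh{layer}"],
                         self.params[f"b{layer}"])
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((T, B, H))
            cache = {"x": inp, "i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
                     "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
                     "c": np.empty((T, B, H)), "tc": np.empty((T, B, H)),
                     "h_prev": np.empty((T, B, H)), "c_prev": np.empty((T, B, H))}
            x_proj = inp @ Wx + b  # (T, B, 4H)
            for t in range(T):
                a = x_proj[t] + h @ Wh
                i_g = _sigmoid(a[:, :H])
                f_g = _sigmoid(a[:, H:2 * H])
                g_g = np.tanh(a[:, 2 * H:3 * H])
                o_g = _sigmoid(a[:, 3 * H:])
                cache["h_prev"][t] = h
                cache["c_prev"][t] = c
                c = f_g * c + i_g * g_g
                tc = np.tanh(c)
                h = o_g * tc
                hs[t] = h
                for k, v in (("i", i_g), ("f", f_g), ("g", g_g), ("o", o_g),
                             ("c", c), ("tc", tc)):
                    cache[k][t] = v
            caches.append(cache)
            inp = hs
        yhat = inp @ self.params["Wy"] + self.params["by"]  # (T, B, out)
        out = yhat.transpose(1, 0, 2)
        if want_cache:
            return out, (caches, inp)
        return out

    # -- backward ----------------------------------------------------------
    def loss_grad(self, x: np.ndarray, y: np.ndarray):
        """Mean-squared error over all frames and its parameter gradients."""
        B, T, _ = x.shape
        H = self.n_hidden
        yhat, (caches, top_h) = self.forward(x, want_cache=True)
        err = yhat - y
        loss = float(np.mean(err**2))
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dyhat = (2.0 * err / err.size).transpose(1, 0, 2)  # (T, B, out)
        grads["Wy"] = np.einsum("tbh,tbo->ho", top_h, dyhat)
        grads["by"] = dyhat.sum(axis=(0, 1))
        dh_above = dyhat @ self.params["Wy"].T  # (T, B, H)
        for layer in range(self.n_layers - 1, -1, -1):
            cache = caches[layer]
            Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
            dWx, dWh, db = (np.zeros_like(Wx), np.zeros_like(Wh),
                            np.zeros_like(self.params[f"b{layer}"]))
            dx = np.empty_like(cache["x"])
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                dh = dh_above[t] + dh_next
                o_g, tc = cache["o"][t], cache["tc"][t]
                do = dh * tc
                dc = dh * o_g * (1.0 - tc**2) + dc_next
                i_g, f_g, g_g = cache["i"][t], cache["f"][t], cache["g"][t]
                di = dc * g_g
                df = dc * cache["c_prev"][t]
                dg = dc * i_g
                da = np.concatenate([
                    di * i_g * (1 - i_g),
                    df * f_g * (1 - f_g),
                    dg * (1 - g_g**2),
                    do * o_g * (1 - o_g),
                ], axis=1)  # (B, 4H)
                dWx += cache["x"][t].T @ da
                dWh += cache["h_prev"][t].T @ da
                db += da.sum(axis=0)
                dx[t] = da @ Wx.T
                dh_next = da @ Wh.T
                dc_next = dc * f_g
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"b{layer}"] = db
            dh_above = dx
        return loss, grads

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat(self, w: np.ndarray) -> None:
        i = 0
        for k in sorted(self.params):
            n = self.params[k].size
            self.params[k] = w[i:i + n].reshape(self.params[k].shape)
            i += n


class Adam:
    """Adam with optional decoupled L2 weight decay on weight matrices."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            if self.weight_decay and not k.startswith("b"):
                g = g + self.weight_decay * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
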