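"""A compact NumPy bidirectional-LSTM classifier.

Implements exactly the architecture the per-motif sub-models use: a stack
of bidirectional LSTM layers over the 5-position feature window (5
features per step), the final layer's per-step outputs flattened into a
three-layer fully connected head, softmax over two classes with
cross-entropy loss, and Adam updates.  Analytic gradients are written out
by hand (full backpropagation through time) and are checked against
central finite differences in the test suite.

Kept dependency-free on purpose: training is CPU-scale (thousands of
events, 5 time steps), and a self-contained implementation gives strict
run-to-run determinism under a fixed seed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

__all__ = ["BiLSTMNet", "AdamOptimizer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class BiLSTMNet:
    """Stacked bidirectional LSTM + 3-layer fully connected head.

    Parameters
    ----------
    n_features : input features per time step.
    n_steps : sequence length (window positions).
    hidden_size : LSTM hidden units per direction.
    n_layers : number of stacked bidirectional LSTM layers.
    fc_sizes : widths of the two hidden fully connected layers; the output
        layer has 2 units (softmax).
    seed : parameter-initialisation seed.
    """

    def __init__(
        self,
        n_features: int = 5,
        n_steps: int = 5,
        hidden_size: int = 64,
        n_layers: int = 3,
        fc_sizes: tuple[int, int] = (64, 32),
        seed: int = 0,
    ) -> None:
        self.n_features = n_features
        self.n_steps = n_steps
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.fc_sizes = fc_sizes
        rng = np.random.default_rng(seed)
        H = hidden_size
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        for layer in range(n_layers):
            d_in = n_features if layer == 0 else 2 * H
            for d in ("f", "b"):
                self.params[f"l{layer}{d}_Wx"] = rng.uniform(-k, k, size=(d_in, 4 * H))
                self.params[f"l{layer}{d}_Wh"] = rng.uniform(-k, k, size=(H, 4 * H))
                b = np.zeros(4 * H)
                b[H : 2 * H] = 1.0  # forget-gate bias
                self.params[f"l{layer}{d}_b"] = b
        dims = [n_steps * 2 * H, fc_sizes[0], fc_sizes[1], 2]
        for i, (din, dout) in enumerate(zip(dims, dims[1:])):
            bound = 1.0 / np.sqrt(din)
            self.params[f"fc{i}_W"] = rng.uniform(-bound, bound, size=(din, dout))
            self.params[f"fc{i}_b"] = np.zeros(dout)

    # -- LSTM single direction ------------------------------------------------

    def _lstm_forward(self, X: np.ndarray, prefix: str) -> tuple[np.ndarray, list]:
        """X: (B, T, D) -> H_seq (B, T, H) plus per-step cache."""
        Wx, Wh, b = (self.params[f"{prefix}_Wx"], self.params[f"{prefix}_Wh"],
                     self.params[f"{prefix}_b"])
        B, T, _ = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        H_seq = np.empty((B, T, H))
        cache = []
        for t in range(T):
            x = X[:, t]
            z = x @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            H_seq[:, t] = h
        return H_seq, cache

    def _lstm_backward(
        self, dH_seq: np.ndarray, cache: list, prefix: str, grads: dict
    ) -> np.ndarray:
        Wx, Wh = self.params[f"{prefix}_Wx"], self.params[f"{prefix}_Wh"]
        B, T, H = dH_seq.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.empty((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dH_seq[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
        grads[f"{prefix}_Wx"] = dWx
        grads[f"{prefix}_Wh"] = dWh
        grads[f"{prefix}_b"] = db
        return dX

    # -- full network ---------------------------------------------------------

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """X: (B, T, F) -> class probabilities (B, 2)."""
        X = np.asarray(X, dtype=float)
        caches = []
        inp = X
        for layer in range(self.n_layers):
            Hf, cf = self._lstm_forward(inp, f"l{layer}f")
            Hb_rev, cb = self._lstm_forward(inp[:, ::-1], f"l{layer}b")
            Hb = Hb_rev[:, ::-1]
            out = np.concatenate([Hf, Hb], axis=2)
            caches.append((cf, cb, inp.shape))
            inp = out
        B = X.shape[0]
        flat = inp.reshape(B, -1)
        a = flat
        fc_cache = []
        for i in range(3):
            z = a @ self.params[f"fc{i}_W"] + self.params[f"fc{i}_b"]
            if i < 2:
                a_new = np.maximum(z, 0.0)
            else:
                a_new = z
            fc_cache.append((a, z))
            a = a_new
        probs = _softmax(a)
        if return_cache:
            return probs, (caches, flat, fc_cache)
        return probs

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and gradients for a batch."""
        probs, (caches, flat, fc_cache) = self.forward(X, return_cache=True)
        B = len(y)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(B), y] + eps)))
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        da = dlogits
        for i in reversed(range(3)):
            a_in, z = fc_cache[i]
            grads[f"fc{i}_W"] = a_in.T @ da
            grads[f"fc{i}_b"] = da.sum(axis=0)
            da = da @ self.params[f"fc{i}_W"].T
            if i > 0:
                prev_z = fc_cache[i - 1][1]
                da = da * (prev_z > 0)
        dflat = da
        H = self.hidden_size
        dout = dflat.reshape(X.shape[0], self.n_steps, 2 * H)
        for layer in reversed(range(self.n_layers)):
            cf, cb, in_shape = caches[layer]
            dHf = dout[:, :, :H]
            dHb = dout[:, :, H:]
            dX_f = self._lstm_backward(dHf, cf, f"l{layer}f", grads)
            dX_b_rev = self._lstm_backward(dHb[:, ::-1], cb, f"l{layer}b", grads)
            dout = dX_f + dX_b_rev[:, ::-1]
        return loss, grads

    # -- parameter snapshots ---------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(params[k], dtype=float)


class AdamOptimizer:
    """Adam with externally supplied (scheduled) learning rate."""

    def __init__(self, params: Mapping[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
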