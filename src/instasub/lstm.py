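"""A compact bidirectional LSTM sequence classifier in pure numpy.

Architecture: a single bidirectional LSTM layer (default 20 hidden units per
direction) reading the 100 x 3 latent trajectory segments, the two final
hidden states concatenated into a dense softmax layer over the four object
classes.  Trained with Adam on the cross-entropy loss, mini-batches, and
early stopping on a training-loss plateau.  The model is tiny (a few thousand
parameters), so full-batch gradients via backpropagation through time are
cheap on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMClassifier"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class BiLSTMClassifier:
    """Sequence classifier: (K, T, n_inputs) float sequences -> class labels."""

    def __init__(
        self,
        n_inputs: int = 3,
        n_hidden: int = 20,
        n_classes: int = 4,
        rng: np.random.Generator | None = None,
    ):
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.n_classes = n_classes
        rng = rng if rng is not None else np.random.default_rng(0)
        H, I, C = n_hidden, n_inputs, n_classes

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        self.params = {}
        for d in ("f", "b"):  # forward / backward direction
            self.params[f"Wx_{d}"] = glorot((I, 4 * H))
            self.params[f"Wh_{d}"] = glorot((H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = bias
        self.params["Wo"] = glorot((2 * H, C))
        self.params["bo"] = np.zeros(C)

    # ------------------------------------------------------------------
    def _run_dir(self, X, d, want_cache=False):
        H = self.n_hidden
        Wx, Wh, b = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"])
        B, T, _ = X.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        xw = X @ Wx + b
        cache = []
        for t in range(T):
            z = xw[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if want_cache:
                cache.append((i, f, g, o, c_prev, h_prev, tc))
        return h, cache

    def _backward_dir(self, X, d, cache, dh_last):
        H = self.n_hidden
        Wh = self.params[f"Wh_{d}"]
        B, T, _ = X.shape
        dh = dh_last
        dc = np.zeros_like(dh)
        dzs = np.empty((T, B, 4 * H))
        dWh = np.zeros_like(Wh)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dzs[t] = dz
            dWh += h_prev.T @ dz
            dh = dz @ Wh.T
            dc = dc * f
        dWx = np.einsum("tbi,tbh->ih", X.transpose(1, 0, 2), dzs)
        db = dzs.sum(axis=(0, 1))
        return {f"Wx_{d}": dWx, f"Wh_{d}": dWh, f"b_{d}": db}

    def _features(self, X, want_cache=False):
        hf, cf = self._run_dir(X, "f", want_cache)
        hb, cb = self._run_dir(X[:, ::-1], "b", want_cache)
        return np.concatenate([hf, hb], axis=1), cf, cb

    def _loss_and_grads(self, X, y):
        H = self.n_hidden
        feat, cf, cb = self._features(X, want_cache=True)
        logits = feat @ self.params["Wo"] + self.params["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        B = X.shape[0]
        loss = -np.mean(np.log(p[np.arange(B), y] + 1e-12))
        dlog = p.copy()
        dlog[np.arange(B), y] -= 1.0
        dlog /= B
        grads = {
            "Wo": feat.T @ dlog,
            "bo": dlog.sum(axis=0),
        }
        dfeat = dlog @ self.params["Wo"].T
        grads.update(self._backward_dir(X, "f", cf, dfeat[:, :H]))
        grads.update(self._backward_dir(X[:, ::-1], "b", cb, dfeat[:, H:]))
        return loss, grads

    # ------------------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        max_epochs: int = 100,
        lr: float = 1e-3,
        batch_size: int = 16,
        patience: int = 10,
        min_delta: float = 1e-3,
        rng: np.random.Generator | None = None,
    ) -> "BiLSTMClassifier":
        """Train with Adam; stops early when the epoch loss plateaus."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = rng if rng is not None else np.random.default_rng(0)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = np.inf
        stall = 0
        for _ in range(max_epochs):
            order = rng.permutation(len(y))
            losses = []
            for s in range(0, len(y), batch_size):
                idx = order[s : s + batch_size]
                loss, grads = self._loss_and_grads(X[idx], y[idx])
                losses.append(loss)
                step += 1
                for k, g in grads.items():
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mh = m[k] / (1 - b1**step)
                    vh = v[k] / (1 - b2**step)
                    self.params[k] -= lr * mh / (np.sqrt(vh) + eps)
            epoch_loss = float(np.mean(losses))
            if best - epoch_loss > min_delta:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        feat, _, _ = self._features(np.asarray(X, dtype=float))
        logits = feat @ self.params["Wo"] + self.params["bo"]
        return np.argmax(logits, axis=1)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
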