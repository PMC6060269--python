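"""Feedforward neural network trained on the Poisson likelihood.

Architecture: two dense hidden layers (configurable sizes) with batch
normalization and rectified-linear activations, dropout after the first
hidden layer, and a final exponentiation so the output is a positive mean
count per bin.  With zero hidden layers the network reduces exactly to the
exponential-link Poisson GLM.  Weights (not biases) carry an elastic-net
penalty.  Training minimizes the per-sample Poisson negative log-likelihood
mean(mu - y log mu) with Adam on shuffled mini-batches; all randomness
(initialization, shuffling, dropout) flows from one integer seed, so training
is bit-reproducible.

Implemented directly in NumPy (forward and backward passes are hand-written),
which keeps the dependency surface small and the arithmetic deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FeedforwardPoissonNet"]

_ETA_MAX = 30.0
_BN_EPS = 1e-5


class FeedforwardPoissonNet:
    """Poisson-output multilayer perceptron.

    Parameters
    ----------
    hidden : tuple of layer sizes; ``()`` degenerates to a GLM.
    dropout : drop probability after the first hidden layer.
    l1, l2 : elastic-net penalty on weight matrices (biases unpenalized).
    learning_rate, epochs, batch_size : Adam training schedule.
    seed : controls initialization, shuffling and dropout masks.
    """

    def __init__(
        self,
        hidden=(64, 32),
        dropout: float = 0.1,
        l1: float = 0.0,
        l2: float = 1e-4,
        learning_rate: float = 1e-2,
        epochs: int = 60,
        batch_size: int = 256,
        seed: int = 0,
    ):
        hidden = tuple(int(h) for h in hidden)
        if any(h < 1 for h in hidden):
            raise ValueError("hidden layer sizes must be >= 1")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if l1 < 0 or l2 < 0:
            raise ValueError("penalties must be nonnegative")
        if epochs < 1 or batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.hidden = hidden
        self.dropout = float(dropout)
        self.l1 = float(l1)
        self.l2 = float(l2)
        self.learning_rate = float(learning_rate)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self._fitted = False

    # -- parameter bookkeeping ------------------------------------------------

    def _init_params(self, n_features: int, rng) -> None:
        sizes = (n_features, *self.hidden)
        self.W_, self.b_ = [], []
        self.gamma_, self.beta_ = [], []
        self.run_mean_, self.run_var_ = [], []
        for i in range(len(self.hidden)):
            fan_in = sizes[i]
            self.W_.append(rng.standard_normal((fan_in, sizes[i + 1])) * np.sqrt(2.0 / fan_in))
            self.b_.append(np.zeros(sizes[i + 1]))
            self.gamma_.append(np.ones(sizes[i + 1]))
            self.beta_.append(np.zeros(sizes[i + 1]))
            self.run_mean_.append(np.zeros(sizes[i + 1]))
            self.run_var_.append(np.ones(sizes[i + 1]))
        self.W_out_ = rng.standard_normal((sizes[-1], 1)) * np.sqrt(1.0 / sizes[-1])
        self.b_out_ = np.zeros(1)

    def _params(self):
        return [*self.W_, *self.b_, *self.gamma_, *self.beta_, self.W_out_, self.b_out_]

    # -- forward / backward ---------------------------------------------------

    def _forward_train(self, x, rng):
        cache = []
        a = x
        for i in range(len(self.hidden)):
            z = a @ self.W_[i] + self.b_[i]
            mu_b = z.mean(axis=0)
            var_b = z.var(axis=0)
            inv_std = 1.0 / np.sqrt(var_b + _BN_EPS)
            zhat = (z - mu_b) * inv_std
            u = self.gamma_[i] * zhat + self.beta_[i]
            act = np.maximum(u, 0.0)
            mask = None
            if i == 0 and self.dropout > 0.0:
                mask = (rng.random(act.shape) >= self.dropout) / (1.0 - self.dropout)
                act = act * mask
            self.run_mean_[i] = 0.9 * self.run_mean_[i] + 0.1 * mu_b
            self.run_var_[i] = 0.9 * self.run_var_[i] + 0.1 * var_b
            cache.append((a, zhat, inv_std, u, mask))
            a = act
        eta = (a @ self.W_out_ + self.b_out_).ravel()
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        return eta, a, cache

    def _backward(self, x, y, eta, a_last, cache):
        B = x.shape[0]
        mu = np.exp(eta)
        d_eta = ((mu - y) / B)[:, None]
        gW, gb, ggamma, gbeta = (
            [None] * len(self.hidden),
            [None] * len(self.hidden),
            [None] * len(self.hidden),
            [None] * len(self.hidden),
        )
        gW_out = a_last.T @ d_eta + self.l2 * self.W_out_ + self.l1 * np.sign(self.W_out_)
        gb_out = d_eta.sum(axis=0)
        d_a = d_eta @ self.W_out_.T
        for i in reversed(range(len(self.hidden))):
            a_prev, zhat, inv_std, u, mask = cache[i]
            if mask is not None:
                d_a = d_a * mask
            d_u = d_a * (u > 0)
            ggamma[i] = (d_u * zhat).sum(axis=0)
            gbeta[i] = d_u.sum(axis=0)
            d_zhat = d_u * self.gamma_[i]
            d_z = (
                inv_std
                / B
                * (B * d_zhat - d_zhat.sum(axis=0) - zhat * (d_zhat * zhat).sum(axis=0))
            )
            gW[i] = a_prev.T @ d_z + self.l2 * self.W_[i] + self.l1 * np.sign(self.W_[i])
            gb[i] = d_z.sum(axis=0)
            d_a = d_z @ self.W_[i].T
        return [*gW, *gb, *ggamma, *gbeta, gW_out, gb_out]

    # -- training -------------------------------------------------------------

    def fit(self, X, y) -> "FeedforwardPoissonNet":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        rng = np.random.default_rng(self.seed)
        self._mu_x = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd_x = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu_x) / self._sd_x
        self._init_params(Xs.shape[1], rng)
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        step = 0
        n = Xs.shape[0]
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], y[idx]
                eta, a_last, cache = self._forward_train(xb, rng)
                epoch_loss += float(np.sum(np.exp(eta) - yb * eta))
                grads = self._backward(xb, yb, eta, a_last, cache)
                step += 1
                lr_t = self.learning_rate * np.sqrt(1 - 0.999**step) / (1 - 0.9**step)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= 0.9
                    mi += 0.1 * g
                    vi *= 0.999
                    vi += 0.001 * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + 1e-8)
            self.loss_history_.append(epoch_loss / n)
        self._fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted mean counts per bin (inference mode: running BN stats,
        no dropout)."""
        if not self._fitted:
            raise RuntimeError("predict called before fit")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        a = (X - self._mu_x) / self._sd_x
        for i in range(len(self.hidden)):
            z = a @ self.W_[i] + self.b_[i]
            zhat = (z - self.run_mean_[i]) / np.sqrt(self.run_var_[i] + _BN_EPS)
            a = np.maximum(self.gamma_[i] * zhat + self.beta_[i], 0.0)
        eta = np.clip((a @ self.W_out_ + self.b_out_).ravel(), -_ETA_MAX, _ETA_MAX)
        return np.exp(eta)
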