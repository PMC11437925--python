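"""Minimal feed-forward softmax networks with analytic gradients.

Everything the dosing models need is a softmax classifier over either linear
scores or a single ReLU hidden layer, trained by Adam on minibatches — small
enough that explicit numpy backpropagation is both transparent and fast, and
every gradient can be (and is, in the test suite) checked against central
finite differences.

Three families live here:

* :class:`LinearNet` — softmax regression, used for interpretable policies.
* :class:`MLP` — one ReLU hidden layer with optional (inverted) dropout;
  the behaviour-policy imputation network and the default policy network.
* :class:`BayesByBackpropNet` — the same MLP architecture with a mean-field
  Gaussian posterior over every weight, trained by maximizing a Monte-Carlo
  estimate of the evidence lower bound with the reparameterization trick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bandit_core import softmax

__all__ = [
    "AdamOptimizer",
    "SoftmaxNet",
    "LinearNet",
    "MLP",
    "ScaleMixturePrior",
    "BayesByBackpropNet",
    "train_classifier",
    "TrainConfig",
]


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def one_hot(y: np.ndarray, K: int) -> np.ndarray:
    Y = np.zeros((len(y), K))
    Y[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return Y


class AdamOptimizer:
    """Adam over a list of parameter arrays.

    Note the default betas follow the dosing-model training recipe,
    (beta1, beta2) = (0.999, 0.9) — reversed from the conventional
    (0.9, 0.999), which remains available by passing it explicitly.
    """

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.999, 0.9),
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        """In-place descent step along ``grads``."""
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SoftmaxNet:
    """Interface shared by the softmax networks.

    Subclasses provide ``params`` (list of arrays), ``logits`` and
    ``grad_from_logits``; the generic pieces (probabilities, cross-entropy
    gradient, flat-parameter access for finite-difference checks) live here.
    """

    n_in: int
    n_out: int

    @property
    def params(self) -> list[np.ndarray]:
        raise NotImplementedError

    def logits(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def grad_from_logits(self, X: np.ndarray, Gz: np.ndarray) -> list[np.ndarray]:
        """Gradient of ``sum(Gz * logits(X))`` w.r.t. each parameter array."""
        raise NotImplementedError

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(X))

    def prob_of(self, X: np.ndarray, actions: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[np.arange(len(actions)), np.asarray(actions, int)]

    def nll(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy (natural log)."""
        P = self.predict_proba(X)
        p = P[np.arange(len(y)), np.asarray(y, int)]
        return float(-np.mean(np.log(np.clip(p, 1e-300, None))))

    def nll_grads(self, X: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        """Gradient of the mean cross-entropy w.r.t. parameters."""
        P = self.predict_proba(X)
        Gz = (P - one_hot(y, self.n_out)) / len(y)
        return self.grad_from_logits(X, Gz)

    # flat-parameter access: finite-difference oracles perturb single entries
    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_flat(self, theta: np.ndarray) -> None:
        k = 0
        for p in self.params:
            p[...] = theta[k : k + p.size].reshape(p.shape)
            k += p.size

    def copy(self) -> "SoftmaxNet":
        import copy as _copy

        return _copy.deepcopy(self)


class LinearNet(SoftmaxNet):
    """Softmax regression: logits = X @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 init_scale: float = 0.0):
        self.n_in, self.n_out = int(n_in), int(n_out)
        if rng is None or init_scale == 0.0:
            self.W = np.zeros((n_in, n_out))
        else:
            self.W = init_scale * rng.standard_normal((n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def logits(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.W + self.b

    def grad_from_logits(self, X: np.ndarray, Gz: np.ndarray) -> list[np.ndarray]:
        X = np.atleast_2d(X)
        return [X.T @ Gz, Gz.sum(axis=0)]


class MLP(SoftmaxNet):
    """One ReLU hidden layer; optional inverted dropout after the hidden layer.

    Dropout is applied only when a mask generator is passed to
    :meth:`logits` / :meth:`mc_predict_proba`, so the deterministic forward
    pass used at evaluation time needs no flag-flipping.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        n_out: int,
        rng: np.random.Generator,
        dropout_rate: float = 0.0,
    ):
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.n_in, self.n_hidden, self.n_out = int(n_in), int(n_hidden), int(n_out)
        self.dropout_rate = float(dropout_rate)
        # He initialization for the ReLU layer, Glorot-ish for the readout
        self.W1 = rng.standard_normal((n_in, n_hidden)) * np.sqrt(2.0 / n_in)
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.standard_normal((n_hidden, n_out)) * np.sqrt(1.0 / n_hidden)
        self.b2 = np.zeros(n_out)

    @classmethod
    def from_params(cls, W1, b1, W2, b2, dropout_rate: float = 0.0) -> "MLP":
        net = cls.__new__(cls)
        net.W1 = np.asarray(W1, float).copy()
        net.b1 = np.asarray(b1, float).copy()
        net.W2 = np.asarray(W2, float).copy()
        net.b2 = np.asarray(b2, float).copy()
        net.n_in, net.n_hidden = net.W1.shape
        net.n_out = net.W2.shape[1]
        net.dropout_rate = float(dropout_rate)
        return net

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return relu(np.atleast_2d(X) @ self.W1 + self.b1)

    def logits(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        H = self._hidden(X)
        if mask is not None:
            H = H * mask / (1.0 - self.dropout_rate)
        return H @ self.W2 + self.b2

    def sample_mask(self, n_rows: int, rng: np.random.Generator) -> np.ndarray:
        if self.dropout_rate <= 0:
            raise ValueError("dropout_rate is 0; no stochastic masks to sample")
        return (rng.random((n_rows, self.n_hidden)) >= self.dropout_rate).astype(float)

    def mc_predict_proba(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One stochastic forward pass with a fresh dropout mask."""
        X = np.atleast_2d(X)
        return softmax(self.logits(X, mask=self.sample_mask(X.shape[0], rng)))

    def grad_from_logits(
        self, X: np.ndarray, Gz: np.ndarray, mask: np.ndarray | None = None
    ) -> list[np.ndarray]:
        X = np.atleast_2d(X)
        Z1 = X @ self.W1 + self.b1
        H = relu(Z1)
        scale = 1.0
        if mask is not None:
            scale = mask / (1.0 - self.dropout_rate)
            Hd = H * scale
        else:
            Hd = H
        gW2 = Hd.T @ Gz
        gb2 = Gz.sum(axis=0)
        Gh = (Gz @ self.W2.T) * scale * (Z1 > 0)
        gW1 = X.T @ Gh
        gb1 = Gh.sum(axis=0)
        return [gW1, gb1, gW2, gb2]


@dataclass
class TrainConfig:
    """Optimization settings for classifier training.

    Defaults follow the dosing-model recipe: lr 1e-3, minibatch 50,
    dropout 0.25 on the hidden layer, 80/20 train/validation split with
    progressive-validation early stopping (patience 5 epochs).
    """

    hidden_units: int = 20
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 50
    adam_betas: tuple[float, float] = (0.999, 0.9)
    max_epochs: int = 200
    patience: int = 5
    train_frac: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.train_frac <= 1:
            raise ValueError("train_frac must be in (0, 1]")


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for k in range(0, n, batch_size):
        yield order[k : k + batch_size]


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    seed: int,
    n_out: int | None = None,
) -> MLP:
    """Fit a single-hidden-layer softmax classifier, deterministically per seed.

    The data are split train/validation by ``cfg.train_frac``; training stops
    once validation cross-entropy has failed to improve for ``cfg.patience``
    consecutive epochs, returning the parameters from the best epoch.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=int)
    if n_out is None:
        n_out = int(y.max()) + 1
    if len(np.unique(y)) < 2:
        missing = sorted(set(range(n_out)) - set(np.unique(y)))
        raise ValueError(
            f"degenerate single-action data: no observations for actions {missing}"
        )
    rng = np.random.default_rng(seed)
    net = MLP(X.shape[1], cfg.hidden_units, n_out, rng, dropout_rate=cfg.dropout_rate)
    opt = AdamOptimizer(net.params, lr=cfg.learning_rate, betas=cfg.adam_betas)

    n = len(y)
    if cfg.train_frac < 1.0 and n >= 10:
        perm = rng.permutation(n)
        n_tr = max(1, int(round(cfg.train_frac * n)))
        tr, va = perm[:n_tr], perm[n_tr:]
    else:
        tr = np.arange(n)
        va = np.arange(n)
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    best_loss = np.inf
    best_params = [p.copy() for p in net.params]
    stall = 0
    for _epoch in range(cfg.max_epochs):
        for idx in _minibatches(len(ytr), cfg.batch_size, rng):
            xb, yb = Xtr[idx], ytr[idx]
            if cfg.dropout_rate > 0:
                mask = net.sample_mask(len(yb), rng)
                P = softmax(net.logits(xb, mask=mask))
                Gz = (P - one_hot(yb, n_out)) / len(yb)
                grads = net.grad_from_logits(xb, Gz, mask=mask)
            else:
                grads = net.nll_grads(xb, yb)
            opt.step(net.params, grads)
        val_loss = net.nll(Xva, yva)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = [p.copy() for p in net.params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    for p, bp in zip(net.params, best_params):
        p[...] = bp
    return net


# ---------------------------------------------------------------------------
# Bayes-by-backprop
# ---------------------------------------------------------------------------


@dataclass
class ScaleMixturePrior:
    """Scale mixture of two zero-mean Gaussians over each weight.

    Defaults: 0.5 N(0, 0.5) + 0.5 N(0, 0.002) — a broad slab plus a narrow
    spike that shrinks uninformative weights.
    """

    weights: tuple[float, float] = (0.5, 0.5)
    variances: tuple[float, float] = (0.5, 0.002)
    means: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if any(v <= 0 for v in self.variances):
            raise ValueError("mixture variances must be positive")

    def _component_logpdf(self, w: np.ndarray) -> np.ndarray:
        # stacked (2, ...) component log densities
        out = []
        for mu, var in zip(self.means, self.variances):
            out.append(-0.5 * np.log(2 * np.pi * var) - 0.5 * (w - mu) ** 2 / var)
        return np.stack(out)

    def log_prob(self, w: np.ndarray) -> float:
        lp = self._component_logpdf(w)
        lw = np.log(np.asarray(self.weights))[:, None]
        m = np.max(lp + lw.reshape(2, *([1] * w.ndim)), axis=0)
        z = np.exp(lp + np.log(np.asarray(self.weights)).reshape(2, *([1] * w.ndim)) - m)
        return float(np.sum(m + np.log(z.sum(axis=0))))

    def grad_log_prob(self, w: np.ndarray) -> np.ndarray:
        """d log p(w) / dw, via mixture responsibilities."""
        lp = self._component_logpdf(w)
        lw = np.log(np.asarray(self.weights)).reshape(2, *([1] * w.ndim))
        r = softmax(np.moveaxis(lp + lw, 0, -1))  # responsibilities
        r = np.moveaxis(r, -1, 0)
        g = np.zeros_like(w)
        for k, (mu, var) in enumerate(zip(self.means, self.variances)):
            g += r[k] * (-(w - mu) / var)
        return g


def _softplus(rho: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(rho))) + np.maximum(rho, 0.0)


def _softplus_grad(rho: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rho))


class BayesByBackpropNet:
    """Mean-field Gaussian posterior over the weights of an :class:`MLP`.

    Each weight has variational parameters (mu, rho) with sigma =
    softplus(rho).  Training minimizes the single-sample Monte-Carlo estimate
    of the negative ELBO,

        log q(w|theta) - log p(w) - log p(D|w),

    with w = mu + sigma * eps drawn by the reparameterization trick.  The KL
    terms are scaled per minibatch by batch/n so one epoch sums to the full
    objective.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        n_out: int,
        prior: ScaleMixturePrior,
        rng: np.random.Generator,
        init_rho: float = -5.0,
    ):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.prior = prior
        shapes = [(n_in, n_hidden), (n_hidden,), (n_hidden, n_out), (n_out,)]
        self.mu = [rng.standard_normal(s) * 0.1 for s in shapes]
        self.rho = [np.full(s, init_rho, dtype=float) for s in shapes]

    @property
    def sigmas(self) -> list[np.ndarray]:
        return [_softplus(r) for r in self.rho]

    def sample_network(self, rng: np.random.Generator) -> MLP:
        ws = [m + s * rng.standard_normal(m.shape) for m, s in zip(self.mu, self.sigmas)]
        return MLP.from_params(*ws)

    def mean_network(self) -> MLP:
        return MLP.from_params(*self.mu)

    def _elbo_terms(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
        kl_scale: float,
    ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """One MC sample of the negative ELBO and its (mu, rho) gradients.

        With w = mu + sigma*eps the pathwise mu-gradient of
        [log q - log p(w) - log lik] reduces to the w-gradient of
        [-log p(w) - log lik] (the log q terms cancel), and the rho-gradient
        gains the closed-form -sigma'(rho)/sigma entropy term.
        """
        eps = [rng.standard_normal(m.shape) for m in self.mu]
        sig = self.sigmas
        ws = [m + s * e for m, s, e in zip(self.mu, sig, eps)]
        net = MLP.from_params(*ws)
        # negative log likelihood over the batch (sum), rescaled to full-data
        P = net.predict_proba(X)
        p = np.clip(P[np.arange(len(y)), y], 1e-300, None)
        nll = -np.sum(np.log(p))
        g_nll = net.grad_from_logits(X, P - one_hot(y, self.n_out))

        logq = 0.0
        logp = 0.0
        g_mu, g_rho = [], []
        for w, m, s, r, e, gl in zip(ws, self.mu, sig, self.rho, eps, g_nll):
            logp += self.prior.log_prob(w)
            logq += float(
                np.sum(-0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * e**2)
            )
            g_w = -self.prior.grad_log_prob(w) * kl_scale + gl
            g_mu.append(g_w)
            g_rho.append((g_w * e - kl_scale / s) * _softplus_grad(r))
        loss = kl_scale * (logq - logp) + nll
        return float(loss), g_mu, g_rho

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        lr: float = 1e-3,
        batch_size: int = 50,
        betas: tuple[float, float] = (0.999, 0.9),
        seed: int = 0,
    ) -> list[float]:
        """Run minibatch ELBO optimization; returns the per-epoch loss trace."""
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        params = self.mu + self.rho
        opt = AdamOptimizer(params, lr=lr, betas=betas)
        n = len(y)
        trace: list[float] = []
        for step_epoch in range(epochs):
            total = 0.0
            for idx in _minibatches(n, batch_size, rng):
                xb, yb = X[idx], y[idx]
                kl_scale = len(yb) / n
                loss, g_mu, g_rho = self._elbo_terms(xb, yb, rng, kl_scale)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"ELBO diverged (non-finite loss) at epoch {step_epoch}"
                    )
                opt.step(params, g_mu + g_rho)
                total += loss
            trace.append(total)
        return trace

    def elbo_estimate(
        self, X: np.ndarray, y: np.ndarray, n_samples: int, seed: int
    ) -> float:
        """Monte-Carlo ELBO (higher is better) with ``n_samples`` weight draws."""
        rng = np.random.default_rng(seed)
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, dtype=int)
        vals = []
        for _ in range(n_samples):
            loss, _, _ = self._elbo_terms(X, y, rng, kl_scale=1.0)
            vals.append(-loss)
        return float(np.mean(vals))
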