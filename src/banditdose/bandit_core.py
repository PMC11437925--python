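"""Core data model for logged contextual-bandit data and stochastic policies.

A logged bandit dataset ``D = {(x_i, a_i, r_i)}`` records, for each patient
(or generic context) ``x_i``, the single action ``a_i`` the behaviour policy
took and the reward ``r_i`` that followed.  Rewards for the actions *not*
taken are never observed; every estimator in :mod:`banditdose.estimators`
exists to work around that.

Policies are maps from a context row to a probability vector over the ``K``
discrete actions.  Deterministic clinical rules are represented as point-mass
policies so that one interface covers the logging policy ``h0``, any target
policy ``h`` and learned policies ``h_w``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoggedBandit",
    "StochasticPolicy",
    "LinearSoftmaxPolicy",
    "MLPSoftmaxPolicy",
    "PointMassPolicy",
    "UniformPolicy",
    "FunctionPolicy",
    "EstimateResult",
    "load_bandit_table",
    "save_bandit_table",
    "empirical_mean_reward",
    "policy_from_weights",
    "softmax",
]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised by the max-shift identity."""
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class LoggedBandit:
    """Immutable container for a logged bandit dataset.

    Parameters
    ----------
    contexts : (n, d) float array
        Patient/context feature rows ``x_i``.
    actions : (n,) int array
        Logged actions ``a_i`` in ``{0, ..., n_actions-1}``.
    rewards : (n,) float array
        Observed rewards ``r_i``; finite reals, binary {0,1} in the dosing
        applications but not enforced.
    logged_propensity : (n,) float array, optional
        The true behaviour-policy probability of the logged action, when the
        simulator that produced the log recorded it.  Every entry must be
        strictly positive (the overlap assumption: wherever the target policy
        has support, the behaviour policy must too).
    n_actions : int, optional
        ``K``.  Inferred as ``max(actions) + 1`` when omitted; pass it
        explicitly when a rare action may be absent from a split.
    action_labels : sequence of str, optional
        Sidecar clinical names ("low"/"medium"/"high") for the integer codes.
    """

    contexts: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    logged_propensity: np.ndarray | None = None
    n_actions: int | None = None
    action_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.contexts = np.atleast_2d(np.asarray(self.contexts, dtype=float))
        self.actions = np.asarray(self.actions)
        self.rewards = np.asarray(self.rewards, dtype=float)
        n = self.contexts.shape[0]
        if n < 1:
            raise ValueError("logged bandit dataset must contain at least one record")
        if len(self.actions) != n or len(self.rewards) != n:
            raise ValueError(
                f"length mismatch: {n} context rows, {len(self.actions)} actions, "
                f"{len(self.rewards)} rewards"
            )
        if not np.all(np.isfinite(self.contexts)):
            raise ValueError("contexts contain non-finite values")
        if not np.all(np.isfinite(self.rewards)):
            raise ValueError("rewards contain non-finite values")
        af = np.asarray(self.actions, dtype=float)
        if not np.all(af == np.round(af)):
            raise ValueError("actions must be integer-coded")
        self.actions = self.actions.astype(np.int64)
        if self.actions.min() < 0:
            raise ValueError("actions must be >= 0")
        if self.n_actions is None:
            self.n_actions = int(self.actions.max()) + 1
        if self.actions.max() >= self.n_actions:
            raise ValueError(
                f"action {int(self.actions.max())} outside [0, {self.n_actions})"
            )
        if self.logged_propensity is not None:
            self.logged_propensity = np.asarray(self.logged_propensity, dtype=float)
            if len(self.logged_propensity) != n:
                raise ValueError("logged_propensity length mismatch")
            if not np.all(
                (self.logged_propensity > 0) & (self.logged_propensity <= 1)
            ):
                raise ValueError(
                    "logged propensities must lie in (0, 1]: overlap requires "
                    "p_h0(a_i|x_i) > 0 for every logged action"
                )
        if self.action_labels is not None:
            self.action_labels = tuple(self.action_labels)
            if len(self.action_labels) != self.n_actions:
                raise ValueError("need one action label per action")

    @property
    def n(self) -> int:
        return self.contexts.shape[0]

    @property
    def d(self) -> int:
        return self.contexts.shape[1]

    def subset(self, idx: np.ndarray) -> "LoggedBandit":
        """Row-subset (bootstrap resamples, train/test splits)."""
        return LoggedBandit(
            contexts=self.contexts[idx],
            actions=self.actions[idx],
            rewards=self.rewards[idx],
            logged_propensity=None
            if self.logged_propensity is None
            else self.logged_propensity[idx],
            n_actions=self.n_actions,
            action_labels=self.action_labels,
        )


class StochasticPolicy:
    """Base class: a map from context rows to probability vectors over K actions."""

    n_actions: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Return an (n, K) matrix of action probabilities; rows sum to 1."""
        raise NotImplementedError

    def prob_of(self, X: np.ndarray, actions: np.ndarray) -> np.ndarray:
        """p(a_i | x_i) for paired contexts and actions."""
        P = self.predict_proba(X)
        return P[np.arange(len(actions)), np.asarray(actions, dtype=int)]

    def greedy_actions(self, X: np.ndarray) -> np.ndarray:
        """Argmax action per row; ties broken toward the lowest action index."""
        return np.argmax(self.predict_proba(X), axis=1)

    def sample_actions(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        P = self.predict_proba(np.atleast_2d(X))
        u = rng.random(P.shape[0])
        return (P.cumsum(axis=1) < u[:, None]).sum(axis=1)


class LinearSoftmaxPolicy(StochasticPolicy):
    """Softmax over linear scores ``x @ W + b``; strictly positive outputs."""

    def __init__(self, W: np.ndarray, b: np.ndarray | None = None):
        W = np.asarray(W, dtype=float)
        if W.ndim != 2:
            raise ValueError("weight matrix must be 2-D (d x K)")
        if not np.all(np.isfinite(W)):
            raise ValueError("non-finite policy weights")
        self.W = W
        self.b = np.zeros(W.shape[1]) if b is None else np.asarray(b, dtype=float)
        if self.b.shape != (W.shape[1],):
            raise ValueError("bias shape mismatch")
        self.n_actions = W.shape[1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"context dimension {X.shape[1]} does not match policy ({self.W.shape[0]})"
            )
        return softmax(X @ self.W + self.b)


class MLPSoftmaxPolicy(StochasticPolicy):
    """Single-hidden-layer ReLU network with a softmax output layer."""

    def __init__(self, net) -> None:  # net: banditdose.nnet.MLP
        self.net = net
        self.n_actions = net.n_out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(np.atleast_2d(np.asarray(X, dtype=float)))


class PointMassPolicy(StochasticPolicy):
    """Deterministic rule wrapped as a policy: all mass on ``rule(x)``."""

    def __init__(self, rule: Callable[[np.ndarray], np.ndarray], n_actions: int):
        self.rule = rule
        self.n_actions = int(n_actions)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a = np.asarray(self.rule(X), dtype=int)
        P = np.zeros((X.shape[0], self.n_actions))
        P[np.arange(X.shape[0]), a] = 1.0
        return P


class UniformPolicy(StochasticPolicy):
    def __init__(self, n_actions: int):
        self.n_actions = int(n_actions)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.full((X.shape[0], self.n_actions), 1.0 / self.n_actions)


class FunctionPolicy(StochasticPolicy):
    """Adapter turning any row->simplex callable into a policy."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], n_actions: int):
        self.fn = fn
        self.n_actions = int(n_actions)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(np.asarray(self.fn(np.atleast_2d(X)), dtype=float))
        return P


@dataclass
class EstimateResult:
    """A counterfactual value estimate with its uncertainty diagnostics.

    ``per_member`` holds one estimate per bootstrap/ensemble member when the
    estimator is ensemble-based; the percentile confidence interval is taken
    over those.  ``weights`` stores the importance weights actually used, so
    callers can inspect effective sample size and weight concentration.
    """

    estimate: float
    estimator_name: str
    per_member: np.ndarray | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    weights: np.ndarray | None = None

    @property
    def effective_sample_size(self) -> float | None:
        if self.weights is None:
            return None
        w = np.asarray(self.weights, dtype=float)
        s = w.sum()
        if s == 0:
            return 0.0
        return float(s**2 / np.sum(w**2))

    @property
    def max_weight(self) -> float | None:
        if self.weights is None:
            return None
        return float(np.max(self.weights))

    def to_dict(self) -> dict:
        return {
            "estimate": float(self.estimate),
            "estimator": self.estimator_name,
            "ci_low": None if self.ci_low is None else float(self.ci_low),
            "ci_high": None if self.ci_high is None else float(self.ci_high),
            "per_member": None
            if self.per_member is None
            else [float(v) for v in np.asarray(self.per_member)],
            "max_weight": self.max_weight,
            "effective_sample_size": self.effective_sample_size,
        }


# ---------------------------------------------------------------------------
# Tabular I/O.  CSV dialect: header row, feature columns prefixed `x`,
# required `action` and `reward` columns, optional `propensity`.
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {"action": "action", "reward": "reward", "propensity": "propensity"}


def load_bandit_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    n_actions: int | None = None,
) -> LoggedBandit:
    """Read a logged-bandit CSV into a validated :class:`LoggedBandit`.

    ``schema`` remaps the required column names, e.g.
    ``{"action": "dose_bin", "reward": "in_window"}``.  Feature columns are
    all columns prefixed ``x``, in file order.  A JSON sidecar
    ``<path>.meta.json`` (written by :func:`save_bandit_table`) supplies
    ``n_actions`` and action labels when present.
    """
    path = Path(path)
    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("action", "reward"):
        if cols[key] not in df.columns:
            raise KeyError(f"required column {cols[key]!r} missing from {path.name}")
    feat_cols = [c for c in df.columns if c.startswith("x")]
    if not feat_cols:
        raise KeyError(f"no feature columns (prefixed 'x') in {path.name}")
    labels = None
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        n_actions = n_actions or meta.get("n_actions")
        labels = meta.get("action_labels")
    prop = None
    if cols["propensity"] in df.columns:
        prop = df[cols["propensity"]].to_numpy(dtype=float)
    return LoggedBandit(
        contexts=df[feat_cols].to_numpy(dtype=float),
        actions=df[cols["action"]].to_numpy(),
        rewards=df[cols["reward"]].to_numpy(dtype=float),
        logged_propensity=prop,
        n_actions=n_actions,
        action_labels=labels,
    )


def save_bandit_table(D: LoggedBandit, path: str | Path) -> None:
    """Write ``D`` to the CSV dialect plus a JSON metadata sidecar.

    Full float precision (repr round-trip) so that read-back reproduces the
    arrays bit-for-bit.
    """
    path = Path(path)
    data = {f"x{j}": D.contexts[:, j] for j in range(D.d)}
    data["action"] = D.actions
    data["reward"] = D.rewards
    if D.logged_propensity is not None:
        data["propensity"] = D.logged_propensity
    # default float formatting is shortest-round-trip repr: lossless read-back
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {
        "n_actions": int(D.n_actions),
        "action_labels": None if D.action_labels is None else list(D.action_labels),
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))


def empirical_mean_reward(D: LoggedBandit) -> float:
    """On-policy baseline: the plain average of the logged rewards."""
    return float(np.mean(D.rewards))


def policy_from_weights(
    weight_matrix: np.ndarray,
    kind: str = "linear-softmax",
    bias: np.ndarray | None = None,
) -> StochasticPolicy:
    """Build a softmax policy from an explicit d x K weight matrix."""
    if kind == "linear-softmax":
        return LinearSoftmaxPolicy(weight_matrix, bias)
    if kind == "mlp-softmax":
        from .nnet import MLP  # deferred: avoids circularity at import time

        if not (isinstance(weight_matrix, (list, tuple)) and len(weight_matrix) == 4):
            raise ValueError(
                "mlp-softmax expects the four parameter arrays (W1, b1, W2, b2)"
            )
        net = MLP.from_params(*weight_matrix)
        return MLPSoftmaxPolicy(net)
    raise ValueError(f"unknown policy kind {kind!r}")
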