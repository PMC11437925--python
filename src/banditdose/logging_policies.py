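"""Simulated clinician (logging) policies and supervised-to-bandit conversion.

A fully labelled classification table ``(X, y)`` becomes a partial-feedback
bandit log by sampling actions from a simulated logging policy and rewarding
label matches, ``r_i = I(y_i = a_i)``.  Two logging-policy families are
provided:

* **LR** — a multiclass logistic regression fitted on a small random
  subsample (5% by default) of the training data, with its weights perturbed
  by standard-normal noise to add stochasticity;
* **mixture** — an equal-probability mixture of two user-supplied
  deterministic dosing rules, emulating clinicians who follow one of two
  published formulas.

The clinical discretization rules for warfarin and heparin doses and the
aPTT therapeutic-window reward live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .bandit_core import (
    LinearSoftmaxPolicy,
    LoggedBandit,
    PointMassPolicy,
    StochasticPolicy,
)

__all__ = [
    "LoggingSimConfig",
    "fit_lr_logging_policy",
    "MixturePolicy",
    "mixture_policy",
    "supervised_to_bandit",
    "discretize_warfarin_dose",
    "discretize_heparin_dose",
    "heparin_reward",
]


@dataclass
class LoggingSimConfig:
    """Knobs of the simulated logging policies.

    ``subsample_frac`` — fraction of the data the LR logging policy sees
    (default 0.05: a deliberately weak expert).
    ``perturb_noise_sd`` — scale of the i.i.d. Gaussian perturbation added to
    every fitted LR coefficient (default 1, i.e. standard normal).
    ``mixture_threshold`` — the per-record uniform draw below which the
    mixture policy follows its first component (default 0.5).
    """

    subsample_frac: float = 0.05
    perturb_noise_sd: float = 1.0
    mixture_threshold: float = 0.5
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValueError("subsample_frac must be in (0, 1]")
        if self.perturb_noise_sd < 0:
            raise ValueError("perturb_noise_sd must be >= 0")


def fit_lr_logging_policy(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LoggingSimConfig | None = None,
    seed: int = 0,
) -> LinearSoftmaxPolicy:
    """Fit the weak LR logging policy on a small random subsample.

    A multinomial logistic regression is fitted on ``subsample_frac`` of the
    rows (resampled until at least two classes are present, up to
    ``max_retries``), then every coefficient is perturbed by i.i.d.
    ``N(0, perturb_noise_sd^2)`` noise.  Deterministic given ``seed``.
    """
    cfg = cfg or LoggingSimConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=int)
    K = int(y.max()) + 1
    n = len(y)
    n_sub = max(2, int(round(cfg.subsample_frac * n)))
    rng = np.random.default_rng(seed)
    for attempt in range(cfg.max_retries + 1):
        idx = rng.choice(n, size=min(n_sub, n), replace=False)
        if len(np.unique(y[idx])) >= 2:
            break
    else:
        raise ValueError(
            f"subsample contained a single class after {cfg.max_retries} retries"
        )
    lr = LogisticRegression(max_iter=1000)
    lr.fit(X[idx], y[idx])
    # expand sklearn's coefficient layout to a full d x K score matrix
    W = np.zeros((X.shape[1], K))
    b = np.zeros(K)
    if len(lr.classes_) == 2 and lr.coef_.shape[0] == 1:
        c0, c1 = (int(c) for c in lr.classes_)
        W[:, c1] = lr.coef_[0]
        b[c1] = lr.intercept_[0]
    else:
        for j, c in enumerate(lr.classes_):
            W[:, int(c)] = lr.coef_[j]
            b[int(c)] = lr.intercept_[j]
    if cfg.perturb_noise_sd > 0:
        W = W + cfg.perturb_noise_sd * rng.standard_normal(W.shape)
        b = b + cfg.perturb_noise_sd * rng.standard_normal(b.shape)
    return LinearSoftmaxPolicy(W, b)


class MixturePolicy(StochasticPolicy):
    """Equal-probability mixture of two deterministic policies.

    Sampling draws a uniform ``u`` per record and follows the first component
    when ``u <= threshold``; the propensity of action ``a`` at ``x`` is
    ``0.5 I(h1(x)=a) + 0.5 I(h2(x)=a)`` (for the default threshold).
    """

    def __init__(
        self,
        h1: PointMassPolicy,
        h2: PointMassPolicy,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        if h1.n_actions != h2.n_actions:
            raise ValueError("component policies must share the action space")
        self.h1, self.h2 = h1, h2
        self.threshold = float(threshold)
        self.seed = int(seed)
        self.n_actions = h1.n_actions

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        t = self.threshold
        return t * self.h1.predict_proba(X) + (1.0 - t) * self.h2.predict_proba(X)

    def sample_actions(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        u = rng.random(X.shape[0])
        a1 = self.h1.greedy_actions(X)
        a2 = self.h2.greedy_actions(X)
        return np.where(u <= self.threshold, a1, a2)


def mixture_policy(
    h1: PointMassPolicy, h2: PointMassPolicy, seed: int = 0,
    threshold: float = 0.5,
) -> MixturePolicy:
    """Convenience constructor for :class:`MixturePolicy`."""
    return MixturePolicy(h1, h2, threshold=threshold, seed=seed)


def supervised_to_bandit(
    X: np.ndarray,
    y: np.ndarray,
    logging: StochasticPolicy,
    seed: int = 0,
) -> LoggedBandit:
    """Convert a labelled table into a bandit log under ``logging``.

    For each row, an action is sampled from the logging policy, the reward is
    the label-match indicator, and the true propensity of the sampled action
    is recorded — so downstream estimators can be run either with the exact
    logged propensities or with imputed ones.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    a = logging.sample_actions(X, rng)
    prop = logging.prob_of(X, a)
    K = max(logging.n_actions, int(y.max()) + 1)
    return LoggedBandit(
        contexts=X,
        actions=a,
        rewards=(a == y).astype(float),
        logged_propensity=prop,
        n_actions=K,
    )


def discretize_warfarin_dose(dose_mg_per_week: float | np.ndarray) -> np.ndarray:
    """Warfarin weekly dose to {0: low, 1: medium, 2: high}.

    low < 21 mg/wk; 21 <= medium <= 49 mg/wk; high > 49 mg/wk.
    """
    dose = np.asarray(dose_mg_per_week, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be positive")
    out = np.where(dose < 21.0, 0, np.where(dose <= 49.0, 1, 2))
    return out if out.ndim else out[()]


def discretize_heparin_dose(dose: float | np.ndarray) -> np.ndarray:
    """Heparin dose to {0: low, 1: medium, 2: high}; thresholds 10 and 15.

    The thresholds are treated as unit-agnostic numbers: the boundary
    convention (strict below, inclusive middle, strict above) matches the
    warfarin rule.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be positive")
    out = np.where(d < 10.0, 0, np.where(d <= 15.0, 1, 2))
    return out if out.ndim else out[()]


def heparin_reward(aptt_seconds: float | np.ndarray) -> np.ndarray:
    """Therapeutic-window indicator: 1 iff 60s <= aPTT(6h) <= 100s."""
    a = np.asarray(aptt_seconds, dtype=float)
    if np.any(a < 0):
        raise ValueError("aPTT cannot be negative")
    out = ((a >= 60.0) & (a <= 100.0)).astype(float)
    return out if out.ndim else out[()]
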