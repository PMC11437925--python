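"""Gradient-based counterfactual policy optimization.

A parametric softmax policy ``h_w`` is trained to maximize an off-policy
estimate of its reward on the log, by minibatch stochastic gradient ascent on

    R^(h_w) = (1/B) sum_i  p_hw(a_i|x_i) r_i / q_i,

where ``q_i`` is the imputed behaviour-policy propensity of the logged
action.  Variants:

* ``single`` — one behaviour model supplies ``q_i``;
* ``avg``    — ``q_i`` is the mean of M bootstrapped members' propensities;
* ``inv``    — the objective is the mean of the M per-member objectives;
* ``snips``  — any of the above with per-minibatch self-normalized weights
  (a biased-per-batch surrogate for the SNIPS ratio, see docs);
* adversarial — a two-player scheme in which the behaviour model ``h0``
  simultaneously minimizes the policy's estimated reward and its own
  imputation cross-entropy (weighted by ``lambda``), while ``h`` maximizes
  reward against that worst-case ``h0``.

All gradients are analytic and checked against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandit_core import (
    LinearSoftmaxPolicy,
    LoggedBandit,
    MLPSoftmaxPolicy,
    StochasticPolicy,
)
from .estimators import snips as snips_estimator
from .nnet import MLP, AdamOptimizer, LinearNet, SoftmaxNet, one_hot
from .propensity import (
    PROPENSITY_FLOOR,
    PropensityEnsemble,
    ensemble_propensity,
)

__all__ = [
    "LearnConfig",
    "AdversarialConfig",
    "batch_objective",
    "ips_policy_gradient",
    "learn_policy",
    "learn_policy_adversarial",
    "evaluate_learned_policy",
    "action_confusion",
    "PolicyLearner",
    "AdversarialPolicyLearner",
    "LearningResults",
]


@dataclass
class LearnConfig:
    """Settings for counterfactual policy optimization.

    ``loss`` selects IPS or SNIPS weighting; ``variant`` selects how an
    ensemble of behaviour models enters the objective.  Defaults follow the
    dosing recipe: 100 epochs, learning rate 1e-3, minibatch 50.
    """

    loss: str = "ips"
    variant: str = "single"
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 50
    policy_arch: str = "linear-softmax"
    hidden_units: int = 20
    adam_betas: tuple[float, float] = (0.999, 0.9)

    def __post_init__(self) -> None:
        if self.loss not in ("ips", "snips"):
            raise ValueError("loss must be 'ips' or 'snips'")
        if self.variant not in ("single", "avg", "inv"):
            raise ValueError("variant must be 'single', 'avg' or 'inv'")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.policy_arch not in ("linear-softmax", "mlp-softmax"):
            raise ValueError("policy_arch must be 'linear-softmax' or 'mlp-softmax'")


@dataclass
class AdversarialConfig:
    """Settings for the adversarial (worst-case behaviour model) learner.

    ``lambda_tradeoff`` balances the adversary's two goals: imputing the
    clinician's actions accurately (cross-entropy term) versus depressing the
    policy's estimated reward.  lambda = 1 is the default; the adversary is
    warm-started by ``warmup_epochs`` of plain cross-entropy training.
    """

    lambda_tradeoff: float = 1.0
    warmup_epochs: int = 4
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 50
    policy_arch: str = "linear-softmax"
    hidden_units: int = 20
    adam_betas: tuple[float, float] = (0.999, 0.9)
    h0_steps: int = 1
    h_steps: int = 1

    def __post_init__(self) -> None:
        if self.lambda_tradeoff < 0:
            raise ValueError("lambda_tradeoff must be >= 0")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")


def _make_policy_net(
    d: int, K: int, arch: str, hidden: int, rng: np.random.Generator
) -> SoftmaxNet:
    if arch == "linear-softmax":
        return LinearNet(d, K, rng, init_scale=0.01)
    return MLP(d, hidden, K, rng)


def _wrap_policy(net: SoftmaxNet) -> StochasticPolicy:
    if isinstance(net, LinearNet):
        return LinearSoftmaxPolicy(net.W, net.b)
    return MLPSoftmaxPolicy(net)


def batch_objective(
    net: SoftmaxNet,
    X: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    prop: np.ndarray,
    loss: str = "ips",
    variant: str = "single",
) -> tuple[float, list[np.ndarray]]:
    """Objective value and its ascent gradient for one minibatch.

    ``prop`` is a vector of per-record behaviour propensities for
    ``variant in ('single', 'avg')`` (for ``avg`` pass the member mean), or
    the (M, B) member propensity matrix for ``variant == 'inv'``.

    The gradient of every variant reduces to sum_i c_i * grad p(a_i|x_i)
    for per-record coefficients ``c_i``; through the softmax this becomes a
    logit-space upstream gradient c_i * p_i(a_i) * (onehot(a_i) - P_i).
    """
    X = np.atleast_2d(X)
    a = np.asarray(actions, dtype=int)
    r = np.asarray(rewards, dtype=float)
    B = len(a)
    P = net.predict_proba(X)
    p_a = P[np.arange(B), a]

    prop = np.asarray(prop, dtype=float)
    if variant == "inv":
        if prop.ndim != 2:
            raise ValueError("variant 'inv' needs the (M, B) member matrix")
        Q = prop  # (M, B)
        if loss == "ips":
            # mean over members of per-member IPS; linear in p_a
            inv_q = (1.0 / Q).mean(axis=0)
            value = float(np.mean(p_a * r * inv_q))
            c = r * inv_q / B
        else:
            # mean over members of per-member SNIPS ratios
            W = p_a[None, :] / Q  # (M, B)
            sums = W.sum(axis=1)
            if np.any(sums <= 0):
                raise ValueError("zero total importance weight in a member")
            R_m = (W * r[None, :]).sum(axis=1) / sums
            value = float(R_m.mean())
            c = ((r[None, :] - R_m[:, None]) / (Q * sums[:, None])).mean(axis=0)
    else:
        if prop.ndim != 1:
            raise ValueError("variants 'single'/'avg' need a per-record vector")
        q = prop
        w = p_a / q
        if loss == "ips":
            value = float(np.mean(w * r))
            c = r / (q * B)
        else:
            s = w.sum()
            if s <= 0:
                raise ValueError("zero total importance weight")
            value = float(np.sum(w * r) / s)
            c = (r - value) / (q * s)

    Gz = (c * p_a)[:, None] * (one_hot(a, net.n_out) - P)
    grads = net.grad_from_logits(X, Gz)
    if not all(np.all(np.isfinite(g)) for g in grads):
        bad = [int(i) for i in np.where(~np.isfinite(c * p_a))[0][:5]]
        raise FloatingPointError(f"non-finite policy gradient (records {bad})")
    return value, grads


def ips_policy_gradient(
    D: LoggedBandit,
    net: SoftmaxNet,
    p_h0: np.ndarray,
    minibatch: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Ascent gradient of the minibatch IPS objective w.r.t. policy params."""
    idx = np.arange(D.n) if minibatch is None else np.asarray(minibatch)
    _, grads = batch_objective(
        net, D.contexts[idx], D.actions[idx], D.rewards[idx],
        np.asarray(p_h0)[idx], loss="ips", variant="single",
    )
    return grads


def _resolve_propensity_source(
    D: LoggedBandit, source, variant: str
) -> np.ndarray:
    """Vector for single/avg variants; (M, n) matrix for inv."""
    if isinstance(source, PropensityEnsemble):
        mat = ensemble_propensity(source, D)
        if variant == "inv":
            return mat
        return mat.mean(axis=0)
    p = np.asarray(source, dtype=float)
    if np.any(p <= 0):
        raise ValueError("behaviour propensities must be strictly positive")
    p = np.clip(p, PROPENSITY_FLOOR, None)
    if p.ndim == 2:
        return p if variant == "inv" else p.mean(axis=0)
    if variant == "inv":
        return p[None, :]
    return p


def learn_policy(
    D: LoggedBandit,
    propensity_source,
    cfg: LearnConfig | None = None,
    seed: int = 0,
) -> tuple[StochasticPolicy, list[float]]:
    """Maximize the selected counterfactual objective by minibatch ascent.

    ``propensity_source`` may be a per-record propensity vector, an (M, n)
    member matrix, or a fitted :class:`PropensityEnsemble`.  Returns the
    learned policy and the per-epoch full-data objective trace.
    """
    cfg = cfg or LearnConfig()
    rng = np.random.default_rng(seed)
    net = _make_policy_net(D.d, D.n_actions, cfg.policy_arch, cfg.hidden_units, rng)
    prop = _resolve_propensity_source(D, propensity_source, cfg.variant)
    if np.any(prop <= 0):
        raise ValueError("behaviour propensities must be strictly positive")
    opt = AdamOptimizer(net.params, lr=cfg.learning_rate, betas=cfg.adam_betas)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(D.n)
        for k in range(0, D.n, cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            pb = prop[:, idx] if cfg.variant == "inv" else prop[idx]
            try:
                _, grads = batch_objective(
                    net, D.contexts[idx], D.actions[idx], D.rewards[idx],
                    pb, cfg.loss, cfg.variant,
                )
            except FloatingPointError as exc:
                raise FloatingPointError(f"diverged at epoch {epoch}: {exc}") from exc
            opt.step(net.params, [-g for g in grads])  # ascent
        value, _ = batch_objective(
            net, D.contexts, D.actions, D.rewards, prop, cfg.loss, cfg.variant
        )
        trace.append(value)
    return _wrap_policy(net), trace


def learn_policy_adversarial(
    D: LoggedBandit,
    cfg: AdversarialConfig | None = None,
    h0_hidden: int = 20,
    seed: int = 0,
) -> tuple[StochasticPolicy, MLP, dict[str, list[float]]]:
    """Adversarial policy optimization against a worst-case behaviour model.

    The adversary ``h0`` (an MLP classifier of logged actions) is warm-started
    with ``warmup_epochs`` of cross-entropy training, then the two players
    alternate per minibatch: ``h0`` descends ``R(h, h0) + lambda * CE`` and
    the policy ``h`` ascends ``R(h, h0)``.  Returns the policy, the final
    adversarial behaviour model, and per-epoch traces of the reward objective
    and the adversary's cross-entropy.
    """
    cfg = cfg or AdversarialConfig()
    rng = np.random.default_rng(seed)
    h0 = MLP(D.d, h0_hidden, D.n_actions, rng)
    h_net = _make_policy_net(D.d, D.n_actions, cfg.policy_arch, cfg.hidden_units, rng)
    opt0 = AdamOptimizer(h0.params, lr=cfg.learning_rate, betas=cfg.adam_betas)
    opth = AdamOptimizer(h_net.params, lr=cfg.learning_rate, betas=cfg.adam_betas)

    # warm start: plain imputation so the adversary begins near a plausible h0
    for _ in range(cfg.warmup_epochs):
        order = rng.permutation(D.n)
        for k in range(0, D.n, cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            opt0.step(h0.params, h0.nll_grads(D.contexts[idx], D.actions[idx]))

    traces: dict[str, list[float]] = {"reward_objective": [], "h0_cross_entropy": []}
    arange = np.arange
    for epoch in range(cfg.epochs):
        order = rng.permutation(D.n)
        for k in range(0, D.n, cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            Xb, ab, rb = D.contexts[idx], D.actions[idx], D.rewards[idx]
            B = len(ab)
            # --- adversary: descend R(h, h0) + lambda * CE ------------------
            for _ in range(cfg.h0_steps):
                p_h = h_net.prob_of(Xb, ab)
                P0 = h0.predict_proba(Xb)
                q = np.clip(P0[arange(B), ab], PROPENSITY_FLOOR, None)
                # dR/dq_i = -p_h r_i / q_i^2 ; chain through h0's softmax
                dR_dq = -p_h * rb / (q**2) / B
                Gz0 = (dR_dq * q)[:, None] * (one_hot(ab, D.n_actions) - P0)
                g_R = h0.grad_from_logits(Xb, Gz0)
                g_CE = h0.nll_grads(Xb, ab)
                grads0 = [
                    gr + cfg.lambda_tradeoff * gc for gr, gc in zip(g_R, g_CE)
                ]
                if not all(np.all(np.isfinite(g)) for g in grads0):
                    raise FloatingPointError(f"adversary diverged at epoch {epoch}")
                opt0.step(h0.params, grads0)
            # --- policy: ascend R(h, h0) -----------------------------------
            for _ in range(cfg.h_steps):
                q = np.clip(h0.prob_of(Xb, ab), PROPENSITY_FLOOR, None)
                _, grads = batch_objective(
                    h_net, Xb, ab, rb, q, loss="ips", variant="single"
                )
                opth.step(h_net.params, [-g for g in grads])
        q_all = np.clip(h0.prob_of(D.contexts, D.actions), PROPENSITY_FLOOR, None)
        value, _ = batch_objective(
            h_net, D.contexts, D.actions, D.rewards, q_all, "ips", "single"
        )
        traces["reward_objective"].append(value)
        traces["h0_cross_entropy"].append(h0.nll(D.contexts, D.actions))
    return _wrap_policy(h_net), h0, traces


def evaluate_learned_policy(
    h: StochasticPolicy,
    test,
    mode: str = "ground-truth",
    labels: np.ndarray | None = None,
    propensity_source=None,
) -> float:
    """Reward of a learned policy on held-out data.

    ``ground-truth`` mode needs labelled contexts (``test`` is the feature
    matrix, ``labels`` the true actions) and returns argmax-action accuracy,
    ties broken toward the lowest action index.  ``snips`` mode needs a
    held-out :class:`LoggedBandit` plus a propensity source and returns the
    SNIPS estimate of ``h`` on that log.
    """
    if mode == "ground-truth":
        X = np.atleast_2d(np.asarray(test, float))
        if labels is None:
            raise ValueError("ground-truth mode requires labels")
        pred = h.greedy_actions(X)
        return float(np.mean(pred == np.asarray(labels, int)))
    if mode == "snips":
        D: LoggedBandit = test
        if propensity_source is None:
            if D.logged_propensity is None:
                raise ValueError("snips mode requires a propensity source")
            q = D.logged_propensity
        else:
            q = _resolve_propensity_source(D, propensity_source, "single")
        return snips_estimator(D, h, q).estimate
    raise ValueError("mode must be 'ground-truth' or 'snips'")


def action_confusion(
    h: StochasticPolicy, X: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """K x K matrix of predicted-action counts as percentages of row totals.

    Rows index the true action, columns the policy's argmax action; each row
    with at least one observation sums to 100.  Rows for actions absent from
    the labels are NaN (undefined), not zero.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(labels, dtype=int)
    K = h.n_actions
    pred = h.greedy_actions(X)
    M = np.full((K, K), np.nan)
    for a in range(K):
        row = pred[y == a]
        if len(row):
            M[a] = 100.0 * np.bincount(row, minlength=K) / len(row)
    return M


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


@dataclass
class LearningResults:
    """Fitted policy plus training diagnostics."""

    policy: StochasticPolicy
    trace: list[float] = field(default_factory=list)
    traces: dict[str, list[float]] | None = None
    adversary: MLP | None = None
    config: object | None = None
    seed: int = 0

    @property
    def final_objective(self) -> float | None:
        if self.trace:
            return self.trace[-1]
        if self.traces:
            return self.traces["reward_objective"][-1]
        return None

    def evaluate(self, test, mode="ground-truth", **kw) -> float:
        return evaluate_learned_policy(self.policy, test, mode=mode, **kw)

    def summary(self) -> str:
        cfg = self.config
        lines = ["Counterfactual policy learning"]
        if cfg is not None:
            lines.append(f"  config: {cfg}")
        lines.append(f"  seed: {self.seed}")
        fo = self.final_objective
        if fo is not None:
            lines.append(f"  final objective: {fo:.4f}")
        if self.traces is not None:
            lines.append(
                f"  final adversary cross-entropy: "
                f"{self.traces['h0_cross_entropy'][-1]:.4f}"
            )
        return "\n".join(lines)


class PolicyLearner:
    """Counterfactual policy optimization as a model object.

    ``PolicyLearner(D, propensity_source, cfg).fit(seed)`` returns a
    :class:`LearningResults` carrying the learned policy and the per-epoch
    objective trace.
    """

    def __init__(self, data: LoggedBandit, propensity_source, cfg: LearnConfig | None = None):
        self.data = data
        self.propensity_source = propensity_source
        self.cfg = cfg or LearnConfig()

    def fit(self, seed: int = 0) -> LearningResults:
        policy, trace = learn_policy(self.data, self.propensity_source, self.cfg, seed)
        return LearningResults(policy=policy, trace=trace, config=self.cfg, seed=seed)


class AdversarialPolicyLearner:
    """Worst-case (adversarial behaviour model) policy optimization."""

    def __init__(self, data: LoggedBandit, cfg: AdversarialConfig | None = None,
                 h0_hidden: int = 20):
        self.data = data
        self.cfg = cfg or AdversarialConfig()
        self.h0_hidden = h0_hidden

    def fit(self, seed: int = 0) -> LearningResults:
        policy, h0, traces = learn_policy_adversarial(
            self.data, self.cfg, h0_hidden=self.h0_hidden, seed=seed
        )
        return LearningResults(
            policy=policy, traces=traces, adversary=h0, config=self.cfg, seed=seed
        )
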