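"""Study runners: evaluation-error simulation, bootstrap-count sweep,
policy-learning comparison.

Each runner repeats a full pipeline — simulate a logging policy, convert the
labelled table to a bandit log, impute the behaviour policy, estimate or
learn — over ``n_simulations`` independent seeds and aggregates the results
into a report dict (JSON-serializable) that embeds the resolved
configuration and every seed used, so any report can be reproduced exactly.

Per-component seeds are derived from the per-simulation seed by a fixed
offset table (`_COMPONENT_OFFSETS`), so adding an estimator or method to a
study does not shift the randomness of the others.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .bandit_core import LoggedBandit, StochasticPolicy
from .estimators import (
    ESTIMATOR_REGISTRY,
    _ENSEMBLE_ESTIMATORS,
    evaluation_error,
    ips,
    snips,
)
from .logging_policies import LoggingSimConfig, fit_lr_logging_policy, supervised_to_bandit
from .nnet import TrainConfig
from .policy_learning import (
    AdversarialConfig,
    LearnConfig,
    action_confusion,
    evaluate_learned_policy,
    learn_policy,
    learn_policy_adversarial,
)
from .propensity import (
    PROPENSITY_FLOOR,
    bootstrap_ensemble,
    fit_behavior_model,
    fit_bnn_vi,
    mc_dropout_ensemble,
)

__all__ = [
    "ExperimentConfig",
    "run_evaluation_study",
    "run_bootstrap_sweep",
    "run_learning_study",
]

_COMPONENT_OFFSETS = {
    "logging": 101,
    "conversion": 211,
    "subsample": 307,
    "propensity": 401,
    "learning": 503,
    "adversarial": 601,
}


def _component_seed(sim_seed: int, component: str) -> int:
    return int((sim_seed * 1009 + _COMPONENT_OFFSETS[component]) % (2**31 - 1))


@dataclass
class ExperimentConfig:
    """Resolved settings of a study run.

    Defaults follow the dosing-study design: 20 evaluation / 10 learning
    simulations, 70% evaluation subsample, 70/30 train-test split for
    learning, 10 ensemble members, LR logging policy fitted on 5% subsamples.
    """

    n_simulations: int = 20
    eval_subsample: float = 0.70
    test_split: float = 0.30
    members: int = 10
    estimators: tuple[str, ...] = (
        "ips", "snips", "ips_avg", "ips_inv", "snips_avg", "snips_inv"
    )
    uncertainty: str = "nn-ensemble"
    resample_data: bool = True
    base_seed: int = 0
    logging_cfg: LoggingSimConfig = field(default_factory=LoggingSimConfig)
    propensity_cfg: TrainConfig = field(default_factory=TrainConfig)
    learn_cfg: LearnConfig = field(default_factory=LearnConfig)
    adversarial_cfg: AdversarialConfig = field(default_factory=AdversarialConfig)
    include_adversarial: bool = True

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        for f in (self.eval_subsample, self.test_split):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must be in (0, 1)")
        unknown = set(self.estimators) - set(ESTIMATOR_REGISTRY)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _expected_match_reward(h: StochasticPolicy, X: np.ndarray, y: np.ndarray) -> float:
    """Exact expected match reward of a stochastic policy on labelled rows."""
    return float(np.mean(h.prob_of(X, y)))


def _fit_target_policy(X: np.ndarray, y: np.ndarray) -> StochasticPolicy:
    from sklearn.linear_model import LogisticRegression

    from .bandit_core import LinearSoftmaxPolicy

    lr = LogisticRegression(max_iter=1000)
    lr.fit(X, y)
    K = int(np.max(y)) + 1
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
    return LinearSoftmaxPolicy(W, b)


def _build_ensemble(D: LoggedBandit, cfg: ExperimentConfig, seed: int):
    if cfg.uncertainty == "nn-ensemble":
        return bootstrap_ensemble(
            D, cfg.propensity_cfg, M=cfg.members,
            resample_data=cfg.resample_data, base_seed=seed,
        )
    if cfg.uncertainty == "mc-dropout":
        model = fit_behavior_model(D, cfg.propensity_cfg, seed)
        return mc_dropout_ensemble(model, M=cfg.members, seed=seed)
    if cfg.uncertainty == "bnn-vi":
        return fit_bnn_vi(D, cfg=cfg.propensity_cfg, seed=seed, M=cfg.members)
    raise ValueError(f"unknown uncertainty method {cfg.uncertainty!r}")


def run_evaluation_study(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ExperimentConfig | None = None,
    use_true_propensities: bool = False,
) -> dict:
    """Policy-evaluation error study.

    Per simulation: fit the (perturbed, 5%-subsample) LR logging policy,
    convert the labelled table to a bandit log, subsample the evaluation
    fraction, fit the target policy on the full labelled data (its exact
    expected match reward is the ground truth R(h)), impute the behaviour
    policy, and compute every configured estimator.  Reports per-estimator
    MAE, RMSE and across-simulation sd of the estimates.

    With ``use_true_propensities`` the single-model ``ips``/``snips``
    columns use the simulator's exact logged propensities instead of a
    fitted model (the consistency benchmark).
    """
    cfg = cfg or ExperimentConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=int)
    h = _fit_target_policy(X, y)

    estimates: dict[str, list[float]] = {e: [] for e in cfg.estimators}
    truths: list[float] = []
    sim_seeds = [cfg.base_seed + s for s in range(cfg.n_simulations)]
    for seed in sim_seeds:
        logging = fit_lr_logging_policy(
            X, y, cfg.logging_cfg, _component_seed(seed, "logging")
        )
        D_full = supervised_to_bandit(X, y, logging, _component_seed(seed, "conversion"))
        rng = np.random.default_rng(_component_seed(seed, "subsample"))
        idx = rng.choice(D_full.n, size=int(round(cfg.eval_subsample * D_full.n)),
                         replace=False)
        D = D_full.subset(idx)
        truths.append(_expected_match_reward(h, X, y))

        ens = None
        if any(e in _ENSEMBLE_ESTIMATORS for e in cfg.estimators):
            ens = _build_ensemble(D, cfg, _component_seed(seed, "propensity"))
        single_p = None
        for name in cfg.estimators:
            if name in _ENSEMBLE_ESTIMATORS:
                res = ESTIMATOR_REGISTRY[name](D, h, ens)
            else:
                if single_p is None:
                    if use_true_propensities:
                        single_p = D.logged_propensity
                    else:
                        model = fit_behavior_model(
                            D, cfg.propensity_cfg, _component_seed(seed, "propensity")
                        )
                        single_p = np.clip(
                            model.prob_of(D.contexts, D.actions), PROPENSITY_FLOOR, 1.0
                        )
                res = ESTIMATOR_REGISTRY[name](D, h, single_p)
            estimates[name].append(res.estimate)

    table = {}
    for name, est in estimates.items():
        mae, rmse, sd = evaluation_error(np.asarray(est), float(np.mean(truths)))
        table[name] = {"mae": mae, "rmse": rmse, "sd": sd,
                       "estimates": [float(v) for v in est]}
    return {
        "study": "evaluation",
        "config": cfg.to_dict(),
        "sim_seeds": sim_seeds,
        "truth": float(np.mean(truths)),
        "per_estimator": table,
    }


def run_bootstrap_sweep(
    X: np.ndarray,
    y: np.ndarray,
    M_values: Sequence[int] = (1, 5, 10),
    cfg: ExperimentConfig | None = None,
    estimators: Sequence[str] = ("snips_avg", "snips_inv"),
) -> dict:
    """Evaluation error as a function of the bootstrap (ensemble) count M.

    Runs the evaluation study once per M with identical simulation seeds, so
    rows differ only in ensemble size.
    """
    if not M_values:
        raise ValueError("M_values must be nonempty")
    cfg = cfg or ExperimentConfig()
    rows = []
    for M in M_values:
        from dataclasses import replace

        sub = replace(cfg, members=int(M), estimators=tuple(estimators))
        rep = run_evaluation_study(X, y, sub)
        for name in estimators:
            e = rep["per_estimator"][name]
            rows.append({"M": int(M), "estimator": name,
                         "mae": e["mae"], "rmse": e["rmse"], "sd": e["sd"]})
    return {
        "study": "bootstrap_sweep",
        "config": cfg.to_dict(),
        "M_values": [int(m) for m in M_values],
        "rows": rows,
    }


def run_learning_study(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ExperimentConfig | None = None,
    losses: Sequence[tuple[str, str]] = (
        ("ips", "single"), ("ips", "inv"), ("ips", "avg")
    ),
) -> dict:
    """Policy-learning comparison on a labelled (semi-synthetic) task.

    Per simulation: 70/30 train-test split; a bandit log is built on the
    training side under the LR logging policy; one policy per configured
    loss (plus the adversarial learner) is trained on the log; each is
    scored by ground-truth argmax accuracy on the held-out test rows.
    Reports mean +/- sd rewards and the action-confusion matrix of the first
    simulation's policies.
    """
    cfg = cfg or ExperimentConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=int)
    n = len(y)
    names = [f"{l}_{v}" if v != "single" else l for l, v in losses]
    if cfg.include_adversarial:
        names.append("adversarial")
    rewards: dict[str, list[float]] = {name: [] for name in names}
    confusions: dict[str, list] = {}
    sim_seeds = [cfg.base_seed + s for s in range(cfg.n_simulations)]
    for s_i, seed in enumerate(sim_seeds):
        rng = np.random.default_rng(_component_seed(seed, "subsample"))
        perm = rng.permutation(n)
        n_test = int(round(cfg.test_split * n))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        logging = fit_lr_logging_policy(
            Xtr, ytr, cfg.logging_cfg, _component_seed(seed, "logging")
        )
        D = supervised_to_bandit(Xtr, ytr, logging, _component_seed(seed, "conversion"))
        ens = _build_ensemble(D, cfg, _component_seed(seed, "propensity"))
        mean_p = None
        for (loss, variant), name in zip(losses, names):
            from dataclasses import replace

            lc = replace(cfg.learn_cfg, loss=loss, variant=variant)
            source = ens
            if variant == "single":
                if mean_p is None:
                    mean_p = np.clip(
                        ens.members[0].predict_proba(D.contexts)[
                            np.arange(D.n), D.actions
                        ],
                        PROPENSITY_FLOOR, 1.0,
                    )
                source = mean_p
            policy, _ = learn_policy(D, source, lc, _component_seed(seed, "learning"))
            r = evaluate_learned_policy(policy, Xte, mode="ground-truth", labels=yte)
            rewards[name].append(r)
            if s_i == 0:
                confusions[name] = action_confusion(policy, Xte, yte).tolist()
        if cfg.include_adversarial:
            policy, _, _ = learn_policy_adversarial(
                D, cfg.adversarial_cfg, seed=_component_seed(seed, "adversarial")
            )
            r = evaluate_learned_policy(policy, Xte, mode="ground-truth", labels=yte)
            rewards["adversarial"].append(r)
            if s_i == 0:
                confusions["adversarial"] = action_confusion(policy, Xte, yte).tolist()

    table = {
        name: {
            "mean_reward": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "rewards": [float(x) for x in v],
        }
        for name, v in rewards.items()
    }
    return {
        "study": "learning",
        "config": cfg.to_dict(),
        "sim_seeds": sim_seeds,
        "per_loss": table,
        "confusion_matrices": confusions,
    }
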