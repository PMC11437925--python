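"""Behaviour-policy imputation with model-uncertainty quantification.

Clinicians do not record the probability with which they chose a treatment,
so the behaviour policy ``h0`` must be imputed from the log by treating the
logged actions as multiclass labels and reading propensities off the softmax
layer of a classifier.  With limited clinical data many different networks
fit equally well yet disagree off the training points; the three ensembling
strategies here turn that model uncertainty into a *set* of propensity
models:

* bootstrapped NN ensembles (reseeded initialization + minibatch order,
  optionally with data resampling),
* MC-dropout (stochastic forward passes of a single dropout-trained net),
* variational Bayesian networks trained by Bayes-by-backprop, from whose
  weight posterior member networks are sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandit_core import LoggedBandit
from .nnet import (
    MLP,
    BayesByBackpropNet,
    ScaleMixturePrior,
    TrainConfig,
    train_classifier,
)

__all__ = [
    "PROPENSITY_FLOOR",
    "PropensityModelConfig",
    "BNNPriorConfig",
    "PropensityEnsemble",
    "fit_behavior_model",
    "bootstrap_ensemble",
    "mc_dropout_samples",
    "mc_dropout_ensemble",
    "fit_bnn_vi",
    "ensemble_propensity",
]

#: Floor applied to extracted propensities.  This guards divisions against
#: numerically-zero softmax outputs and is deliberately far below any
#: plausible weight cap, which remains an explicit estimator option.
PROPENSITY_FLOOR = 1e-6

# The propensity model shares the classifier training recipe.
PropensityModelConfig = TrainConfig

# Prior over BNN weights: scale mixture of two zero-mean Gaussians.
BNNPriorConfig = ScaleMixturePrior


class _MCDropoutMember:
    """A single MC-dropout ensemble member: the trained net plus a mask seed.

    Each call draws the dropout mask stream from the member's own seed, so a
    member is a deterministic function of its inputs while distinct members
    apply distinct masks.
    """

    def __init__(self, net: MLP, mask_seed: int):
        if net.dropout_rate <= 0:
            raise ValueError("MC-dropout requires a network trained with dropout > 0")
        self.net = net
        self.mask_seed = int(mask_seed)
        self.n_out = net.n_out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.mask_seed)
        return self.net.mc_predict_proba(X, rng)


@dataclass
class PropensityEnsemble:
    """M fitted behaviour-policy models plus how they were produced.

    ``kind`` is one of ``nn-ensemble``, ``mc-dropout``, ``bnn-vi``.  The
    ensemble's pooled prediction is the arithmetic mean of member
    probabilities.
    """

    members: list
    kind: str
    member_seeds: list[int] = field(default_factory=list)
    resampled_data: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_actions(self) -> int:
        return self.members[0].n_out

    def member_proba(self, X: np.ndarray) -> np.ndarray:
        """(M, n, K) tensor of member probabilities."""
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Pooled prediction p(a|x) = (1/M) sum_m p_m(a|x)."""
        return self.member_proba(X).mean(axis=0)


def fit_behavior_model(
    D: LoggedBandit,
    cfg: PropensityModelConfig | None = None,
    seed: int = 0,
) -> MLP:
    """Fit one single-hidden-layer softmax classifier of logged actions."""
    cfg = cfg or PropensityModelConfig()
    return train_classifier(D.contexts, D.actions, cfg, seed, n_out=D.n_actions)


def _resample(D: LoggedBandit, rng: np.random.Generator) -> LoggedBandit:
    idx = rng.integers(0, D.n, size=D.n)
    return D.subset(idx)


def bootstrap_ensemble(
    D: LoggedBandit,
    cfg: PropensityModelConfig | None = None,
    M: int = 10,
    resample_data: bool = True,
    base_seed: int = 0,
    max_retries: int = 20,
) -> PropensityEnsemble:
    """Bootstrap ``M`` behaviour models with seeds in multiples of 2.

    Member ``m`` trains with seed ``base_seed + 2m``, which reseeds both the
    weight initialization and the minibatch order; with ``resample_data`` it
    also refits on an n-with-replacement resample of ``D``.  A resample that
    happens to drop an entire action class is redrawn (bounded retries).
    """
    if M < 1:
        raise ValueError("ensemble size M must be >= 1")
    cfg = cfg or PropensityModelConfig()
    members, seeds = [], []
    for m in range(M):
        seed = base_seed + 2 * m
        Dm = D
        if resample_data:
            rng = np.random.default_rng(seed)
            Dm = _resample(D, rng)
            tries = 0
            while len(np.unique(Dm.actions)) < 2:
                tries += 1
                if tries > max_retries:
                    raise ValueError(
                        "could not draw a bootstrap resample containing at "
                        "least two action classes"
                    )
                Dm = _resample(D, rng)
        members.append(fit_behavior_model(Dm, cfg, seed))
        seeds.append(seed)
    return PropensityEnsemble(
        members=members, kind="nn-ensemble", member_seeds=seeds,
        resampled_data=resample_data,
    )


def mc_dropout_samples(
    model: MLP, X: np.ndarray, M: int, seed: int = 0
) -> np.ndarray:
    """(M, n, K) tensor of stochastic forward passes with dropout active.

    The mask stream is seeded, so the same ``seed`` reproduces the same
    samples exactly.
    """
    if model.dropout_rate <= 0:
        raise ValueError("model was trained without dropout; nothing to sample")
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, float))
    return np.stack([model.mc_predict_proba(X, rng) for _ in range(M)])


def mc_dropout_ensemble(model: MLP, M: int, seed: int = 0) -> PropensityEnsemble:
    """Wrap one dropout-trained net as an M-member ensemble of masked nets."""
    seeds = [seed + m for m in range(M)]
    members = [_MCDropoutMember(model, s) for s in seeds]
    return PropensityEnsemble(members=members, kind="mc-dropout", member_seeds=seeds)


def fit_bnn_vi(
    D: LoggedBandit,
    prior: BNNPriorConfig | None = None,
    cfg: PropensityModelConfig | None = None,
    seed: int = 0,
    M: int = 10,
    independent_posteriors: bool = False,
    epochs: int | None = None,
) -> PropensityEnsemble:
    """Variational Bayesian behaviour model; returns M sampled member nets.

    By default M networks are drawn from a single mean-field posterior;
    with ``independent_posteriors`` M separate BNNs are trained (seeds in
    multiples of 2, data resampled per member) and one network is sampled
    from each.
    """
    prior = prior or BNNPriorConfig()
    cfg = cfg or PropensityModelConfig()
    epochs = cfg.max_epochs if epochs is None else epochs
    members, seeds = [], []
    if independent_posteriors:
        for m in range(M):
            s = seed + 2 * m
            rng = np.random.default_rng(s)
            Dm = _resample(D, rng)
            tries = 0
            while len(np.unique(Dm.actions)) < 2:
                tries += 1
                if tries > 20:
                    raise ValueError("bootstrap resample lost an action class")
                Dm = _resample(D, rng)
            bnn = BayesByBackpropNet(
                Dm.d, cfg.hidden_units, Dm.n_actions, prior, rng
            )
            bnn.fit(
                Dm.contexts, Dm.actions, epochs=epochs, lr=cfg.learning_rate,
                batch_size=cfg.batch_size, betas=cfg.adam_betas, seed=s,
            )
            members.append(bnn.sample_network(np.random.default_rng(s + 1)))
            seeds.append(s)
    else:
        rng = np.random.default_rng(seed)
        bnn = BayesByBackpropNet(D.d, cfg.hidden_units, D.n_actions, prior, rng)
        bnn.fit(
            D.contexts, D.actions, epochs=epochs, lr=cfg.learning_rate,
            batch_size=cfg.batch_size, betas=cfg.adam_betas, seed=seed,
        )
        draw_rng = np.random.default_rng(seed + 1)
        members = [bnn.sample_network(draw_rng) for _ in range(M)]
        seeds = [seed] * M
    return PropensityEnsemble(members=members, kind="bnn-vi", member_seeds=seeds)


def ensemble_propensity(E: PropensityEnsemble, D: LoggedBandit) -> np.ndarray:
    """(M, n) matrix: member m's probability of the logged action a_i at x_i.

    Entries are floored at :data:`PROPENSITY_FLOOR` so downstream importance
    weights stay finite even for actions a member assigns ~zero mass.
    """
    P = E.member_proba(D.contexts)  # (M, n, K)
    idx = np.arange(D.n)
    mat = P[:, idx, D.actions]
    return np.clip(mat, PROPENSITY_FLOOR, 1.0)
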