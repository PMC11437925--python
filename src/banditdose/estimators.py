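"""Counterfactual (off-policy) reward estimators and bootstrapped evaluation.

Given a log ``D = {(x_i, a_i, r_i)}`` collected under a behaviour policy
``h0``, the expected reward ``R(h)`` of a different target policy ``h`` is
estimated by importance weighting:

    IPS      R^(h) = (1/n) sum_i  [p_h(a_i|x_i) / p_h0(a_i|x_i)] r_i
    capped   denominator replaced by max(M, p_h0)          (0 < M < 1)
    SNIPS    R^(h) = sum_i r_i w_i / sum_i w_i             (self-normalized)

When ``h0`` is imputed by an ensemble of M bootstrapped models, two
combinations of the per-member propensities are available:

    IPS_avg  per-record denominator = arithmetic mean of member propensities
    IPS_inv  average of the M per-member IPS estimates, i.e. a harmonic-mean
             denominator per record

and likewise ``SNIPS_avg`` / ``SNIPS_inv``.  The across-member spread yields
a percentile confidence interval for the estimate (bootstrapped evaluation).

The statsmodels-style entry point is :class:`PolicyEvaluation`:
``PolicyEvaluation(D, h).fit()`` returns an :class:`EvaluationResults` with
the point estimates, confidence intervals and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .bandit_core import EstimateResult, LoggedBandit, StochasticPolicy
from .propensity import (
    PropensityEnsemble,
    PropensityModelConfig,
    bootstrap_ensemble,
    ensemble_propensity,
    fit_behavior_model,
    fit_bnn_vi,
    mc_dropout_ensemble,
)

__all__ = [
    "EstimatorConfig",
    "direct_method",
    "ips",
    "capped_ips",
    "snips",
    "ips_avg",
    "ips_inv",
    "snips_avg",
    "snips_inv",
    "balance_heuristic",
    "bootstrapped_evaluation",
    "evaluation_error",
    "ESTIMATOR_REGISTRY",
    "PolicyEvaluation",
    "EvaluationResults",
]


@dataclass
class EstimatorConfig:
    """Options shared by the estimators.

    ``cap_M`` activates weight capping (denominator ``max(M, p_h0)``) and
    must lie strictly inside (0, 1); smaller caps mean less bias but more
    variance.  Confidence intervals are percentile intervals over per-member
    estimates at level ``ci_level``.
    """

    cap_M: float | None = None
    ci_level: float = 0.95
    ci_method: str = "percentile"

    def __post_init__(self) -> None:
        if self.cap_M is not None and not (0.0 < self.cap_M < 1.0):
            raise ValueError("cap_M must lie in the open interval (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


def _validate_propensities(p_h0: np.ndarray) -> np.ndarray:
    p = np.asarray(p_h0, dtype=float)
    if np.any(p <= 0):
        raise ValueError(
            "overlap violation: behaviour-policy propensity of a logged "
            "action is <= 0; IPS-type estimators require p_h0(a_i|x_i) > 0"
        )
    return p


def _weights(D: LoggedBandit, h: StochasticPolicy, p_h0: np.ndarray) -> np.ndarray:
    p_h = h.prob_of(D.contexts, D.actions)
    return p_h / _validate_propensities(p_h0)


def direct_method(
    D: LoggedBandit,
    h: StochasticPolicy,
    reward_model: Callable[[np.ndarray, int], np.ndarray],
) -> EstimateResult:
    """Regression-adjustment estimate: average of sum_a p_h(a|x_i) r^(x_i, a).

    ``reward_model(X, a)`` must return the predicted reward of action ``a``
    at every row of ``X``.
    """
    P = h.predict_proba(D.contexts)
    total = np.zeros(D.n)
    for a in range(D.n_actions):
        rhat = np.asarray(reward_model(D.contexts, a), dtype=float)
        if rhat.shape != (D.n,):
            raise ValueError(f"reward model returned wrong shape for action {a}")
        total += P[:, a] * rhat
    return EstimateResult(float(np.mean(total)), "direct_method")


def ips(D: LoggedBandit, h: StochasticPolicy, p_h0: np.ndarray) -> EstimateResult:
    """Inverse propensity scoring, normalized by n."""
    w = _weights(D, h, p_h0)
    return EstimateResult(float(np.mean(w * D.rewards)), "ips", weights=w)


def capped_ips(
    D: LoggedBandit, h: StochasticPolicy, p_h0: np.ndarray, cap_M: float
) -> EstimateResult:
    """IPS with the denominator floored at ``cap_M`` (variance for bias)."""
    if not 0.0 < cap_M < 1.0:
        raise ValueError("cap_M must lie in (0, 1)")
    p = _validate_propensities(p_h0)
    w = h.prob_of(D.contexts, D.actions) / np.maximum(cap_M, p)
    return EstimateResult(float(np.mean(w * D.rewards)), "capped_ips", weights=w)


def snips(D: LoggedBandit, h: StochasticPolicy, p_h0: np.ndarray) -> EstimateResult:
    """Self-normalized IPS: a convex combination of the observed rewards."""
    w = _weights(D, h, p_h0)
    s = w.sum()
    if s <= 0:
        raise ValueError("all importance weights are zero; SNIPS undefined")
    return EstimateResult(float(np.sum(w * D.rewards) / s), "snips", weights=w)


def ips_avg(
    D: LoggedBandit, h: StochasticPolicy, E: PropensityEnsemble
) -> EstimateResult:
    """IPS with the per-record denominator averaged across ensemble members."""
    mat = ensemble_propensity(E, D)  # (M, n)
    p_bar = mat.mean(axis=0)
    res = ips(D, h, p_bar)
    per_member = np.array([ips(D, h, mat[m]).estimate for m in range(E.size)])
    return EstimateResult(
        res.estimate, "ips_avg", per_member=per_member, weights=res.weights
    )


def ips_inv(
    D: LoggedBandit, h: StochasticPolicy, E: PropensityEnsemble
) -> EstimateResult:
    """Mean of per-member IPS estimates (harmonic-mean denominator)."""
    mat = ensemble_propensity(E, D)
    per_member = np.array([ips(D, h, mat[m]).estimate for m in range(E.size)])
    # diagnostic weights: per-record average of member weights
    p_h = h.prob_of(D.contexts, D.actions)
    w = (p_h[None, :] / mat).mean(axis=0)
    return EstimateResult(
        float(per_member.mean()), "ips_inv", per_member=per_member, weights=w
    )


def snips_avg(
    D: LoggedBandit, h: StochasticPolicy, E: PropensityEnsemble
) -> EstimateResult:
    """SNIPS computed with averaged-propensity weights."""
    mat = ensemble_propensity(E, D)
    res = snips(D, h, mat.mean(axis=0))
    per_member = np.array([snips(D, h, mat[m]).estimate for m in range(E.size)])
    return EstimateResult(
        res.estimate, "snips_avg", per_member=per_member, weights=res.weights
    )


def snips_inv(
    D: LoggedBandit, h: StochasticPolicy, E: PropensityEnsemble
) -> EstimateResult:
    """Mean of per-member SNIPS estimates."""
    mat = ensemble_propensity(E, D)
    per_member = np.array([snips(D, h, mat[m]).estimate for m in range(E.size)])
    p_h = h.prob_of(D.contexts, D.actions)
    w = (p_h[None, :] / mat).mean(axis=0)
    return EstimateResult(
        float(per_member.mean()), "snips_inv", per_member=per_member, weights=w
    )


def balance_heuristic(
    parts: Sequence[LoggedBandit],
    h: StochasticPolicy,
    part_propensities: Sequence[np.ndarray],
) -> EstimateResult:
    """Multiple-importance-sampling estimate with the mixture denominator.

    Each sub-log ``parts[k]`` (size ``N_k``) carries its own behaviour-policy
    model; record i of part k contributes

        p_h(a_i|x_i) r_i / sum_j (N_j / N) p_0^j(a_i|x_i)

    averaged over all N records.  With equal part sizes and identical
    records this reduces to ``ips_avg``; with K = 1 it is plain IPS.
    """
    if len(parts) != len(part_propensities):
        raise ValueError("need one propensity model output per part")
    sizes = np.array([p.n for p in parts])
    N = int(sizes.sum())
    total = 0.0
    all_w = []
    for k, Dk in enumerate(parts):
        pk = np.asarray(part_propensities[k], dtype=float)  # (K_parts, N_k)
        if pk.shape != (len(parts), Dk.n):
            raise ValueError(
                "part_propensities[k] must be (n_parts, N_k): every part's "
                "model evaluated on part k's records"
            )
        _validate_propensities(pk)
        denom = (sizes[:, None] * pk).sum(axis=0) / N
        p_h = h.prob_of(Dk.contexts, Dk.actions)
        w = p_h / denom
        all_w.append(w)
        total += float(np.sum(w * Dk.rewards))
    return EstimateResult(
        total / N, "balance_heuristic", weights=np.concatenate(all_w)
    )


ESTIMATOR_REGISTRY: dict[str, Callable] = {
    "ips": ips,
    "snips": snips,
    "ips_avg": ips_avg,
    "ips_inv": ips_inv,
    "snips_avg": snips_avg,
    "snips_inv": snips_inv,
}

_ENSEMBLE_ESTIMATORS = {"ips_avg", "ips_inv", "snips_avg", "snips_inv"}


def _percentile_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrapped_evaluation(
    D: LoggedBandit,
    h: StochasticPolicy,
    estimator: str = "snips_avg",
    ensemble: PropensityEnsemble | None = None,
    M: int = 10,
    uncertainty: str = "nn-ensemble",
    propensity_cfg: PropensityModelConfig | None = None,
    resample_data: bool = True,
    ci_level: float = 0.95,
    seed: int = 0,
) -> EstimateResult:
    """Bootstrapped policy evaluation: fit an ensemble, estimate, attach a CI.

    The confidence interval is the percentile interval over the M per-member
    estimates — for the ``avg`` estimators too, where it serves as the
    uncertainty band around the pooled point estimate.
    """
    if estimator not in _ENSEMBLE_ESTIMATORS:
        raise ValueError(
            f"unknown ensemble estimator {estimator!r}; "
            f"choose from {sorted(_ENSEMBLE_ESTIMATORS)}"
        )
    if ensemble is None:
        if uncertainty == "nn-ensemble":
            ensemble = bootstrap_ensemble(
                D, propensity_cfg, M=M, resample_data=resample_data, base_seed=seed
            )
        elif uncertainty == "mc-dropout":
            model = fit_behavior_model(D, propensity_cfg, seed)
            ensemble = mc_dropout_ensemble(model, M=M, seed=seed)
        elif uncertainty == "bnn-vi":
            ensemble = fit_bnn_vi(D, cfg=propensity_cfg, seed=seed, M=M)
        else:
            raise ValueError(f"unknown uncertainty method {uncertainty!r}")
    res = ESTIMATOR_REGISTRY[estimator](D, h, ensemble)
    lo, hi = _percentile_ci(res.per_member, ci_level)
    res.ci_low, res.ci_high = lo, hi
    return res


def evaluation_error(
    estimates: np.ndarray, truth: float
) -> tuple[float, float, float]:
    """(MAE, RMSE, sd) of estimates around the true policy value.

    The standard deviation uses the sample (n-1) convention; with a single
    estimate it is reported as 0.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one estimate")
    err = est - truth
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sd = float(np.std(est, ddof=1)) if est.size > 1 else 0.0
    return mae, rmse, sd


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class PolicyEvaluation:
    """Off-policy evaluation of a target policy on a logged bandit dataset.

    Parameters
    ----------
    data : LoggedBandit
        The log collected under the (unknown) behaviour policy.
    policy : StochasticPolicy
        The target policy ``h`` whose expected reward is wanted.
    estimators : sequence of str
        Names from the estimator registry.  Plain ``ips``/``snips`` use the
        logged propensities when the data carry them, otherwise a single
        fitted behaviour model; ensemble estimators share one fitted
        ensemble.
    uncertainty : {"nn-ensemble", "mc-dropout", "bnn-vi"}
        How the behaviour-model ensemble is produced.

    ``fit(seed=...)`` performs the imputation and estimation and returns an
    :class:`EvaluationResults`.
    """

    def __init__(
        self,
        data: LoggedBandit,
        policy: StochasticPolicy,
        estimators: Sequence[str] = ("ips", "snips", "ips_avg", "ips_inv",
                                     "snips_avg", "snips_inv"),
        uncertainty: str = "nn-ensemble",
        n_members: int = 10,
        resample_data: bool = True,
        propensity_cfg: PropensityModelConfig | None = None,
        estimator_cfg: EstimatorConfig | None = None,
    ):
        unknown = set(estimators) - set(ESTIMATOR_REGISTRY)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")
        self.data = data
        self.policy = policy
        self.estimators = tuple(estimators)
        self.uncertainty = uncertainty
        self.n_members = n_members
        self.resample_data = resample_data
        self.propensity_cfg = propensity_cfg
        self.estimator_cfg = estimator_cfg or EstimatorConfig()

    @classmethod
    def from_dataframe(cls, df, policy, n_actions=None, **kwargs):
        """Build from a dataframe in the logged-bandit dialect."""
        import pandas as pd

        feat = [c for c in df.columns if c.startswith("x")]
        D = LoggedBandit(
            contexts=df[feat].to_numpy(float),
            actions=df["action"].to_numpy(),
            rewards=df["reward"].to_numpy(float),
            logged_propensity=df["propensity"].to_numpy(float)
            if "propensity" in df.columns
            else None,
            n_actions=n_actions,
        )
        return cls(D, policy, **kwargs)

    def _single_propensities(self, seed: int) -> np.ndarray:
        if self.data.logged_propensity is not None:
            return self.data.logged_propensity
        model = fit_behavior_model(self.data, self.propensity_cfg, seed)
        from .propensity import PROPENSITY_FLOOR

        return np.clip(
            model.prob_of(self.data.contexts, self.data.actions),
            PROPENSITY_FLOOR, 1.0,
        )

    def fit(self, seed: int = 0) -> "EvaluationResults":
        D, h = self.data, self.policy
        need_ensemble = any(e in _ENSEMBLE_ESTIMATORS for e in self.estimators)
        ensemble = None
        if need_ensemble:
            if self.uncertainty == "nn-ensemble":
                ensemble = bootstrap_ensemble(
                    D, self.propensity_cfg, M=self.n_members,
                    resample_data=self.resample_data, base_seed=seed,
                )
            elif self.uncertainty == "mc-dropout":
                model = fit_behavior_model(D, self.propensity_cfg, seed)
                ensemble = mc_dropout_ensemble(model, M=self.n_members, seed=seed)
            elif self.uncertainty == "bnn-vi":
                ensemble = fit_bnn_vi(
                    D, cfg=self.propensity_cfg, seed=seed, M=self.n_members
                )
            else:
                raise ValueError(f"unknown uncertainty method {self.uncertainty!r}")
        single_p = None
        results: dict[str, EstimateResult] = {}
        for name in self.estimators:
            if name in _ENSEMBLE_ESTIMATORS:
                res = ESTIMATOR_REGISTRY[name](D, h, ensemble)
                res.ci_low, res.ci_high = _percentile_ci(
                    res.per_member, self.estimator_cfg.ci_level
                )
            else:
                if single_p is None:
                    single_p = self._single_propensities(seed)
                if name == "ips" and self.estimator_cfg.cap_M is not None:
                    res = capped_ips(D, h, single_p, self.estimator_cfg.cap_M)
                else:
                    res = ESTIMATOR_REGISTRY[name](D, h, single_p)
            results[name] = res
        return EvaluationResults(self, results, ensemble, seed)


class EvaluationResults:
    """Container for fitted :class:`PolicyEvaluation` output."""

    def __init__(self, model, results, ensemble, seed):
        self.model = model
        self.results: dict[str, EstimateResult] = results
        self.ensemble = ensemble
        self.seed = seed

    def __getitem__(self, name: str) -> EstimateResult:
        return self.results[name]

    @property
    def estimates(self) -> dict[str, float]:
        return {k: v.estimate for k, v in self.results.items()}

    def to_dict(self) -> dict:
        return {k: v.to_dict() for k, v in self.results.items()}

    def summary(self) -> str:
        lines = [
            "Off-policy evaluation",
            f"  n = {self.model.data.n}, K = {self.model.data.n_actions}, "
            f"uncertainty = {self.model.uncertainty}, "
            f"members = {self.model.n_members}, seed = {self.seed}",
            "",
            f"{'estimator':<12}{'estimate':>10}{'ci_low':>10}{'ci_high':>10}"
            f"{'max_w':>10}{'ESS':>10}",
        ]
        for name, r in self.results.items():
            ci_lo = "" if r.ci_low is None else f"{r.ci_low:10.4f}"
            ci_hi = "" if r.ci_high is None else f"{r.ci_high:10.4f}"
            mw = "" if r.max_weight is None else f"{r.max_weight:10.3f}"
            ess = (
                ""
                if r.effective_sample_size is None
                else f"{r.effective_sample_size:10.1f}"
            )
            lines.append(
                f"{name:<12}{r.estimate:10.4f}{ci_lo:>10}{ci_hi:>10}{mw:>10}{ess:>10}"
            )
        return "\n".join(lines)
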