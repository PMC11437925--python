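"""Synthetic benchmark generators.

These stand in for the external sources the dosing studies draw on (UCI
classification tables, pharmacogenomic warfarin records, ICU heparin logs)
while keeping every ground truth computable:

* :func:`make_classification_task` — Gaussian-blob multiclass data with a
  Monte-Carlo Bayes-accuracy oracle from the known generator;
* :func:`make_discrete_task` — a *small discrete context grid* whose label
  distribution is tabulated, so the true value ``R(h)`` of any policy is an
  exact finite sum (the enumeration oracle the estimator tests rely on);
* :func:`make_dosing_cohort` — an ICU-style cohort with covariates, a
  continuous dose, and an aPTT response that is monotone in dose with
  patient-specific sensitivity (an emulation device, not a pharmacological
  model);
* :func:`apply_cohort_filters` — the three-step exclusion chain
  (aPTT present, complete covariates, not transferred) with per-step counts.

Every generator is seed-deterministic and carries a provenance block.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .bandit_core import LoggedBandit, StochasticPolicy

__all__ = [
    "GENERATOR_VERSION",
    "ClassificationTask",
    "make_classification_task",
    "DiscreteTask",
    "make_discrete_task",
    "CohortParams",
    "make_dosing_cohort",
    "apply_cohort_filters",
    "optimal_heparin_dose",
]

GENERATOR_VERSION = "1.0"


def _provenance(name: str, seed: int, params: dict) -> dict:
    return {
        "generator": name,
        "version": GENERATOR_VERSION,
        "seed": int(seed),
        "params": params,
    }


class ClassificationTask(NamedTuple):
    """A labelled table plus a Monte-Carlo Bayes-accuracy oracle."""

    X: np.ndarray
    y: np.ndarray
    bayes_accuracy: Callable[[int, int], float]
    provenance: dict


def make_classification_task(
    n: int, d: int = 5, K: int = 3, class_separation: float = 2.0, seed: int = 0
) -> ClassificationTask:
    """Equal-prior Gaussian blobs with unit isotropic covariance.

    Class means are placed ``class_separation`` apart along random
    orthonormal directions; the Bayes rule is therefore nearest-mean, and
    ``bayes_accuracy(n_mc, seed)`` estimates its accuracy by Monte Carlo from
    the generator itself.
    """
    if not (n >= K >= 2):
        raise ValueError("need n >= K >= 2")
    if d < 1 or class_separation < 0:
        raise ValueError("invalid dimensions or separation")
    rng = np.random.default_rng(seed)
    # random orthonormal directions via QR; K may exceed d, then reuse columns
    A = rng.standard_normal((d, max(d, K)))
    Q, _ = np.linalg.qr(A[:, :d])
    dirs = np.stack([Q[:, k % d] * (1 + k // d) for k in range(K)])
    means = class_separation * dirs  # (K, d)
    y = rng.integers(0, K, size=n)
    X = means[y] + rng.standard_normal((n, d))

    def bayes_accuracy(n_mc: int = 100_000, mc_seed: int = 0) -> float:
        r = np.random.default_rng(mc_seed)
        yy = r.integers(0, K, size=n_mc)
        xx = means[yy] + r.standard_normal((n_mc, d))
        d2 = ((xx[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        return float(np.mean(np.argmin(d2, axis=1) == yy))

    prov = _provenance(
        "classification_blobs", seed,
        {"n": n, "d": d, "K": K, "class_separation": class_separation},
    )
    return ClassificationTask(X, y, bayes_accuracy, prov)


@dataclass
class DiscreteTask:
    """Finite context grid with tabulated label probabilities.

    ``context_points`` is a (C, d) matrix of distinct contexts, drawn with
    probabilities ``context_probs``; the label at context c is categorical
    with probabilities ``label_probs[c]``.  Because everything is finite,
    the match-reward value of any policy is the exact double sum

        R(h) = sum_c p(c) sum_a h(a|x_c) p(y=a|c).
    """

    context_points: np.ndarray
    context_probs: np.ndarray
    label_probs: np.ndarray
    provenance: dict

    @property
    def n_contexts(self) -> int:
        return self.context_points.shape[0]

    @property
    def n_actions(self) -> int:
        return self.label_probs.shape[1]

    def sample(self, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        c = rng.choice(self.n_contexts, size=n, p=self.context_probs)
        u = rng.random(n)
        y = (self.label_probs[c].cumsum(axis=1) < u[:, None]).sum(axis=1)
        return self.context_points[c], y

    def exact_policy_value(self, h: StochasticPolicy) -> float:
        """Exact expected match reward of ``h`` by enumeration."""
        H = h.predict_proba(self.context_points)  # (C, K)
        return float(np.sum(self.context_probs[:, None] * H * self.label_probs))

    def sample_log(
        self, n: int, logging: StochasticPolicy, seed: int = 0
    ) -> LoggedBandit:
        """A bandit log under ``logging`` with exact logged propensities."""
        X, y = self.sample(n, seed)
        rng = np.random.default_rng(seed + 1)
        a = logging.sample_actions(X, rng)
        return LoggedBandit(
            contexts=X,
            actions=a,
            rewards=(a == y).astype(float),
            logged_propensity=logging.prob_of(X, a),
            n_actions=self.n_actions,
        )


def make_discrete_task(
    n_contexts: int = 8, d: int = 2, K: int = 3, concentration: float = 1.0,
    seed: int = 0,
) -> DiscreteTask:
    """Random enumerable task: Dirichlet label distributions on a small grid."""
    if n_contexts < 1 or K < 2:
        raise ValueError("need n_contexts >= 1 and K >= 2")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_contexts, d))
    cp = rng.dirichlet(np.full(n_contexts, 5.0))
    lp = rng.dirichlet(np.full(K, concentration), size=n_contexts)
    prov = _provenance(
        "discrete_grid", seed,
        {"n_contexts": n_contexts, "d": d, "K": K, "concentration": concentration},
    )
    return DiscreteTask(pts, cp, lp, prov)


# ---------------------------------------------------------------------------
# Dosing cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortParams:
    """Parameters of the synthetic ICU dosing cohort.

    The aPTT response is a logistic curve in dose,

        aPTT(dose) = base + amplitude * sigmoid((dose - midpoint) / width),

    with the patient-specific ``midpoint`` shifted by weight, renal function
    (creatinine, ESRD) and obesity — heavier patients need more drug, renal
    impairment potentiates it.  Multiplicative lognormal noise with scale
    ``noise_sd`` is applied on top.  Logged doses follow a weight-based rule
    with clinician-to-clinician scatter.
    """

    aptt_base: float = 30.0
    aptt_amplitude: float = 90.0
    response_width: float = 3.0
    midpoint_base: float = 8.0
    midpoint_per_kg: float = 0.06
    midpoint_esrd: float = -2.0
    midpoint_creatinine: float = -0.8
    midpoint_obesity: float = 1.0
    noise_sd: float = 0.12
    dose_policy_sd: float = 2.5
    aptt_missing_rate: float = 0.25
    covariate_missing_rate: float = 0.15
    transfer_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.response_width <= 0:
            raise ValueError("noise_sd must be >= 0 and response_width > 0")
        for r in (self.aptt_missing_rate, self.covariate_missing_rate,
                  self.transfer_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")


def _midpoint(df: pd.DataFrame, p: CohortParams) -> np.ndarray:
    """Patient-specific dose midpoint of the logistic aPTT response."""
    creat = np.nan_to_num(df["creatinine"].to_numpy(float), nan=1.0)
    return (
        p.midpoint_base
        + p.midpoint_per_kg * (df["weight"].to_numpy(float) - 80.0)
        + p.midpoint_esrd * df["esrd"].to_numpy(float)
        + p.midpoint_creatinine * (creat - 1.0)
        + p.midpoint_obesity * df["obesity"].to_numpy(float)
    )


def _mean_aptt(dose: np.ndarray, midpoint: np.ndarray, p: CohortParams) -> np.ndarray:
    z = (np.asarray(dose, float) - midpoint) / p.response_width
    return p.aptt_base + p.aptt_amplitude / (1.0 + np.exp(-z))


def optimal_heparin_dose(
    df: pd.DataFrame, params: CohortParams | None = None, target_aptt: float = 80.0
) -> np.ndarray:
    """Generator-optimal dose: solves mean aPTT(dose) = target exactly.

    Inverts the logistic response; the default target (80 s) is the centre
    of the 60-100 s therapeutic window, so at zero noise the reward of
    dosing optimally is 1 for every patient.
    """
    p = params or CohortParams()
    frac = (target_aptt - p.aptt_base) / p.aptt_amplitude
    if not 0.0 < frac < 1.0:
        raise ValueError("target aPTT outside the response range")
    return _midpoint(df, p) + p.response_width * np.log(frac / (1.0 - frac))


def make_dosing_cohort(
    n: int, seed: int = 0, params: CohortParams | None = None
) -> pd.DataFrame:
    """Generate the synthetic ICU heparin-dosing cohort.

    Returns a dataframe with demographic/physiological covariates, the
    continuous administered dose, the 6-hour aPTT (NaN when unmeasured), and
    the transfer flag; provenance is attached as ``df.attrs['provenance']``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(65, 15, n), 18, 95)
    sex = rng.integers(0, 2, n)
    height = np.where(sex == 1, rng.normal(176, 7, n), rng.normal(162, 7, n))
    bmi = np.clip(rng.lognormal(np.log(26), 0.18, n), 15, 55)
    weight = bmi * (height / 100.0) ** 2
    obesity = (bmi >= 30).astype(int)
    ethnicity = rng.integers(0, 4, n)
    esrd = (rng.random(n) < 0.08).astype(int)
    creatinine = np.clip(
        rng.lognormal(np.log(1.0), 0.4, n) + 2.5 * esrd * rng.random(n), 0.3, 12.0
    )
    sofa = rng.poisson(5, n)
    icu_type = rng.integers(0, 4, n)
    pulmonary_embolism = (rng.random(n) < 0.15).astype(int)
    transferred = (rng.random(n) < p.transfer_rate).astype(int)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "height": height,
            "weight": weight,
            "obesity": obesity,
            "ethnicity": ethnicity,
            "esrd": esrd,
            "creatinine": creatinine,
            "sofa": sofa,
            "icu_type": icu_type,
            "pulmonary_embolism": pulmonary_embolism,
            "transferred": transferred,
        }
    )

    # clinician dosing: weight-proportional with scatter, ignoring renal status
    dose = np.clip(
        0.11 * weight + rng.normal(0, p.dose_policy_sd, n), 1.0, 40.0
    )
    df["dose"] = dose
    mid = _midpoint(df, p)
    mean_aptt = _mean_aptt(dose, mid, p)
    if p.noise_sd > 0:
        aptt = mean_aptt * rng.lognormal(0.0, p.noise_sd, n)
    else:
        aptt = mean_aptt.copy()
    aptt_missing = rng.random(n) < p.aptt_missing_rate
    aptt[aptt_missing] = np.nan
    df["aptt_6h"] = aptt

    # missing covariates: MCAR over creatinine and height
    miss = rng.random(n) < p.covariate_missing_rate
    which = rng.random(n) < 0.5
    df.loc[miss & which, "creatinine"] = np.nan
    df.loc[miss & ~which, "height"] = np.nan

    df.attrs["provenance"] = _provenance("dosing_cohort", seed, asdict(p))
    return df


def apply_cohort_filters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three cohort exclusions in order, recording per-step counts.

    1. keep patients with a 6-hour aPTT measurement;
    2. drop patients with any missing covariate;
    3. drop patients transferred from another hospital.
    """
    counts = {"initial": len(cohort)}
    step1 = cohort[cohort["aptt_6h"].notna()]
    counts["with_aptt_6h"] = len(step1)
    covar_cols = [c for c in step1.columns if c not in ("aptt_6h",)]
    step2 = step1[step1[covar_cols].notna().all(axis=1)]
    counts["complete_covariates"] = len(step2)
    step3 = step2[step2["transferred"] == 0]
    counts["not_transferred"] = len(step3)
    return step3.reset_index(drop=True), counts
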