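# Methods

## Setting and notation

A logged contextual-bandit dataset D = {(xᵢ, aᵢ, rᵢ)}ⁿᵢ₌₁ records, per
patient, a context x ∈ ℝᵈ, one discrete action a ∈ {0, …, K−1} chosen by an
unknown behaviour policy h₀, and the reward r of that action only.  All
policies are maps x ↦ Δᴷ (a probability vector over actions); deterministic
clinical rules are point masses.  The value of a policy h is
R(h) = E_{x, a~h(·|x)}[r(x, a)].

## Estimators

With behaviour propensities q_i = p_{h₀}(aᵢ|xᵢ) and importance weights
wᵢ = p_h(aᵢ|xᵢ)/qᵢ:

* **IPS**: R̂ = (1/n) Σ wᵢ rᵢ.  Unbiased when the qᵢ are exact and overlap
  holds (qᵢ > 0 wherever p_h > 0); unbounded variance when weights blow up.
* **Capped IPS**: denominator max(M, qᵢ), 0 < M < 1.  Bias for variance.
* **SNIPS**: R̂ = Σ wᵢrᵢ / Σ wᵢ.  A convex combination of observed rewards,
  hence always inside [min r, max r], invariant to rescaling all weights,
  and resistant to propensity overfitting.
* **Direct method**: fit r̂(x, a) by regression and average
  Σ_a p_h(a|xᵢ) r̂(xᵢ, a).

When h₀ is imputed by an ensemble of M models with propensities q⁽ᵐ⁾ᵢ:

* **IPS_avg** uses the arithmetic-mean denominator (1/M) Σₘ q⁽ᵐ⁾ᵢ per
  record;
* **IPS_inv** averages the M per-member IPS estimates, equivalent to a
  harmonic-mean denominator.  By AM ≥ HM, for nonnegative rewards
  IPS_inv ≥ IPS_avg always (property-tested).
* **SNIPS_avg / SNIPS_inv**: the printed sources name these columns without
  formulas; here SNIPS_avg applies self-normalization to the
  averaged-propensity weights and SNIPS_inv averages per-member SNIPS
  estimates.  Both collapse to plain SNIPS for a degenerate ensemble and
  both return c exactly for constant reward c.
* **Balance heuristic**: K sub-logs of sizes N_k, each with its own
  behaviour model p₀ʲ, combined with the mixture denominator
  Σⱼ (Nⱼ/N) p₀ʲ(aᵢ|xᵢ); with equal part sizes it coincides with IPS_avg,
  with one part it is plain IPS.

As printed, the ensemble-estimator formulas omit the reward factor and the
logged-action subscripts inside the sums; they are implemented with rᵢ
multiplying every record term and all propensities evaluated at the logged
(xᵢ, aᵢ), which is the only reading under which they estimate reward and
reduce to plain IPS for M = 1.  The plain-IPS formula is likewise normalized
by n throughout (one printed variant drops the 1/n).

**Bootstrapped evaluation** fits the ensemble, computes the chosen
estimator, and reports the percentile interval (default 95%) of the M
per-member estimates as the uncertainty band; for `avg`-type estimators this
band is attached to the pooled point estimate.  Reported diagnostics: the
weight vector, its maximum, and the effective sample size (Σw)²/Σw².

## Behaviour-policy imputation and model uncertainty

Propensities are read off the softmax layer of a single-hidden-layer ReLU
classifier of logged actions.  Training: Adam with learning rate 1e-3,
minibatch 50, inverted dropout 0.25 on the hidden layer, 80/20
train/validation split with early stopping after 5 epochs without
validation-loss improvement (the patience is this package's choice; the
split follows the study design).  The Adam moment coefficients default to
(β₁, β₂) = (0.999, 0.9) — deliberately matching the training recipe as
printed even though it reverses the usual convention; the conventional
(0.9, 0.999) is one config field away.  Hidden width defaults to 20
(40 suits the larger dosing task).  Contexts are used as-is; callers who
need standardization apply it before constructing the log.

Three uncertainty mechanisms produce the ensemble:

* **NN ensemble** — member m trains with seed base+2m (reseeding both weight
  init and minibatch order) on an n-with-replacement resample of the log
  (resampling optional; resamples that lose an action class are redrawn,
  bounded retries).
* **MC-dropout** — one dropout-trained network, M stochastic forward passes;
  each ensemble member owns a mask seed so members are deterministic
  functions.  Dropout is applied after the hidden layer only (the placement
  is otherwise unspecified in the literature this follows).
* **BNN (Bayes-by-backprop)** — a mean-field Gaussian posterior
  q(w|θ) = Π N(wᵢ|μᵢ, σᵢ²), σ = softplus(ρ), trained by minimizing the
  single-sample Monte-Carlo estimate of log q(w) − log p(w) − log p(D|w)
  with the reparameterization trick; the prior is a scale mixture
  0.5 N(0, 0.5) + 0.5 N(0, 0.002).  The KL terms are scaled by
  batch/n so an epoch sums to the full objective.  M member networks are
  drawn from the posterior (or one from each of M independently trained
  posteriors — both constructions are exposed).

Extracted propensities are floored at ε = 1e-6.  This is a numerical guard
against division blow-ups, kept far below any plausible weight cap so that
capping remains a visible, deliberate estimator option.

## Policy learning

Policies are linear-softmax (default, interpretable) or one-hidden-layer
MLP-softmax networks trained by minibatch gradient ascent (same Adam recipe,
100 epochs) on one of six objectives: {IPS, SNIPS} × {single, avg, inv}.
The `inv` objective is the mean of per-member objectives (verified equal to
machine precision); `avg` uses mean-propensity denominators.  The SNIPS
objective is optimized as the *per-minibatch* self-normalized ratio — a
biased-per-batch surrogate for the full-data ratio, standard practice since
the exact ratio has no unbiased minibatch gradient.  All gradients are
analytic; the quotient-rule gradient of the SNIPS ratio reduces to
per-record coefficients (rᵢ − R̂_batch)/(qᵢ Σw), and every variant is checked
against central finite differences at relative error < 1e-3.

**Adversarial learner.**  The behaviour model h₀ (an MLP classifier) is
warm-started with 4 epochs of cross-entropy training, then the two players
alternate per minibatch — one h₀ descent step on R(h, h₀) + λ·CE(ĥ₀, h₀)
followed by one policy ascent step on R(h, h₀) (both step counts
configurable).  λ = 1 by default; the λ grid (0.5, 1, 1.5, 2) is available
as a sweep, not auto-selected.  The cross-entropy term is computed on the
minibatch.  Two sanity properties are enforced by tests: at λ → ∞ the
adversarial phase cannot degrade the imputation fit (held-out CE within 5%
of the warm start), and at λ = 0 the adversary inflates the propensities of
rewarded logged actions, measurably depressing the policy's achievable
objective relative to a run whose h₀ is frozen after warm start.  The
frozen-h₀ baseline is the same procedure with h₀ updates disabled
(`h0_steps=0`): a baseline that keeps CE-training h₀ is not "fixed" — the
continued fit itself lowers the objective — and does not isolate the
adversary's effect.

Evaluation of learned policies: on semi-synthetic tasks, argmax-action
accuracy against the known labels (ties broken toward the lowest action
index); on true bandit logs, the SNIPS estimate on a held-out log.  The
action-confusion matrix reports predicted counts as percentages of each true
action's total; rows for actions absent from the labels are undefined (NaN),
not zero.

## Simulated logging policies and clinical rules

* **LR expert**: multiclass logistic regression fit on a 5% random
  subsample of the training rows (resampled while single-class, bounded
  retries), then perturbed by i.i.d. standard-normal noise added to every
  coefficient (the per-coefficient choice is this package's; the sources do
  not specify the perturbation's granularity).
* **Mixture expert**: two user-supplied deterministic dosing rules followed
  with equal probability — the per-record uniform draw u ≤ 0.5 selects the
  first; the propensity is 0.5·I(h₁(x)=a) + 0.5·I(h₂(x)=a).  The published
  linear dosing formulas sometimes mixed this way carry coefficients from an
  external reference and are not reproduced; any deterministic pair plugs
  in.
* **Supervised→bandit conversion**: actions sampled from the logging
  policy, reward = label-match indicator, exact sampling propensity stored.
* **Dose discretizers**: warfarin weekly dose < 21 → low, 21–49 inclusive →
  medium, > 49 → high; heparin thresholds 10 and 15 with the same boundary
  convention.  The heparin thresholds are treated as unit-agnostic numbers:
  the printed "mg/wk" unit is clinically implausible for IV heparin and is
  recorded, not corrected.
* **Heparin reward**: 1 iff 60 s ≤ aPTT(6 h) ≤ 100 s, inclusive at both
  ends.

## Synthetic generators — what they emulate and what they do not

* `make_classification_task`: equal-prior isotropic Gaussian blobs with
  controllable class separation; Bayes accuracy is Monte-Carlo computable
  from the generator (nearest-mean rule).  Stands in for generic multiclass
  benchmarks used in supervised→bandit conversion.
* `make_discrete_task`: a finite context grid with Dirichlet-tabulated label
  probabilities, so R(h) of *any* policy is an exact finite sum.  This is
  the enumeration oracle behind the unbiasedness and coverage tests.
* `make_dosing_cohort`: ICU-style covariates (age, sex, height, weight/BMI,
  obesity, ethnicity, creatinine, ESRD, SOFA, ICU type, pulmonary embolism,
  transfer flag), a weight-proportional logged dose with clinician scatter,
  and an aPTT response that is a logistic curve in dose with
  patient-specific midpoint (shifted by weight, renal function, obesity)
  times lognormal noise (scale 0.12).  The functional form is an *emulation
  device* chosen to be monotone in dose with heterogeneous sensitivity; it
  is not a pharmacokinetic model, and none of the covariate distributions
  claim clinical validity.  Missingness is missing-completely-at-random at a
  configurable rate (0.15 across creatinine/height), aPTT is unmeasured for
  25% of patients, 10% are transfers — so the three-step exclusion chain
  (aPTT present → complete covariates → not transferred) has non-trivial
  per-step counts.  The generator-optimal dose inverts the logistic response
  at the window centre (80 s), giving an exact upper-bound dosing rule.

Passing tests on these generators therefore demonstrates estimator and
optimizer correctness under known ground truth — not clinical performance:
real cohorts add confounding beyond the recorded covariates, non-random
missingness, measurement error in aPTT timing, and behaviour policies far
from softmax-smooth.

## Study designs and problem sizes

The runners in `banditdose.experiments` mirror the dosing-study designs:
evaluation studies run 20 simulations, each refitting the logging policy on
a fresh 5% subsample, rebuilding the log, subsampling 70% for evaluation,
and fitting the propensity model(s) with the 80/20 early-stopping split;
learning studies run 10 simulations on 70/30 train/test splits with 10
ensemble members.  The ground truth R(h) of the evaluation target (a
multiclass-LR softmax policy fit on the full labelled data) is its *exact
expected match reward* E[p_h(y|x)] rather than argmax accuracy: IPS-type
estimators estimate the expected reward of the stochastic policy actually
evaluated, and an argmax-accuracy "truth" would introduce a constant offset
unrelated to estimator quality.  Per-simulation seeds are base+index;
per-component seeds derive from them through a fixed offset table so adding
an estimator never shifts the randomness of the others.  Reports embed the
resolved configuration and all seeds; reruns reproduce them bit-for-bit.

The default sizes used by the test suite and `scripts/acceptance.py`
(n = 1000 contexts, d = 5, K = 3, 20 simulations, ensembles up to M = 10;
2,000 logs of n = 100 for the unbiasedness benchmark) were chosen as the
smallest sizes at which the Monte-Carlo standard errors are comfortably
below the effects being measured.

## Numerical choices

* Propensity floor ε = 1e-6 at ensemble-matrix extraction.
* Percentile confidence intervals (95% default) over per-member estimates.
* Sample (n−1) standard deviations everywhere.
* Argmax ties break toward the lowest action index.
* Softmax computed with max-shift stabilization; CSV round-trips use
  shortest-round-trip float formatting and exact float parsing.
* Estimator registry is keyed by name; unknown names are hard errors.
* Degenerate inputs (single-action logs, empty datasets, zero total SNIPS
  weight, non-finite losses) raise informative errors rather than returning
  numbers.

## Known limitations

* Doubly-robust and variance-regularized (POEM-style) objectives are out of
  scope, as are sequential/episodic treatments.
* The adversarial game uses alternating first-order steps; like all such
  schemes it can cycle for extreme λ/step-ratio choices, which is why the
  step schedule is exposed.
* BNN posteriors are mean-field Gaussian; their widths converge slowly at
  the default learning rate (the epistemic-contraction test documents the
  settings at which contraction with data is visible).
* The cohort generator's missingness is MCAR; informative missingness,
  common in ICU data, is deliberately not modelled.
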