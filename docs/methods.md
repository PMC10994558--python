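# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the open design decisions behind the package, in
the spirit of a model-description appendix.

## Task environment

Payouts follow a decaying (mean-reverting) Gaussian random walk per
bandit, an AR(1) process with decay `lambda`, attractor `theta`,
innovation SD `sigma_d`, and observation noise `sigma_o` added to the
latent mean before rounding and clipping to 0–100 points. Defaults
(`lambda = 0.9836, theta = 50, sigma_d = 2.8, sigma_o = 4`) are the
classic values for this paradigm; the study this package models reused
existing schedule instantiations that are not public, so two labelled
built-in seeds (`session_out`, `session_in`) play that role — they are
draws from the same process, not reconstructions. Initial means are drawn
from the walk's stationary distribution
`Normal(theta, sigma_d^2 / (1 - lambda^2))` (option: start at `theta`).
`diffusion_sd = 0` is accepted and yields the degenerate noise-free walk
pinned at `theta`, useful as a fixed-point check.

Units: values and payouts are points; `beta` is 1/points; `phi` is
logits per uncertainty unit; `rho` is logits. Bandits and trials are
0-based in memory and 1-based in every file and CLI surface.

## Learning rules

* **Delta rule** — constant-gain update of the chosen bandit only;
  unchosen values do not decay (a decay would add an extra free
  parameter). Prior value 50 for all bandits.
* **Bayesian (Kalman-filter) learner** — tracks each bandit's posterior
  mean and variance under the *known* walk dynamics: observation step for
  the chosen bandit (gain `s^2/(s^2 + sigma_o^2)`), then a prediction
  step for every bandit (mean decays toward `theta`; variance
  `s^2 <- lambda^2 s^2 + sigma_d^2`). Prior variance defaults to the
  stationary walk variance, so a never-chosen bandit's uncertainty sits
  exactly at the diffusion fixed point `sigma_d^2/(1-lambda^2)`; any
  perturbation contracts to it geometrically at rate `lambda^2 ≈ 0.967`
  per trial (about 280 trials per decade of error).

Missed trials: no choice, no outcome, no observation update; the
prediction step still runs (time passes for the walk) and recency
counters advance; the last *made* choice is retained for the
perseveration indicator, since no action occurred on the missed trial.

## Choice rules and the exploration bonus for the delta learner

The logit of bandit `c` is `beta*Q_c + phi*u_c + rho*1[c = last]`, with
the bonus terms entering additively outside `beta` (consistent with
`beta` being the weight on value, and with perseveration magnitudes of
order several logits). `u_c` is the posterior SD by default
(`bonus_on = "variance"` switches to the variance) for the Bayesian
learner.

The eight variants cross both learning rules with all four choice rules.
The delta learner tracks no variance, so its SME/SMEP variants use a
**recency proxy**: `u_c` = trials since bandit `c` was last chosen. This
keeps all eight architectures distinct and mirrors the classifier's
directed-exploration target for delta-rule models (below). The proxy is
on a trials scale rather than a points scale, so delta-rule `phi`
estimates are not numerically comparable to Bayesian ones.

## Choice classification

Using the beliefs holding *before* each trial:

* **exploit** — the chosen bandit attains the maximum estimated value
  (ties count as exploitation if the choice is any argmax; exact ties are
  measure-zero after the first outcome);
* **directed** — otherwise, the choice equals the single designated
  target among the non-best bandits: maximum posterior variance for the
  Bayesian learner, maximum recency for the delta learner (under the
  Bayesian learner with shared dynamics and equal priors these coincide).
  Ties break toward the lowest bandit index;
* **random** — any other lower-valued choice;
* **missed** — missed trials, excluded from all denominators.

Because the Bayesian belief trace along a recorded history does not
depend on the decision parameters, Bayesian classification is
parameter-free; delta-rule classification needs `alpha`.

Behavioural metrics: `p_best` scores the choice against the bandit with
the highest *latent scheduled mean* that trial (a property of the
generative schedule; a flag switches to the realized-payout ranking);
`p_stay` compares each valid choice to the last valid choice (the first
valid trial has no predecessor and is excluded from that denominator;
after a missed trial the comparison is to the last made choice);
`p_missed` divides by all trials. Blocks are trials 1–50, 51–100, …,
251–300.

## Fitting

Per-subject MAP over transformed parameters — `alpha` logit-transformed,
`beta` and `phi` log-transformed (a config flag allows negative `phi`,
i.e. uncertainty aversion, with an identity transform), `rho`
unconstrained — maximized by L-BFGS from 10 Latin-hypercube starts
(ties: best objective, then lowest start index). The objective is
log-likelihood plus the natural-scale log-prior, *without* the transform
Jacobian, so with flat priors the maximizer is exactly the MLE and
likelihood nesting across the model family is preserved. Default priors
are weakly informative: `alpha` flat on (0,1); `beta`, `phi` half-normal
(scales 1 and 2); `rho` normal (SD 5).

Uncertainty comes from a Laplace approximation at the mode: a
finite-difference Hessian, inverted with a ridge fallback, sampled and
mapped back to the natural scale. Marginal SDs on the transformed scale
are capped at 2.5: when a bonus parameter is effectively absent (e.g.
`phi ~ 0`), its log-scale direction is flat and the raw Laplace
covariance would be unbounded; the cap leaves identified parameters
untouched. `fit_posterior` provides the sampling alternative: an
affine-invariant ensemble sampler seeded around the MAP mode, with
split-chain R-hat and bulk ESS diagnostics (a failure is flagged, not
fatal). Likelihood evaluation exploits the parameter-independence of the
Bayesian belief trace (computed once per session; each likelihood
evaluation is a vectorized pass) and a linear-filter form of the
delta-rule trace, which is what keeps 1000+ fits per test run feasible.

Model comparison reports log-likelihood, AIC and BIC per variant and
ranks by BIC by default (the selection criterion used originally is not
stated). Group contrasts are differences of per-subject posterior means
with seeded bootstrap percentile intervals over subjects.

## Synthetic cohort

The generator emulates the study's structure: 22 HC / 28 PD-no-apathy /
25 PD-apathy, one 300-trial session each (a two-session mode reuses the
second built-in schedule), ~3% missed trials (2% HC), LARS scores in
[-36, 36] with the > -22 apathy convention.

Only the **group contrasts** are anchored to published estimates
(PD-apathy minus PD-no-apathy: `beta -0.02, phi -0.40, rho -3.57`; LARS
group means/SDs -28.1±3.6, -28.0±2.9, -14.0±5.2). Absolute parameter
levels are not published, so the anchor for HC/PD-no-apathy
(`beta = 0.15, phi = 0.5, rho = 3.6, alpha = 0.4`) is a calibration
choice: at these levels the simulated no-apathy group shows the study's
qualitative profile (best-bandit choice well above chance, strong
perseveration, exploit-dominant choices), and applying the printed
contrasts reproduces the directional group differences (lower
exploitation, stay probability and best-bandit choice, higher random
exploration in apathy). At substantially smaller `beta` or larger `phi`
the uncertainty bonus dominates the value term and those directions
invert — a useful reminder that classified choice-type proportions are a
joint property of all parameters, not of any single one.

LARS is drawn per group as
`mean + sd * ( -w*z + sqrt(1-w^2)*noise )`, where `z` is the subject's
standardized `beta + rho` composite within their group and `w = 0.5`, so
apathy scores correlate with behaviour through the parameters rather
than being independent noise.

What the generator does *not* emulate: reaction-time dynamics (RTs are
decorative lognormal draws), session-order or fatigue effects, parameter
correlations beyond the LARS loading, medication state, and any
neuroimaging quantity. Passing end-to-end tests therefore shows the
pipeline recovers what this generative family produces — not that real
patients obey the family.

## Recovery harnesses

*Parameter recovery* simulates one session per row of a dispersed
true-parameter table (`alpha` ~ U(0.15, 0.75), `beta` log-uniform on
(0.03, 0.3), `phi` uniform up to 1.5 (bayes) / 0.6 (delta), `rho`
U(0.5, 6)), refits, and reports Spearman correlation, bias and RMSE per
parameter. *Model recovery* uses separate, well-separated generating
regimes — notably `alpha` ~ U(0.15, 0.35), because a delta rule with
`alpha` near the Kalman steady-state gain (~0.5 on the default walk)
produces a nearly identical value trace and the two learning rules are
then genuinely non-identifiable. Model recovery asks whether the
architectures can be told apart where they are distinct; the parameter
ranges are part of that question's definition.

Default problem sizes (40 recovery subjects; 5 replicates per generating
variant in the confusion table; 5 cohort seeds for directional checks)
are chosen to keep a full validation run in the minutes range while
leaving comfortable statistical margins; all are configurable.

## Known limitations

* Fits are per-subject only; no hierarchical pooling across subjects
  (the original study's pooling structure is unstated). Contrast
  intervals are bootstrap-over-subjects, not joint posteriors.
* The Laplace summaries are Gaussian in the transformed space; for
  boundary-flat parameters they are regularized (capped) rather than
  exact.
* Whether the original exploration bonus multiplied the SD or the
  variance, and whether outcomes were rescaled before fitting, is not
  printed; both bonus forms are implemented (`bonus_on`), SD by default,
  and outcomes are used unrescaled.
* Delta-rule `phi` (recency proxy) is not unit-compatible with Bayesian
  `phi`.
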