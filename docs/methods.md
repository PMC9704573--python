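# Methods

## Task environment

The environment is the standard two-stage decision paradigm. Stage 1
offers two options; option `L` reaches stage-2 state 1 with probability
`p_common = 0.7` and state 2 otherwise (option `R` mirrored). Each of the
four (state, chest) slots pays a unit reward with a probability that
performs a Gaussian random walk with per-trial increment SD
`sigma_walk = 0.0275`, constrained to `[0.25, 0.75]`. Two walks start
uniformly in `[0.58, 0.72]` and two in `[0.31, 0.45]`; which slots get
the high band is randomised uniformly over the six possible pairings at
every initialisation, since nothing pins the assignment down and any
fixed choice would build a spurious asymmetry into simulated cohorts.

Boundary handling is by reflection (`x -> 2b - x` at a bound `b`,
iterated via a fold for arbitrarily large excursions). Reflection keeps
the stationary distribution spread over the interval instead of piling
mass at the bounds; clipping is available as `TaskConfig(boundary="clip")`
for sensitivity checks. A condition has 150 trials in two 75-trial
blocks; the two conditions of a session use independent walk
realisations (drawn from the subject's random stream in the order the
conditions are played), since within-subject walk sharing is a design
detail the task description leaves open.

Trials are 1-based and states labelled 1/2 in exported CSV logs;
internal arrays are 0-based throughout.

## Agent

Five parameters: learning rate `alpha` in (0,1), model-based and
model-free weights `beta_mb, beta_mf >= 0`, stage-2 inverse temperature
`beta_2`, perseveration `rho`. All value functions start at 0.5.

The update rule is implemented exactly as the decay-plus-reward form
`Q <- (1 - alpha) Q + r` at both stages. This is *not* the conventional
delta rule: its fixed point under constant unit reward is `1/alpha`, so
values are not bounded by 1, and `beta` parameters are therefore not
directly comparable to delta-rule fits from other studies. Because the
two forms genuinely differ (the delta rule scales the reward by `alpha`),
both are provided; `delta_rule=False` is the default and is what all
defaults, tests and recovery results use. Stage-1 model-based values
hard-code the true 0.7/0.3 transition weights (no learned transition
matrix, no eligibility traces); the perseveration indicator is 0 for
both options on the first trial of a condition; agent state resets
between conditions, matching the convention of fitting each condition as
a separate dataset.

## Likelihood and MAP fitting

The likelihood replays a trial log deterministically: stage-1 probability
from the combined MB/MF/perseveration logits, stage-2 probability from
the `beta_2` softmax, then the value updates with the observed reward.
Missing trials (any of choice1/choice2/reward absent) contribute no
likelihood term and trigger no update — the recorded outcome does not
exist, so pretending an update happened would inject information the
subject never received. Two implementations are kept deliberately: a
readable reference built from the agent-module operations (returns
per-trial terms) and a numba kernel that also returns the analytic
gradient, obtained by forward accumulation of `dQ/dalpha` through the
recursion (the other four gradients are softmax covariances). The two
routes agree to 1e-10 and the gradient matches finite differences to
~1e-5 relative; ties in the stage-2 `max` use the first index as the
subgradient, which only matters on a measure-zero set.

MAP fitting works on the unconstrained scale `alpha = expit(a)`,
`beta_mb = exp(b)`, `beta_mf = exp(c)`, `beta_2`, `rho`, with independent
normal priors (SDs 2.5, 1.5, 1.5, 10, 10) whose joint mode maps to
`(0.5, 1, 1, 0, 0)` — weak enough to leave 150-trial fits data-dominated
while regularising degenerate logs. Multi-start L-BFGS (default 3
starts); non-convergence of all starts is flagged, never raised.

## Hierarchical model

Each group x condition cell is fitted as its own hierarchical model.
For each parameter, subject values are group mean + group scale x
subject error (non-centred):

* `alpha`: built on the pre-logit scale, mean prior Normal(0, 2.5),
  errors Normal(0, 1), mapped by the inverse logit;
* `beta_mb`, `beta_mf`: group mean positive — prior Normal(0, 100)
  truncated at zero, sampled through a log transform with its Jacobian —
  and half-normal subject errors (`sigma |eps|`, an exact
  reparameterization of half-Normal(0,1)), so subject values stay
  non-negative;
* `beta_2`, `rho`: mean prior Normal(0, 100), errors Normal(0, 1);
* all scales half-Cauchy(0, 2.5), sampled on the log scale.

Composing the positive-mean constraint as truncation plus additive
half-normal errors follows the stated structure most literally; the
alternative (transforming a fully Gaussian hierarchy) changes the
implied subject distribution and was not used.

Sampling is an in-package No-U-Turn HMC sampler: canonical recursive
tree doubling with slice sampling, dual-averaging step-size adaptation
to a 0.8 target acceptance, a diagonal mass matrix re-estimated from the
middle 70% of warmup, and divergence flagging at a Hamiltonian error of
1000. Defaults are 4 chains x 2000 post-warmup draws after 2000 warmup.
A fit is `converged` only if every split-R-hat (all group-level
quantities and all per-subject constrained parameters) is below 1.1 and
divergences are under 10% of draws; flagged cells are excluded from
recovery averages with a warning. Per-subject point estimates are
posterior means across chains on the constrained scale. The sampler was
validated on anisotropic Gaussians (moments), against arviz's R-hat, and
by parameter recovery; it is a general-purpose implementation, not tied
to this model.

The `|eps|` half-normal trick leaves a gradient discontinuity on a
measure-zero set; in practice chains cross it freely and no divergences
result at the default target acceptance.

## Synthetic cohorts

The generator is the package's stand-in for a human sample: 32 HC + 35
ED subjects by default, half of each group playing NT first, 150 trials
per condition. Per-subject parameters are drawn per group x condition
cell: `beta_mb`/`beta_mf` truncated-normal at zero, `alpha` logit-normal,
`beta_2`/`rho` normal. Cell means encode the study-pattern of interest —
model-based weight lower in ED (1.42 vs 0.81 in NT) and further reduced
under BID in ED only (0.54; HC 1.64) — with the full table in
`cohort.DEFAULT_CELL_MEANS`. Between-subject SDs (0.96, 0.79, 0.8 on the
logit scale for alpha, 0.68, 0.5) were fixed once from the scale of the
corresponding group-level standard errors at n = 32 and are not tuned.
`rho`'s mean (1.0) is set from the overall stay-rate scale, as no fitted
value is reported for it anywhere.

Covariates (age, EAT-26, AAI, OCI-R totals) are drawn through a Gaussian
copula: the cohort-standardised `delta beta_mb` is mixed with
independent noise at the target correlation (defaults −0.147, −0.312,
−0.314, −0.316) and mapped to each group's mean/SD. Because group
membership also shifts both the covariates and `delta beta_mb`, the
realised cohort-wide correlation scatters around the target (tests allow
±0.25 at n = 67, the sampling error of r). Questionnaire totals are
generated as continuous values; real totals are discrete and bounded,
which the generator does not emulate — nor does it emulate reaction
times, attention lapses, or any within-session nonstationarity of the
parameters. Passing tests therefore demonstrate the correctness of the
analysis machinery on data *from the assumed model*, not the model's
adequacy for human data.

## Exclusions and pipeline

Default data-quality screens — more than 20% missing trials, or a
stage-1 repetition/alternation rate above 95% in any condition — are
package-defined stand-ins (the study-specific criteria are not public)
and are marked `canonical: false` in the pipeline manifest. Every
exclusion is logged with a reason; nothing is dropped silently. The
pipeline writes all tables as CSV plus a manifest with the seed and
settings; rerunning with the same config is byte-identical.

## Statistics

Stay probabilities condition on the previous trial's (reward,
transition) and are computed within blocks: the first trial after the
mid-condition break has no immediately preceding context, so the
cross-break pair is excluded (148 pairs per 150-trial condition). Cells
with empty denominators propagate as NaN and are excluded listwise from
MB-score averages. The regression design codes reward and transition as
+1/−1, z-scores age across the cohort, and leaves GLMM fitting to
standard mixed-model routines — the design matrix is the contract, the
solver is not.

Group t tests from summary statistics use the pooled-variance Student
form (df = n1 + n2 − 2), which reproduces the questionnaire and age
comparisons of the reference cohort to two decimals (the BMI row of that
table is not recoverable from its printed summaries under either pooled
or Welch variants and is excluded from checks). Power calculations use
the noncentral-t distribution exactly; required sample sizes are found
by scanning n upward, which is cheap and immune to approximation error.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced problem sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: 10⁵ draws for
environment rates (3 binomial SEs), 10⁵ increments for the walk SD (±2%
vs. a ~0.2% sampling SE), 80–200 simulated subjects for behavioural
signatures, and a 16-subjects-per-group, 2-chain x 500/500 sampler for
the recovery experiment (the full-scale protocol — 32/35 subjects,
4 chains x 2000/2000 — is the library default and runs in hours rather
than minutes; at desk scale the average recovery correlation typically
lands in the high 0.7s to high 0.8s, consistent with the full-scale
figure of ~0.83). Reflected-boundary folding, softmax max-subtraction,
and the ±30 clip on the pre-logit alpha scale are the only numerical
guards; none bind under typical parameter ranges.

## Known limitations

* The hierarchical sampler is single-threaded and pure Python around a
  compiled gradient; full-scale fits are minutes per cell, not seconds.
* No model comparison (AIC/BIC/LOO) — a single model family is fitted.
* The GLMM itself is delegated; coefficient magnitudes from variational
  or Laplace approximations of logistic mixed models differ slightly
  from likelihood-based R fits.
* Recovery quality depends on the generating ranges; with very low
  between-subject variance, correlations are undefined and reported as
  missing rather than imputed.
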