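# Methods

## The estimation problem

Causes of death for neonates (0–27 days) and children aged 1–59 months are
observed very unevenly across countries: high-quality vital registration
(VR) where it exists, verbal-autopsy (VA) studies elsewhere, and each VA
study reports its own cause list — some distinguish seven causes, others
lump several into a residual category. The pipeline estimates
cause-specific mortality fractions (CSMFs) for every country-year from
this heterogeneous evidence and converts them to death counts and rates
against an externally estimated all-cause mortality envelope.

## Model

For study *s* with covariate vector x_s, true-cause fractions follow a
multinomial logit with a study random effect:

    eta_sc = x_s' beta_c + u_sc,   eta for the base cause = 0
    p_s    = softmax(eta_s)

The study's binary aggregation ("misclassification") matrix G_s — rows are
its reported categories, columns the common true causes, each column
summing to one — maps true fractions to reported-category probabilities,
and observed counts are multinomial:

    y_s ~ Multinomial(N_s, G_s p_s)

G_s is not estimated; it is fully determined by which causes the study
reports. This lets one common set of true causes be modelled across
studies reporting different cause lists, while each study contributes
exactly the information its categories carry.

Priors:

- **Covariate effects** beta (non-intercept): independent
  Laplace(0, 1/lambda) — the Bayesian LASSO. lambda is fixed within a fit
  and selected by cross-validation (below).
- **Intercepts**: Normal(0, 10). Wide enough to be effectively flat for
  logit-scale intercepts; intercepts are deliberately not penalised.
- **Random effects** u_s: Normal(0, sigma), one shared sigma across cause
  contrasts by default (a per-contrast sigma is available via
  `PipelineConfig.per_contrast_sigma`).
- **sigma**: Uniform(0, bound]. The bound is 0.14 for high-mortality
  models — a one-SD study effect then shifts a cause's odds by at most
  ~15% (e^0.14 ≈ 1.15), keeping single studies from dominating a country —
  and 0.01 for low-mortality models, where representative VA studies are
  rare and random effects should carry almost no weight.

Reference (base) causes are fixed per fitted model: preterm birth
complications for the low-mortality neonatal model, intrapartum-related
events for the high-mortality neonatal model, and lower respiratory
infections for both child models; `check_reference_cause` enforces this at
fit time. The low-mortality neonatal model drops diarrhoea entirely
(neonatal diarrhoea deaths are taken as zero in low-mortality settings)
and the fraction is re-inserted as zero before model averaging.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs, chosen for portability (no
gradient machinery) and exactness (no approximation to the bounded-sigma
posterior):

- beta entries are updated one scalar at a time against the full-data
  likelihood;
- all study random-effect rows are updated in one vectorised step
  (acceptance is independent across studies because u_s only enters study
  s's likelihood);
- sigma is updated by Metropolis against its conditional
  sigma^(-M) exp(-SS/2 sigma^2) truncated to (0, bound].

All chains are propagated simultaneously through the same update schedule
(vectorised across the chain axis), which amortises numpy call overhead
and makes a 4-chain x 7500-iteration fit on 40 studies take well under a
minute on one CPU. Proposal scales adapt in batches of 50 iterations
during burn-in only (targets: 0.44 acceptance for scalar updates, 0.28
for random-effect rows) and are frozen afterwards, so retained draws come
from a valid Markov chain. Initial values are beta = 0, u = 0,
sigma = bound/2, jittered per chain; a non-finite initial posterior is
re-jittered up to a retry limit.

Convergence is assessed with the classic Gelman–Rubin potential scale
reduction factor (between-/within-chain variance ratio, not the split or
rank-normalised variant) on every parameter; fits used in the validation
suite reach PSRF < 1.1 throughout. Constant chains return PSRF = 1 by
convention.

Degenerate inputs: reported categories with zero probability and nonzero
counts give a -inf likelihood (flagged); probabilities are floored at
1e-300 inside the sampler so a transient underflow cannot produce NaNs.

## Penalty selection

Leave-studies-out cross-validation (default 5 folds, stratified by study
size): for each held-out study the error is the mean absolute difference
between its empirical reported-category fractions and G_s p_hat(x_s) with
the unseen study's random effect predicted at zero (a squared-error metric
is available). Because CV curves here are often flat over a wide lambda
range, selection uses the one-standard-error rule *in the conservative
direction*: the chosen lambda is the largest one whose mean error is
within one SE of the minimum, so ties resolve to heavier shrinkage and
less overfitting. The SE multiplier is configurable.

## Strata and model averaging

Country-years are assigned to mortality strata by their all-cause rate
(deaths per 1000 livebirths): neonates low < 10, high >= 20; children
1–59 months low < 25, high >= 35. In the moderate band the high- and
low-mortality models' fractions are averaged with weight
(rate - L)/(H - L) on the high model — the simplest continuous
interpolant that reaches exactly 0 and 1 at the band edges, so predicted
fractions are continuous as a country crosses thresholds. Averaging
operates on fractions (with renormalisation), and the envelope is applied
afterwards; the alternative (averaging deaths) differs only by the common
envelope factor. VR countries bypass the models: reported fractions are
linearly interpolated between reporting years, renormalised, and held
constant outside the reporting span.

## Post-processing

Fixed order: **squeeze → splits → TB carve-out → vaccine adjustment →
crisis attribution**. Each step moves deaths between causes without
creating or destroying them, so the envelope total is conserved to 1e-6
relative throughout and no cause goes negative.

- **Squeezing**: exogenous single-cause estimates (measles, HIV, tetanus,
  reported malaria, TB) are taken off the envelope; the remainder is
  distributed over modelled causes by their fractions. If the exogenous
  causes together exceed 90% of the envelope (configurable), they are
  rescaled pro rata — the sources never see each other's totals, so
  collisions must be resolved somewhere, and a proportional cap is the
  least informative choice.
- **Splits**: combined neonatal sepsis/meningitis and child perinatal
  causes are split by externally supplied ratios (GBD-style); a missing
  perinatal ratio falls back to an equal split with a warning.
- **TB**: pulmonary TB is carved from LRI deaths; extrapulmonary TB from
  the communicable share of "other" (default 50%, configurable), with
  excess reassigned from LRI. Categories are floored at zero and
  unabsorbable excess is truncated with a warning rather than borrowing
  from further causes.
- **Vaccine adjustment**: cause deaths are scaled by
  (1 - cov·VE·PAF)/(1 - cov_ref·VE·PAF), where cov_ref is coverage in the
  study era (default 0 — Hib/PCV/rotavirus vaccines largely post-date the
  study base). Default VE·PAF values (Hib 0.15, PCV 0.12, rotavirus 0.20)
  are plausible placeholders living in config, not assertions about any
  published adjustment. Freed deaths are reallocated pro rata so the
  envelope is conserved.
- **Crisis attribution**: crisis deaths (events shorter than 5 years,
  more than ten deaths) are assigned by crisis type — natural disasters to
  injury, conflict-related malnutrition to "other", congenital epidemics
  to congenital abnormalities, or pro rata — with the non-crisis remainder
  distributed by modelled fractions.

Whether vaccine adjustment precedes or follows squeezing is not externally
determined; the fixed order above was chosen once and is applied
everywhere.

## Uncertainty

All uncertainty is propagated by Monte Carlo: posterior fraction draws
(for countries with a nationally representative study, that study's
random-effect draws; otherwise u = 0 for the point estimate and
u ~ Normal(0, sigma draws) for uncertainty), lognormal envelope draws, and
lognormal exogenous-cause draws (mean-corrected, so the expectation equals
the point estimate) are pushed through the full post-processing chain per
draw. Uncertainty ranges are empirical 2.5–97.5 centiles with the
linear-interpolation convention between order statistics. Regional and
global aggregates are summed across countries within each draw before
centiles are computed, preserving cross-country correlation from shared
parameters. Model-averaging weight uncertainty is not propagated.

The annual rate of reduction between years t1 < t2 uses the log-linear
convention ARR = 100·ln(rate_t1/rate_t2)/(t2−t1); the SDG projection
compares each cause's ARR-extrapolated rate with the rate required if the
cause kept its current share when the all-cause target is reached.

## Synthetic data

The generator reproduces the statistical structure the model assumes —
AR(1)-smooth standardised covariate panels (autocorrelation 0.8 by
default), sparse generating coefficients (2 of 5 covariates active with
effects ±0.5, alternating sign across contrasts, intercepts ~ N(0, 0.5)),
study effects at the sigma bound 0.14, multinomial counts through
study-specific aggregation patterns, log-linearly declining envelopes
spanning 15–120 deaths per 1000 livebirths (so countries cross strata),
and exogenous series as envelope shares with lognormal jitter. Study
countries carry real ISO3 codes from the bundled region table so IO
validation is exercised.

What it does *not* emulate: covariate measurement semantics (the panel is
generic, not vaccination coverage or GDP), biased or misclassified VA
cause assignment (the aggregation matrix is exact by construction),
informative study placement (studies land on random country-years), and
overdispersion beyond the multinomial. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to violations of them.

Default validation scenario sizes — 40 studies × 2000 deaths for the
convergence check, 20 replicates of 40 × 1250 for coefficient recovery,
1000 random fixtures for conservation — were chosen so the full suite
runs in a few minutes on one CPU while leaving sampling error well below
the margins being tested.

## Known limitations

- The sampler is exact but not gradient-based; very large study sets
  (hundreds) would benefit from a blocked or HMC sampler.
- Fractional (probabilistic) misclassification matrices are out of scope;
  G is binary aggregation only.
- VA misclassification error and covariate-estimation uncertainty are not
  represented in the uncertainty ranges (they are narrower for it).
- Sex-stratified estimation is not implemented.
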