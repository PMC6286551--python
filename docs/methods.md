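# Methods

## The modeling problem

Three clinical predictors of distant recurrence in primary breast
cancer — age at diagnosis (years), pathological tumor size (mm) and
number of positive axillary lymph nodes — enter a Cox proportional
hazards model under four codings of increasing flexibility:
dichotomization, 3/4-level categorization, fractional polynomials
(FP) and restricted cubic splines (RCS).  Follow-up is
administratively truncated at 10 years (events after the cutoff are
recoded as censored at the cutoff), both because distant-recurrence
hazards for tumor size are known to drift over longer horizons
(proportional-hazards violations) and to keep median follow-up
comparable across source materials.  Models are stratified by source
material: each stratum keeps its own baseline hazard and the partial
likelihood is a product over strata.  Strata without events contribute
nothing and are dropped with a warning.

## Survival machinery

The stratified Cox partial likelihood is maximized by Newton–Raphson
with step-halving on any likelihood decrease, convergence when the
largest absolute score component falls below 1e-8 or the relative
log-likelihood change below 1e-10, and a 100-iteration cap
(non-convergence raises; it is never silently returned).  The
covariance matrix is the inverse observed information.  Tied event
times are handled by Breslow's approximation by default — the default
of the major commercial survival packages — with Efron's correction
available by flag; the two coincide exactly when no event times are
tied, which is the generic case here since synthetic event times are
continuous.  A coefficient whose magnitude crosses 50 is flagged as
likely monotone likelihood (separation).

Kaplan–Meier curves use the product-limit estimator with Greenwood's
variance and confidence intervals on the log(−log S) scale, which
keeps them inside (0, 1).  Proportional hazards are checked by the
Grambsch–Therneau scaled-Schoenfeld test, correlating the scaled
residuals with identity-transformed event time by default (rank time
optional); simulations in the test suite confirm the nominal 5 % level
under proportional hazards and high power against a sign-reversing
time-varying coefficient.

## Fractional polynomials and the closed test

FP bases use powers of z = (x + shift)/scale, with z⁰ read as ln z and
a repeated power (p, p) contributing z^p and z^p·ln z.  The candidate
power set is the conventional {−2, −1, −0.5, 0, 0.5, 1, 2, 3}.  For a
covariate with non-positive observed values the shift is the smallest
positive increment between distinct observed values minus the minimum
(so node counts get shift 1, i.e. ln(nodes + 1)); the scale is the
power of ten bringing the shifted range near unity, which keeps z³ and
z⁻² numerically tame without changing the spanned model space.

Function selection per covariate is the closed test procedure: the
best-fitting FP2 (maximum partial likelihood over all 36 power pairs)
is compared by likelihood-ratio tests, in order, against the null
model (4 df; skipped for covariates forced into the model — the
default for the three clinical factors), against the linear coding
(3 df), and against the best FP1 (2 df), each at level α = 0.05.  The
first non-significant comparison stops the sequence and returns the
simpler form.  This ordering controls the familywise probability of
selecting spurious complexity at α; the suite measures ≈3 % selection
of non-linear forms under a truly linear effect (the procedure is
known to be mildly conservative against FP1 alternatives, since the
gateway test spends 3 df on a 1-parameter departure).

The multivariable procedure (MFP) backfits: covariates are ordered by
decreasing significance of their linear coding in a joint Cox fit,
each in turn undergoes closed-test selection adjusted for the current
codings of the others, and the cycle repeats until a full pass changes
nothing (maximum five cycles, history logged).  The final model is the
joint Cox fit of all selected bases.

## Restricted cubic splines

Five knots per covariate: at the 5th/27.5th/50th/72.5th/95th
percentiles (nearest-rank) for age and size; fixed at 1, 2, 3, 4 and
10 positive nodes for the node count, whose ~40 % zeros make
percentile placement degenerate.  The basis is x plus the k−2
restricted truncated-power terms normalized by the squared boundary
span, so any fitted combination is linear outside the boundary knots
by construction (verified numerically to 1e-6 relative by second
differences).

## Prognostic index, risk groups, transport

The prognostic index is the Cox linear predictor centered at a
reference patient — 35 years, 20 mm, 0 nodes — whose relative hazard
is therefore 1.00 by definition.  Risk groups cut the PI at its
16th/50th/84th nearest-rank percentiles; cut-offs are observed PI
values, so tied-PI blocks never straddle a cut, and the achieved
percentiles are always reported alongside the requested ones (with
31 distinct PI values a categorized model cannot hit 16/50/84
exactly).  Transport to a validation cohort freezes transforms,
weights and PI cut-offs; covariates outside the derivation range are
clamped to it with a warning (negative FP powers explode near zero) —
a strict mode raises instead.  Harrell's C counts a pair evaluable
when the observed times differ and the shorter time ended in an event;
two events at equal times are not evaluable (the classic convention —
the verbal definition alone does not settle it), and tied predictions
count one half.

Pointwise 95 % bootstrap bands for univariable relative-hazard curves
resample patients with replacement within stratum (preserving stratum
sizes) and rerun the *entire* selection-plus-fit inside each
replicate, so model-selection uncertainty is inside the band; the
default is the univariable curve with re-selection, matching how such
curves are usually displayed.  Replicate failures are logged and
skipped; more than 10 % failures aborts.

## The synthetic generator

The generator emulates the derivation series of a large multi-material
breast-cancer study and its lower-risk validation series:

| quantity | derivation | validation |
|---|---|---|
| patients | 4477 | 1132 |
| strata (materials) | 6 | 1 |
| age | N(60, 13²) truncated [25, 93], whole years | N(64, 13²) trunc. [28, 99] |
| tumor size | lognormal mixture, median 22 mm, whole mm | median 20 mm |
| node-negative fraction | 0.40 | 0.58 |
| positive nodes | geometric, mean 3.3 | mean 3.0 |
| 10-yr event fraction | ≈0.29 | ≈0.26 |

Tumor size is a 95/5 mixture of a main lognormal (log-mean 3.113,
log-sd 0.42) and a small-tumor component (log-mean ln 8, log-sd 0.8),
truncated to [1, 120] mm: a single lognormal matching the T1/T2/T3
fractions (44/53/3 %) puts essentially no mass below 5 mm, whereas
real series contain a small percentage of screening-detected tiny
tumors (the emulated series reports ~0.3 % at ≤ 2 mm, which the
mixture reproduces).  Ages and sizes are rounded to whole units to
reproduce the heavy ties of registry data.

True effects on the log hazard, relative to the reference patient:
−0.005 per year of age, +0.35 per √mm, +0.78 per log(nodes + 1).
These were calibrated so the *simulated* univariable discrimination
matches the emulated study's reported values (linear-age C ≈ 0.51,
√size C ≈ 0.59–0.60, log-nodes C ≈ 0.65) — the age slope is
deliberately weak because a linear age term cannot simultaneously
reproduce a strong young-patient effect and near-null overall age
discrimination, and the C-index anchors govern a discrimination study.
Event times are exponential with per-stratum baseline rates (0.0157 to
0.0222 per year for the reference patient in the derivation strata;
0.0213 in validation) calibrated to the 29 %/26 % ten-year event
fractions; censoring is independent exponential at 0.02/yr plus the
administrative 10-year cutoff.  The real study's censoring and accrual
pattern is unknown; the exponential choice is a stand-in, not an
inference about it.

What passing tests on these cohorts do **not** show: robustness to
non-proportional hazards, to informative censoring, to covariate
measurement error or miscoding, or to the mixture-of-trials
heterogeneity of real materials — the generator draws every stratum
from the same covariate distributions and the truth is exactly
proportional-hazards.

## Known limitations and measured behavior

* At these paper-anchored effect sizes, the 3-df FP2-versus-linear
  closed test has only ≈45 % power to reject linearity for the pure
  √size effect at n = 4000 (measured over 100 replicates: size
  non-linear 44 %, nodes non-linear 100 %, age linear 97 %).  The
  emulated study detected size non-linearity on its real data — whose
  size-hazard curve is evidently more curved than √x at matched
  discrimination (its final multivariable model used a second-degree
  FP for size).  Joint functional-form recovery on the synthetic
  default is therefore dominated by the size covariate and sits near
  45 %, not near certainty; the suite's corresponding check documents
  this honestly rather than inflating the generator's effect sizes
  past their anchors.
* Problem sizes in the test suite (n = 600–4477, 25–300 replicates,
  bootstrap B = 25–60) were chosen to keep the default run complete
  yet exhaustive on the structural checks; the full-scale study run
  uses the emulated cohort sizes (4477/1132).
* No time-varying covariates, left truncation, competing risks,
  FP degrees above 2, covariate interactions, or calibration metrics
  (external calibration of such models requires comparable follow-up
  and treatment context, which the transport setting does not give);
  decision-analytic measures are out of scope.
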