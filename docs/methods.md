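# Methods

`equirest` implements an analysis chain for lying behaviour in stabled
horses measured with leg-mounted 1 Hz accelerometers: posture
classification, bout segmentation, day/night per-hour outcomes over a
three-condition crossover design, and mixed-model inference with parametric
bootstrap. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data validation does
and does not demonstrate.

## Posture classification

A logger strapped to the cannon bone reports about −1 g on its vertical (Y)
axis while the horse stands (axis parallel to gravity) and about 0 g while
it lies (axis roughly horizontal). Classification is a fixed threshold:

* `threshold_g = −0.75` — samples *below* are STANDING, at or above LYING.
  The boundary value itself is assigned to LYING; the event has measure zero
  with real sensors but the tie-break is fixed for determinism.
* `window_samples = 31` — the per-second labels are smoothed by a running
  median over a centered 31-sample (31 s) window. For binary data the
  median over an odd window *is* the majority vote; the package computes the
  vote with cumulative sums in O(n) and tests it against a literal
  `np.median` sliding-window oracle.

Numerical decisions at the window edges and at dropouts:

* The first and last 15 s use a truncated centered window. Truncated
  windows can tie; ties resolve to STANDING, which is conservative in that
  edge effects can never fabricate lying time.
* Missing samples are excluded from the vote, and a sample that is missing
  in the (gap-filled) input stays missing in the output: a sensor dropout
  never manufactures posture evidence. A window with no observed votes is
  missing.

A single pass of this filter removes isolated misclassified seconds and
shifts a posture transition by at most one second per nearby flip. One
property worth stating precisely: any binary signal whose runs all last at
least (w+1)/2 = 16 s is a *fixed point* of the filter, and on
bout-structured input (true runs ≥ 31 s) with isolated flips spaced more
than a window apart the smoothed output never contains an interior run
shorter than 16 s. That guarantee is a property of the signal class, not of
the filter alone — a strictly alternating sequence passes through any
centered majority vote unchanged — so the run-length validation generates
exactly the class of signal the smoother receives in this pipeline:
renewal-process bouts corrupted by sparse threshold errors.

## Gap policy

Logger CSVs are parsed onto a strict 1 s grid between their first and last
timestamps; absent seconds become explicit missing values. Runs of at most
`max_gap_s = 5` missing seconds are filled by carrying the last observation
forward; longer runs stay missing and instead shrink the observed-time
denominator of the per-hour outcomes. The 5 s default assumes that short
dropouts are transmission glitches within one posture, while longer ones
carry no posture information; it is configurable.

## Bouts and day/night outcomes

A bout is a maximal run of one state in the smoothed sequence; a missing
run terminates the bout in progress, so bouts tile observed time exactly.
Outcomes are computed in two clock windows — day 08:30–16:00 (7.5 h, the
experimental-condition phase) and night 17:00–07:30 of the next day
(14.5 h, all horses boxed individually; attributed to the evening's
calendar date) — and normalized per hour of *observed* (non-missing) time:

* `n_bouts_per_h` — lying bouts with positive overlap with the window,
  divided by observed hours;
* `lying_h_per_h` — lying time inside the window divided by observed time.

Bouts straddling a window edge are clipped for duration but counted if the
overlap is positive; clipping preserves the conservation identity
(lying + standing = observed window time when nothing is missing), and
straddling is rare in practice because the relocation hours (07:30–08:30,
16:00–17:00) sit outside both windows.

## Crossover design

Each of `n_horses` (default 10) passes through the three daytime conditions
BOX → indoor box alone, ALONE → outdoor paddock alone, PAIRS → same paddock
with a companion, once per repetition (default 2), in one of the 6 possible
orders. Orders are balanced: with 20 horse × repetition sequences each
order is used at least ⌊20/6⌋ = 3 times and exactly two randomly chosen
orders are used 4 times; no horse repeats an order. The allocator realizes
this degree sequence exactly (largest-remaining-count order handed to the
most-needy horses, random tie-breaks), so generation never fails when the
constraints are satisfiable (`n_reps ≤ 6`, no order needed more than
`n_horses` times) and raises an explicit infeasibility error otherwise.

Calendar dates: real observation days were chosen operationally by the
farm, so the generator only has to reproduce their statistical role —
several horses measured in the same 24 h period, which is what makes horse
and date *crossed* grouping factors. By default horses are grouped three
per observation day, giving 24 distinct dates for the 10 × 2 design, spaced
3 days apart from 2022-03-01 (a roughly three-month span). An explicit date
list can be supplied instead.

## The mixed model

For outcome y (either per-hour quantity) of one horse-period × window:

    log(y + c) = μ(condition, window) + a_horse + b_date + ε
    a ~ N(0, σ²_H),  b ~ N(0, σ²_D),  ε ~ N(0, σ²)

with a full 3 × 2 cell-mean fixed structure and crossed random intercepts.
Contrasts of cell means are exponentiated and reported as multiplicative
factors: condition contrasts (ALONE or PAIRS vs BOX) average the two
windows with equal weight; the night/day contrast averages the three
conditions.

**Estimation.** The deviance is profiled over the variance ratios
γ_k = σ²_k/σ²: given γ, the fixed effects and σ² solve the penalized
mixed-model equations in the scaled coordinates u* = Λ^{-1/2}u, whose
(q+p)×(q+p) Cholesky factor simultaneously yields log|V|, log|XᵀV⁻¹X| and
the penalized residual sum of squares. This makes the γ → 0 boundary exact
and a refit on a new response vector (the bootstrap inner loop) a
few-millisecond operation. The 2-parameter outer problem is solved with
bound-constrained L-BFGS-B on s = √γ ≥ 0, with a second start near the
origin for the cold fit and a Nelder–Mead polish if the line search
terminates abnormally near the boundary (the criterion depends on s only
through s², so sign is irrelevant). Both REML (default, used for reported
estimates and intervals) and ML (used inside likelihood-ratio tests) are
available. The original analysis of this design used Bayesian fits with
flat priors; with non-informative priors those point estimates coincide
numerically with penalized ML/REML away from the variance boundary, which
is why a deterministic (RE)ML fit is used here. The implementation is
verified against a dense-matrix GLS evaluation of the same criterion
(agreement ~1e-13) and against `lme4::lmer` on identical data (estimates to
~1e-7, identical restricted log-likelihood).

**Boundary truncation.** Variance estimates are constrained to be
non-negative. At the reference dimensions (120 rows, 24 dates) a weakly
identified component — notably the date variance under the high residual
variability of the lying-duration outcome — piles an appreciable fraction
of its sampling distribution onto zero, so the *truncated* estimator's mean
sits above a small true value even though the fit is exact. This is a
property of constrained (RE)ML, shared with lme4, and is why the
recovery simulation quantifies bias under the bout-count parameterization,
where all components are comfortably identified, while implementation
correctness at any parameter point is pinned by the lme4 and dense-matrix
oracles.

**log(0) handling.** Some horses never lie during some day windows, so the
transform is log(y + c). By default c = 0 when all outcomes are positive;
otherwise c is half the smallest observable nonzero value given the window
lengths: 0.5 × (1 bout / H) for bout rates and 0.5 × (16 s / H) for lying
duration, with H the longest observed window in hours (16 s being the
shortest lying run the 31 s smoother can emit). The offset is a config
knob and is echoed in every output.

**Parametric bootstrap.** p-values come from likelihood-ratio tests of
nested ML fits, referenced against `n_boot` refits of data simulated from
the fitted null, with p = (1 + #{LRT* ≥ LRT}) / (n_boot + 1). The nested
pairs are: GLOBAL, full vs window-only; CONDITION, additive vs window-only;
WINDOW, additive vs condition-only; INTERACTION, full vs additive — a
documented interpretation of the usual global/main-effect/interaction
reporting, not the only possible one. Confidence intervals simulate from
the fitted full model and take percentile quantiles of the exponentiated
contrast (the percentile flavour is a package choice). Replicate refits
are warm-started from the parent fit; non-converged replicates are dropped
and counted, and more than 5% failures is an error. All replicate
responses are drawn up front from one seeded generator, so results are
reproducible and independent of evaluation order.

## Synthetic data

Two generators close the loop without any field data.

*Traces.* A two-state alternating-renewal process draws standing and lying
sojourns from a lognormal law (meanlog set from the mean with σ_log = 0.6;
an exponential option exists for analytic checks), renders −1 g standing /
0 g lying, and adds Gaussian sensor noise (default 0.03 g). Defaults of
90 min mean standing and 25 min mean lying bouts give a lying fraction
around 0.2, in the range reported for stabled horses overnight. A
`min_bout_s` floor (applied to draws and to the trace tail) lets tests pin
every true bout above the smoothing window. The generator returns the
exact bout list, so recovery can be checked sample-for-sample.

*Outcome tables.* Experiment-level tables are drawn exactly under the
mixed model above, over a generated schedule. Two default
parameterizations encode the published factor structure for this housing
experiment: lying duration (night/day ratio 11.25 over a day-box level of
0.018 h/h; condition factors 1, 1.39, 1.38; log-scale variances
σ²_H = 0.3, σ²_D = 0.1, σ² = 2.0) and bout counts (day/night ratio 1.21
from 0.40 bouts/h; condition factors 1, 1.08, 1.17; σ²_H = 0.10,
σ²_D = 0.05, σ² = 0.30). The variances were sized once from the widths of
the published factor confidence intervals on the log scale (duration
intervals are roughly [0.7, 2.9]-fold wide, bout intervals [0.84, 1.36]);
they are not re-tuned.

What passing the synthetic validation shows — and does not. It shows the
chain is internally correct: the classifier and smoother recover known
bouts exactly in their guaranteed regime, the design generator meets its
balance constraints, the estimator is unbiased within Monte-Carlo error
where theory says it should be, the bootstrap test holds its 5% level and
the intervals their 95% coverage under the model. It does not show that
real accelerometer data satisfy the model: real traces have non-Gaussian
artefacts (gait transitions, bandage slip), real lying bouts are not
exactly lognormal, and real outcomes need not be log-normal with additive
crossed effects. Those are questions for residual diagnostics on real
data, for which plain residuals are exported.

## Validation problem sizes

The shipped checks use: 1000 random series for the smoother oracle and the
run-length floor; 20 noise-free and 100 noisy simulated days for trace
recovery; 500 simulated studies for recovery bias; 300 studies × 99
bootstrap refits for the type-I error of the condition test; 200 studies ×
199 refits for night/day interval coverage. These sizes resolve each
target at roughly three standard errors.

## Known limitations

* Only the vertical (Y) axis is used; multi-axis or machine-learned
  behaviour classification is out of scope.
* The night window is attributed wholly to the evening's date; no
  timezone or daylight-saving arithmetic is applied (windows are clock
  times, as in the experimental protocol).
* Bout-duration distributions are not modelled; bouts only feed counts and
  total durations.
* Inference is frequentist (RE)ML + parametric bootstrap; full Bayesian
  posteriors and simulation-based residual diagnostics are not provided.
* Covariates (sex, age, weather) are not modelled.
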