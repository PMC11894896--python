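# Methods

## Model

`melseq` estimates long-term health outcomes of systemic treatment
sequences in advanced (unresectable stage III/IV) cutaneous melanoma
with a semi-Markov cohort model. Patients start first-line treatment
progression-free (PF1) and can progress (PD1), switch to a next
treatment line with or without recorded progression, or die. The
BRAF-mutant model distinguishes three treatment lines plus a terminal
"subsequent therapies" state (8 health states, 16 transitions); the
BRAF wild-type model has two lines (6 states, 11 transitions). Death
is absorbing and reachable from every state.

Two features make the model semi-Markov rather than Markov:

* **Clock reset** — transition intensities out of each PF state are
  functions of time since that line started, not model time.
* **Duration dependence** — intensities out of each PD state are
  functions of time since progression, implemented with tunnel
  states: one occupancy layer per monthly cycle of time in state.

The model runs separately per subgroup: BRAF mutation status crossed
with prognostic group (favorable: normal LDH, ECOG 0–1, no brain
metastases; intermediate: LDH ≤ 2× ULN elevation and/or asymptomatic
brain metastases, ECOG 0–1). Patients with poor prognostic factors
are out of scope.

## Transition hazards

Every allowed transition is a parametric time-to-event model fitted by
maximum likelihood to right-censored per-transition datasets extracted
from line-structured patient histories:

* a progression recorded on the same day as a next-line start (or as
  death) is moved one day earlier, so extracted times are positive;
* each transition is censored at the earliest competing event or at
  the last registered visit;
* PF transitions run on the line clock, PD transitions on the
  progression clock.

Eight families are supported: exponential, Weibull, gamma, generalized
gamma (Prentice), generalized F (Prentice), log-logistic, log-normal,
Gompertz. Baseline covariates (age centered at 60 years, sex, ECOG,
LDH, brain metastases) act log-linearly on each family's location —
accelerated-failure-time for the AFT families, log-rate/log-level for
exponential and Gompertz. The selection workflow fits all candidate
families and ranks them by AIC (BIC reported); the final choice is the
caller's — in practice the visual fit of modeled overall survival to
the observed curve is decisive. Sparse datasets (< 10 events) are restricted to families
with at most two parameters; covariates constant within a dataset
(e.g., LDH inside the favorable group, which is defined by normal LDH)
are dropped from that fit. Standard errors come from the inverse
observed information (finite-difference Hessian), symmetrized and
eigenvalue-clipped to positive semi-definite.

Fitting uses BFGS from method-of-moments starts with up to five
perturbed restarts (gradient tolerance 1e-8); a likelihood that is
never finite raises a convergence error carrying the best point.

## Treatment effects

Baseline hazards estimated from a registry mix of treatments are
population averages. To predict the outcome of one named treatment j,
a transition intensity h(t) is rescaled by

    h_j(t) = h(t) · HR_j / Σ_k p_k HR_k

where p_k is the observed treatment mix of that line and subgroup.
Averaging the rescaled intensities over the mix recovers the baseline
exactly (asserted in tests). The progression hazard ratio (HR_PFS)
applies to PF→PD only, within a class-specific effect window on the
line clock — 2 years for chemotherapy and immunotherapy, 0.5 years
for targeted (BRAF/MEK) therapy in the base case — and reverts to the
unadjusted baseline afterwards, which allows progression-free curves
to cross. The overall-survival hazard ratio (HR_OS) applies to PF→D
and PD→D for the whole line. Switch transitions are never adjusted.
Hazard ratios are treatment-line and prognostic-group invariant;
encorafenib+binimetinib is aliased to dabrafenib+trametinib when its
own row is absent.

Scenarios: s1 and s2 set the targeted PFS window to 0.25 and 1.0
years; s3 lets an immunotherapy's OS effect persist beyond its line,
multiplying the death intensities of all later lines by its normalized
factor HR_OS / mean-line-HR_OS (compounded with the later line's own
effect) — the normalized form keeps the observed-mix sequence exactly
at baseline under s3; s4 caps the horizon at 10 years. Treatment-
duration rules (immunotherapy ≤ 2 years; targeted stopped after 5
progression-free years) are carried in the policy for a future cost
layer and affect no transition here.

## Cohort engine and numerics

Cycles are monthly (dt = 1/12 year; configurable). Within each cycle,
cause-specific intensities are held constant and converted to
probabilities by the competing-exponential embedding: with total
intensity H, stay = exp(−H·dt) and cause k exits with
(r_k/H)(1 − exp(−H·dt)).

Numerical choices, made after measuring their effect on the
dt-refinement stability of life expectancy:

* **Per-cycle intensity** is the average hazard over the cycle,
  (H((u+1)dt) − H(u·dt))/dt, rather than a point evaluation at the
  cycle start. This is exact for the single-risk marginal and remains
  finite for families with h(0) = ∞ (Weibull/gamma shape < 1).
* **Mid-cycle entry correction.** Mass that changes state mid-cycle
  would otherwise wait until the next cycle boundary to be at risk in
  its new state — an O(dt) bias measured at ≈1.7% of life expectancy
  on the reference configuration. Instead, arrivals receive a
  half-cycle exposure to the new state's initial average hazard, and
  entrant-fed tunnel layers evaluate layer d at time-in-state
  (d + 1/2)·dt. Second-generation moves within an arrival half-step
  land in their destination's first layer without a further half-step
  (an O(dt²) truncation). The plain embedding stays available via
  `entry_correction=False` and is what the independent flat-chain and
  trace-composition oracles check bitwise.
* **Life expectancy** is the trapezoidal (half-cycle-corrected) sum of
  alive occupancy by default; the left-Riemann sum alone would move by
  ≈dt/2 ≈ 0.04 years under cycle refinement, which dominates the
  discretization error. `half_cycle=False` restores the plain sum.

With these choices, refining dt from 1/12 to 1/48 moves reference
life expectancy by ≈0.1%.

Death intensities are floored at the general-population all-cause
mortality rate: a single mix-weighted (configured male fraction) rate
at the cohort's current integer age, which advances with global model
time from the start age. The floor applies to each state's summed
death intensity. A lifetime horizon runs to age 110 or until death
occupancy exceeds 1 − 1e−6.

`run_model` uses a global layered engine, so every tunnel layer of
every line sees the correct attained-age floor. `compose_traces`
additionally implements the classic reduction — per-line local traces
convolved by entry flows — which is exact when line dynamics are
entry-time invariant; in that path the floor age inside a later line
runs from that trace's own start age, a documented approximation.

Outcomes: mean time per state (tunnels collapsed), life expectancy,
survival at 2 and 5 years (linear interpolation between cycles), and
median overall survival in months (earliest interpolated time with
survival ≤ 0.5; reported as not reached when the curve never drops
that far).

## Probabilistic sensitivity analysis

Per iteration, every fitted transition's parameter vector is redrawn
as MLE + L·z with L the lower Cholesky factor of its
variance-covariance matrix (jitter ≤ 1e−10 if factorization fails; an
exactly singular PSD matrix falls back to an eigenvalue square root),
and every treatment's HR_PFS and HR_OS are redrawn independently from
log-normal distributions matched to their 95% credible intervals. The
log-normal location is the log-midpoint of the interval so the
empirical 2.5/97.5 percentiles reproduce the interval; for the near
log-symmetric intervals of a network meta-analysis this coincides with
the log-median. PFS and OS ratios of one treatment are drawn
independently because the joint posterior is not available — a
documented limitation. Within an iteration the same draws serve every
sequence (common random numbers), so incremental life-years are
paired. Life-table rates are treated as fixed. Summaries are the mean
and the 2.5/97.5 percentiles over iterations (default 1,000); failed
iterations are redrawn and counted.

## Synthetic registry generator

The generator emulates a national treatment registry so the pipeline
is testable end to end. Defaults: 59% BRAF-mutant, 63% favorable
prognostic factors, age ~ Normal(60, 12) floored at 18, 56% male, 30%
ECOG 1; two modeled treatment lines plus a subsequent-therapy phase;
uniform accrual over 2 years with an administrative cutoff 4 years
after study start (realistic right censoring). True cause-specific
hazards are exponential/Weibull of plausible magnitude on the correct
clocks, with prognostic-factor effects (elevated LDH, brain
metastases, ECOG) on the death transitions using the same covariate
link the fitting module uses; per-line treatment mixes cover the
bundled hazard-ratio table. Event dates are rounded to whole days with
a 1-day minimum gap, which exercises the same-day resolution rules.
The bundled life table is Gompertz–Makeham (a + b·e^{c·age}, male and
female offsets), and the bundled hazard-ratio table holds plausible
NMA-scale values with the dacarbazine reference at exactly 1.

What the generator does not emulate: informative censoring, missing
baseline covariates (available as an exclusion exercise only),
registry governance fields, real Dutch mortality figures, and
treatment-effect modification by line. Passing tests therefore show
the estimator and engine are self-consistent under known hazards —
not that any specific clinical estimate is externally valid.

Test problem sizes (cohorts of 1,500–6,000 patients, 40,000–100,000
microsimulation paths, 100 fitting replicates at n = 2,000, PSA at
40–200 iterations) were chosen so Monte Carlo error is small relative
to each assertion's tolerance while the suite stays quick to run.
Because life expectancy is dominated by small extrapolated death
rates, its sampling error at registry scale is several percent; the
end-to-end consistency test therefore compares the fitted pipeline to
the generator's truth within the pipeline's own propagated 3σ
uncertainty, and checks the engine against the truth-based
microsimulation (0.3–0.5% agreement) with the fitting step removed.

## Known limitations

* Covariates are baseline-only; characteristics at later line starts
  are not updated (inherent to the cohort approach).
* The terminal subsequent-therapy state has a single exit-to-death
  hazard and no internal structure.
* The per-line trace composition path approximates the floor age in
  later lines; the global engine does not.
* Spline-based flexible parametric and cure-fraction survival models
  are out of scope, as are costs and QALYs.
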