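# Methods

## The model and its assumptions

`cjskit` implements the Cormack-Jolly-Seber (CJS) open-population model
for annual encounter histories, conditional on each individual's first
capture. Apparent survival Φ_t and capture probability p_t are modelled
on the logit scale. The likelihood of a history decomposes into the
fully observed segment between first and last detection — survival
factors for every interval, capture/non-capture factors for every
occasion — and the never-seen-again tail

    χ_t = (1 − Φ_t) + Φ_t (1 − p_{t+1}) χ_{t+1},    χ_K = 1,

with p forced to zero at occasions where capture is physically
impossible. Because survival and capture depend only on (occasion, sex,
trap state), histories are aggregated into sufficient count tensors
(`CJSData`), which makes the likelihood cost independent of the number
of individuals.

Assumptions inherited from CJS: homogeneous survival and capture within
a (time × sex × trap-state) cell, independent fates, no mark loss,
instantaneous sampling. Two standard violations are handled explicitly:

* **Transience** — animals passing through the colony are marked once
  and never return; their apparent survival is zero. They are removed
  by suppressing every animal's first encounter
  (`suppress_first_encounter`), which conditions each history on its
  second capture; single-capture histories drop out and are counted.
* **Trap-dependence** — capture at occasion *t* changes the capture
  probability at *t*+1. Capture carries a Markovian state factor
  (m1 = captured at the previous occasion, m2 = not), additive or fully
  interacted with time/sex.

## Study design structure

`StudyDesign` holds the annual occasions, gap years with no fieldwork,
and monitoring *panels* — disjoint samples each followed over its own
year range. The default layout is 34 occasions (1978–2011), a
2000–2003 gap, and panels 1978–1999 / 2004–2011. Capture probability
is structurally zero for panel-1 animals from 2000 onward and for
panel-2 animals before 2004 (a mask, not a fitted value).

A consequence the package makes explicit: because the panels are
disjoint samples, no individual provides observable information across
the gap. The five intervals starting 1999–2003 have zero exposure, so
in time-dependent models they are pooled into a single "gap" level and
flagged `estimable=False` in the survival series — not even their
product is informed by data. Covariate-constrained models predict
through the gap via the linear predictor, which is how the survival
series fills those years.

## Goodness of fit and c-hat

The GOF of the time-dependent model is decomposed per panel × sex into
the four directional contingency components (3.SR, 3.SM, 2.CT, 2.CL),
each a sum of per-occasion tables. Within each table, zero-margin rows
and columns are removed and the sparsest row/column is pooled into its
neighbour until every expected count is at least 2; tables that cannot
reach the floor contribute nothing (χ² = 0, df = 0, flagged
degenerate). p-values are upper-tail χ². Direction statistics are
signed square roots of the 2×2 components (positive = transience for
3.SR, trap-happiness for 2.CT), combined as z-sums across occasions.

Each panel's tests run on its own contiguous active occasions, so
"next occasion" logic never crosses the monitoring gap; panel-1 animals
contribute only up to the panel's last year.

The variance-inflation factor is ĉ = χ²/df of the residual components.
The pipeline's default residual set, after transience removal and with
trap-dependence modelled directly in the capture structure, is
{3.SR, 3.SM, 2.CL} — the immediate trap component is excluded because
the m-state factor absorbs it. `GofReport.c_hat_from` lets users choose
any other subset.

## Fitting and uncertainty

Design matrices are built with patsy using corner-point (treatment)
coding; a sum-to-zero coding is available and the deviance is invariant
to the choice (verified to 1e−6 in the tests). The scaled negative
log-likelihood (per history) is minimized by L-BFGS-B with
finite-difference gradients, default 5 starts (zeros plus random
perturbations, seeded). Deviance is reported as 2 × the conditional
negative log-likelihood; only deviance *differences* are meaningful
across software, since the saturated-model offset is conventional.

The number of estimable parameters np is the numerical rank of the
finite-difference Hessian at the optimum (eigenvalues above 1e−6 × the
largest). This discounts the classic terminal Φ·p confounding of fully
time-dependent models and any zero-exposure (gap) parameters.
Coefficient covariance is the Hessian pseudo-inverse; real-scale Φ and
p carry delta-method standard errors and logit-scale 95% intervals.
Non-convergence is flagged on the result, never raised.

## Covariate preparation

Monthly series are averaged over two seasonal windows: breeding
(April–September of year t) and non-breeding (December t−1 through
February t, labelled year t — the winter preceding breeding season t).
Season-lags 1–4 shift along the calendar sequence
… nb(t), br(t), nb(t+1) …, so lag 2 equals a one-year shift and lag 1
assigns breeding(t) the non-breeding(t) value. Candidates are screened
by pairwise Pearson correlation (significance at α = 0.05, or an |r|
threshold); connected groups of same-unit members are averaged, while
mixed-unit groups go through a PCA on the correlation matrix (units
differ, so the covariance matrix would weight members arbitrarily),
retaining the first two components with their explained-variance
fractions; component signs are fixed by making the largest-magnitude
loading positive. Every reduced covariate is z-standardized over the
informative interval years before entering a design, so slopes are
comparable across covariates.

## Model selection and covariate testing

QAICc = DEV/ĉ + 2np, with the optional small-sample term
2np(np+1)/(ess − np − 1), where the effective sample size is the total
number of releases. The published selection table this package mirrors
reconstructs exactly without the small-sample term, so that term
defaults off in replication mode and should be switched on for new
analyses. Models within ΔQAICc ≤ 2 of the best are flagged preferred.

ANODEV locates a covariate model between a constant and a
time-dependent reference:

    F = [(DEV(Mcst) − DEV(Mcov))/n_cov] / [(DEV(Mcov) − DEV(Mt))/(n − n_cov − 1)]

on (n_cov, n − n_cov − 1) df. The reference size *n* is taken as the
number of *informative* time intervals of the time-dependent model (28
in the default two-panel design) — the time-varying survival parameters
the data can actually estimate — and is an explicit argument because
other conventions exist. The deviance R² is baseline-independent (any
common shift of the three deviances cancels), which is why printed
deviances from other software can be used directly.

## The synthetic-data generator

`simulate_histories` mirrors the generative side of the analysis model:
recruitment at active panel occasions with a geometric decay (rate
0.15/yr) favouring each panel's first years and a 3227:1328 panel
split; immediate permanent emigration with probability τ for transients
(the cleanest mechanism for prospecting animals — apparent survival
zero after marking, rather than merely lowered); resident survival
Φ_t = expit(β₀ + Σ β·z_t); detection at active occasions with
expit(capture_logit + δ·[captured at previous active occasion]).
Defaults are the study conditions: 4,555 individuals, β₀ = logit(0.915),
slopes (−0.104, −0.212, −0.137) for longlining effort, annual SOI and
two-year SST, base capture ≈ 0.6, δ = +1.5, τ = 0.3. One seeded
generator drives a run; identical seeds give byte-identical datasets.

Monthly covariates are synthetic by construction: SST is a seasonal
cycle plus AR(1) anomalies, SOI an AR(1), longline effort a positive
rise-and-fall series; a shared annual factor can be injected to
exercise the correlation-reduction rules. The generator emulates the
statistical structure the analysis assumes — it does not reproduce real
heterogeneity such as individual quality, age effects, mark loss,
density dependence, or spatially structured effort. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the assumed model, not the field validity of any particular
estimate.

## Problem sizes used in the test suite

Simulation scales are the package's own choices, set once: GOF null
calibration uses 500 replicates of 2,000 individuals over 12 occasions
(Φ = 0.87, p = 0.6), where every expected cell count sits safely in the
χ² asymptotic regime; transience/trap power and the suppression effect
use 100 replicates of 800 individuals; slope-coverage uses 100
replicates of 800 individuals over 15 occasions; the constant-survival
recovery runs at the full study scale (4,555 × 34). The likelihood
enumeration oracle covers designs up to 6 occasions, including a
gap-masked design.

## Known limitations

* No multistate or robust-design structures, dead recoveries,
  individual covariates, random effects, or Bayesian estimation.
* Gradients and Hessians are finite-difference; for very large designs
  (hundreds of parameters) the Hessian rank computation dominates
  runtime (`compute_np=False` skips it).
* The pooling floor (expected ≥ 2) is a pragmatic contingency-table
  rule; rejection rates at very sparse scales can drift a point or two
  from nominal.
* `.inp` I/O supports 0/1 histories with group-count columns and
  comments; losses-on-capture (negative counts) are not supported.
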