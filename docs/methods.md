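# Methods

## Model

`mslt` implements a three-state continuous-time Markov illness–death model
with recovery for interval-censored (panel) ageing-cohort data:

- state 1 — healthy (no functional limitation),
- state 2 — functionally limited,
- state 3 — dead (absorbing).

Four transitions are allowed: disability incidence (1→2), recovery (2→1),
mortality of the non-disabled (1→3) and mortality of the disabled (2→3).
Each transition intensity is log-linear in covariates,

```
q_rs(z) = exp( theta_rs + beta_age,rs * (age - 70) + beta_female,rs * female
             + beta_ow,rs * overweight + beta_ob,rs * obese ),
```

so `exp(beta)` is the hazard ratio of that covariate on that transition.
The covariate set and the age-centring constant live in `ModelSpec` and can be
changed; the default matches the SABE-Santiago style analysis (sex and WHO BMI
category with normal weight as reference, age centred at 70).

## Likelihood

Subjects contribute one factor per observation interval:

- **panel → panel**: `P_{x0,x1}(t0, t1)`, the transition probability between
  the observed states;
- **exact death**: `sum_s P_{x0,s}(t0, t1) * q_{s,3}(t1)` over living states
  `s` — the state immediately before death is unknown;
- **censored alive**: `sum_{s in {1,2}} P_{x0,s}(t0, t1)`.

Following the usual panel convention, the intensity matrix is held constant
within each observation interval at its interval-start age. Because state 3 is
absorbing, the matrix exponential of `Q` reduces exactly to the exponential of
the 2×2 living-state block, for which `mslt` uses a closed form via the
eigenvalues `m ± delta` of the block (the death column is the row complement).
This makes the likelihood fully vectorised over all observation intervals: one
evaluation on a 4 000-subject cohort takes milliseconds, and a full maximum
likelihood fit a few seconds. `scipy.linalg.expm` is retained in the test
suite as an independent route.

Estimation is by L-BFGS-B on the negative log-likelihood with
finite-difference gradients; initial values come from crude occurrence /
exposure rates (state-misclassification-naive, floored at 1e-4/yr). The
convergence flag requires both optimizer success and a numeric gradient
max-norm below `1e-4 * max(1, |loglik|)`; the scaling acknowledges that
finite-difference noise on an objective of magnitude ~1e3 makes an absolute
1e-4 unattainable. The covariance matrix is the Moore–Penrose pseudo-inverse
of the central-difference observed information (`h = 1e-4`), with a warning if
the information is not positive definite.

### Boundary-flat directions

When a covariate effect on a rare transition has essentially no attributable
events (typically female or obese effects on healthy-state mortality, the same
transition for which the original study reported intervals like 0.01–1.60),
the MLE drifts to the boundary and the information is singular or indefinite
in that direction. The reported covariance is the pseudo-inverse, as-is. Only
for the simulation-based confidence intervals are the covariance eigenvalues
clipped to `[0, SD_CAP**2]` with `SD_CAP = 10` log-units: curvature-free
directions get a wide-but-finite proposal spread instead of a numerically
meaningless one. `SD_CAP` is an order of magnitude beyond any data-supported
standard error on the log-hazard scale.

## Life expectancy

State occupancy from a starting age `a0` and state `r` is computed as a
product of interval exponentials on a 0.25-year grid (the intensity matrix is
refreshed at every grid age) up to age 115; expected years in each state
`e_rs` are trapezoid integrals of the occupancy curves (a warning is issued if
more than 1% of living mass survives the truncation age). Marginal
(population) life expectancies weight the healthy- and limited-start rows by
the model-predicted baseline prevalence of limitation from an in-package
logistic regression on age and the covariates:

```
LE = (1 - pi) * (e_11 + e_12) + pi * (e_21 + e_22)
```

and similarly for disability-free (DFLE, years in state 1) and disabled (DLE,
years in state 2) life expectancy; `%disabled = 100 * DLE / LE`. The identity
`LE = DFLE + DLE` holds exactly, per draw, by construction.

Uncertainty is quantified by simulation: parameter vectors are drawn from
`N(MLE, covariance)` (stabilised as above), every quantity recomputed per
draw, and 2.5/97.5 empirical percentiles reported. Draws whose worst-case
log-intensity over the integration ages would overflow are rejected, with a
hard error if more than 10% are rejected.

## Synthetic cohort generator

Because the original microdata are not public, the package ships a generator
that emulates the study design:

- baseline ages 60–90 drawn by decade weights (0.52, 0.33, 0.12, 0.03) and
  uniform within decade; sex fraction female 806/1216; per-sex WHO BMI
  category probabilities including a small underweight fraction;
- true transition intensities from `GroundTruthIntensities`: published hazard
  ratios as covariate effects, with baseline intensities
  (0.160, 0.180, 0.022, 0.110)/yr at the reference profile (male, normal
  weight, age 70) calibrated once so that model-implied life expectancies sit
  in a realistic range;
- trajectories simulated by 0.1-year micro-steps of the competing-risks
  process (exact within-step event-time jitter); a 5-year pre-baseline
  burn-in, conditioned segment-wise on survival (≤200 retries, healthy
  fallback), creates realistic prevalent limitation at baseline;
- interviews at 4.5 and 9.5 years after baseline with U(−0.5, 0.5) jitter and
  40% per-wave nonresponse; deaths observed exactly up to an administrative
  cutoff of 10.5 years; subjects alive but missing the final wave contribute a
  censored-alive record at the cutoff;
- ADL/IADL/mobility counts are drawn consistently with the latent state, so
  the phenotype rules (below) recover it.

Every subject has an independent `SeedSequence`-spawned substream, so cohorts
are reproducible and adding subjects never perturbs existing ones.

## Phenotype and exclusions

WHO BMI categories use half-open intervals (`25.0` → overweight, `30.0` →
obese). Functional limitation is defined as ADL ≥ 1 or IADL ≥ 2 or mobility
difficulties ≥ 3. Exclusions are applied in order: missing anthropometry
first, then underweight (BMI < 18.5), with a machine-readable exclusion log.

## Limitations

- Intensities are held constant within observation intervals (panel
  convention); fine-grained age dependence within intervals is ignored.
- The generator is a design emulator, not a reconstruction of the Santiago
  cohort; only the hazard-ratio structure is taken as ground truth.
- Simulation CIs rely on the asymptotic normality of the MLE, which fails in
  boundary-flat directions; the eigenvalue cap keeps the computation defined
  but intervals involving such directions should be read qualitatively.
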