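# Methods notes

This note records the statistical conventions the package commits to, the
places where the procedures' published descriptions left a choice open, and
what the simulation-based validation does and does not establish.

## Data model

A grouped experiment is a sequence of records `(t, d, c)`: at observation
time `t` (typically an integer day), `d` subjects were found dead and `c`
were censored during the interval. Censoring is assumed non-informative.
Within a record, censored subjects are counted as at risk for the deaths at
the same time and leave the risk set afterwards — the standard
right-censoring convention; all estimators and tests inherit it.
Duplicate-time rows are merged on parse (the product-limit estimator is
defined on distinct times), all-zero rows are dropped, and both repairs
warn rather than fail.

## Kaplan-Meier descriptives

* **Restricted mean.** Area under the KM step function from 0 to τ, with τ
  defaulting to the last *observed* time (death or censoring), so an
  uncensored experiment's restricted mean equals the arithmetic mean of its
  death times exactly. The standard error uses the classic KM area
  variance, `Var = Σ_j A_j² d_j / (n_j (n_j − d_j))` with
  `A_j = ∫_{t_j}^{τ} S`, without small-sample inflation factors; it
  reproduces R `survival::survfit`'s `se(rmean)` to 8 decimals on reference
  data. The 95% CI is the normal approximation.
* **Ages at % mortality.** The smallest event time with `S(t) ≤ 1 − q/100`,
  no interpolation. The 100% age is reported as undefined ("-") whenever
  the longest-surviving subject was censored, since the time of last death
  then understates the cohort's full mortality span.
* **Log cumulative hazard.** Default `y(t) = ln(−ln S_KM(t))`, so the curve
  is consistent with the displayed KM estimate; the Nelson-Aalen sum
  `ln(Σ d_i/n_i)` is available via `estimator="nelson-aalen"`. Points exist
  only at event times with `0 < S < 1`.

## Two-sample test conventions

* **Log-rank.** Hypergeometric variance with the `n_i − 1` denominator;
  event times with a single subject at risk contribute zero variance.
* **Weighted log-rank.** Fleming-Harrington weights evaluated on the
  *left-continuous* pooled KM estimate, the standard convention; with
  `rho = gamma = 0` the statistic reduces to the plain log-rank exactly
  (asserted to machine precision in the tests). Weight configurations that
  zero every variance term (e.g. `gamma > 0` with one event time) raise a
  "degenerate weights" error rather than returning 0/0.
* **Fisher at a mortality quantile.** The comparison time `t*` is the
  *first* pooled event time at or after the requested pooled KM mortality
  (nearest-time was the other candidate; first-at-or-after is
  deterministic and monotone in the fraction). Subjects censored strictly
  before `t*` are excluded from the 2×2 table — their status at `t*` is
  unknown; subjects censored exactly at `t*` count as alive. Two-sided
  p-value by probability-mass ordering of hypergeometric tables, not by
  doubling.
* **Permutation calibration (KS, Neyman).** Both tests permute group labels
  of the subject-level records with `p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm)`
  (default `n_perm = 2000`). This keeps them valid under crossing hazards
  and under the heavy day-ties of integer-day assays; the classical
  tie-free warning is still emitted because the asymptotic theory the
  procedures were derived under assumes no ties. Because permutation
  p-values are discrete, the exact-level rejection rule is `p ≤ α`.
* **Neyman smooth test.** The score alternatives use orthonormal Legendre
  polynomials `P_0 .. P_{d−1}` evaluated on the pooled Nelson-Aalen
  cumulative hazard rescaled linearly to [−1, 1]. This time transform is a
  documented approximation: it weights the basis by where death mass
  actually accrues, in the spirit of the smooth-test literature, and makes
  dimension 1 (constant weight) coincide with the log-rank direction — so
  the selected dimension reads as 1 = constant hazard ratio, 2 = monotonic,
  3 = convex/concave. The dimension is chosen by the Schwarz rule
  `argmax_d (T_d − d ln N)` with `N` the pooled death count; `max_dim`
  (default 5) is reduced with a warning when there are fewer pooled event
  times. The chi-square(1) approximation for the selected statistic is
  available (`p_method="chi2"`) but permutation is the default.
* **Chow test.** `k = 3` by default, matching the procedure's published
  parameter count for hazard-curve regressions, although a slope+intercept
  line has two coefficients; `k` is exposed for users who prefer the
  textbook 2.

## Variance tests

* **Death-time reconstruction.** The F-test needs a death-time sample, so
  each censored subject's unit mass is redistributed over the later death
  times in proportion to the KM conditional probability of dying there,
  `(S(t_{k−1}) − S(t_k))/S(t_cens)`. Mass falling beyond the last death
  time cannot be placed and is truncated with an explicit warning. This
  realizes "estimate the dead from S(t)" as conditional-probability
  bookkeeping; expanding censored subjects into pseudo-deaths or rescaling
  variances were rejected as alternatives because they either fabricate
  times or lose the weighting. Weighted variances use denominator
  `Σw − 1`; F degrees of freedom are `round(Σw) − 1` per group
  (fractional-weight df corrections are out of scope).
* **Shapiro-Wilk gate.** The F-test assumes Gaussian lifespans; each
  reconstructed sample (expanded to integer multiplicities) is screened and
  a warning is attached when either p < 0.01. The gate threshold is a
  module constant.
* **Partial-slopes rank-sum.** Slopes are successive difference quotients
  of the log cumulative hazard curve at its event times. At least six curve
  points per group are required (the slope count, not the animal count, is
  the effective sample size); 6–10 points add a low-power warning. The
  exact Mann-Whitney null is enumerated for ≤ 20 combined slopes without
  ties, otherwise the tie-corrected, continuity-corrected normal
  approximation is used.
* **Normalized Chow.** Time and log cumulative hazard are centered to mean
  zero within each curve; the pooled fit uses the per-curve-centered points
  re-centered as a set, which makes the statistic exactly invariant to
  independent vertical shifts of either curve (an intercept difference —
  i.e. a mean-lifespan difference — cannot leak into the pooled residuals).
  Fits are slope-only through the origin. The parameter count keeps
  `k = 3`: although only the slope is free after centering, null
  simulations under the package's own calibration design (two equal
  Gaussian(20, 4) integer-day cohorts, n = 100/group) show `k = 1` rejects
  at ≈ 0.21 at a nominal 0.05 while `k = 3` holds ≈ 0.059 — the extra
  denominator df absorbs the serial correlation of KM-derived residuals.
  `k` remains configurable.

## Cox regression

Newton-Raphson from β = 0 with step-halving (the log partial likelihood is
non-decreasing across iterations); convergence at gradient max-norm < 1e-9.
Breslow ties by default — the convention of most legacy survival tools —
with Efron available. A coefficient escaping |β| > 20 with the likelihood
still rising is reported as complete separation of risk. Robust standard
errors use the score-residual sandwich `I⁻¹ (Σ UᵢUᵢᵀ) I⁻¹` with
Breslow-form residuals (under Efron ties the robust variance therefore
carries a Breslow-level tie approximation). The baseline hazard is not
estimated: only β inference is reported, matching the package's output
contract. The score test at β = 0 with one binary covariate and no ties
equals the log-rank chi-square — asserted to 1e-8 in the tests as a
cross-module consistency check.

## The simulator and what validation shows

`simulate_lifespans` draws death times from Gaussian, Gompertz
(`h(t) = a·e^{bt}`, inverse-transform sampled) or exponential families,
truncates to positive times, optionally censors a fixed fraction at
uniform(0, death) times (non-informative), and records on an integer-day
grid — emulating a daily scoring schedule. The three-cohort validation
design uses A ~ N(20, 2²), B ~ N(20, 4²), C ~ N(30, 4²) days, where the
spread parameters are read as standard deviations (their unit is days);
the default cohort size is 250, chosen so the qualitative discrimination
pattern is reproducible with high probability across seeds.

What the simulations do *not* cover: real assays have informative
censoring, inter-plate batch effects, misclassified deaths (bagging,
matricide) and non-Gaussian tails; passing the validation pattern shows the
tests respond to mean vs variance differences as designed under clean
conditions, not that they are robust to those artifacts.

Measured calibration under the null design (two equal Gaussian(20, 4)
cohorts, n = 100/group, high-replicate runs): log-rank ≈ 0.050, censored KS
≈ 0.042 (slightly conservative from tie-induced discreteness of D), Neyman
≈ 0.05, F-test ≈ 0.05, normalized Chow (k=3) ≈ 0.059. The partial-slopes
rank-sum test is strongly conservative (≈ 0.004 at nominal 0.05): the
slopes within one curve share the cohort's hazard trend, so the two slope
sets interleave far more tightly than exchangeable iid samples would. It
still ranks spread differences correctly (its rejection rate on SD-2-vs-4
cohorts exceeds its null rate by two orders of magnitude), but its p-values
should be read as conservative. Likewise, the log-rank test is *not*
powerless against pure spread differences: at n = 250/group it rejects the
equal-mean SD-2-vs-4 pair most of the time, so "log-rank non-significant,
F-test significant" patterns should be expected mainly at smaller cohort
sizes (see the README example at n = 120).

## Numerical details

* Survival factors with an empty risk set are treated as 1 (the KM step
  carries forward); Greenwood terms at `S = 0` contribute 0.
* The smooth-test covariance gets a 1e-10·trace ridge before solving, so
  near-degenerate permutations stay finite.
* Collinearity in Chow-type tests is declared when `RSS₁+RSS₂` falls below
  1e-12 of the response's sum of squares.
* Permutation engines are vectorized across permutations (label matrix ×
  per-subject indicator matrices), so 1000-replicate calibration runs with
  ~1000 permutations each complete in seconds.
* All simulation seeds flow through `numpy.random.SeedSequence` spawning;
  identical seeds give identical datasets byte-for-byte.
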