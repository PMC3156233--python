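# lifespans

Survival analysis for lifespan assays in aging research: Kaplan-Meier
descriptive statistics, two-sample tests for differences in lifespan
*length*, in hazard-function *shape*, and — the part mean-oriented tools
miss — in lifespan *variance*, plus Cox proportional-hazards regression and
a lifespan-assay simulator for validation.

The package is aimed at researchers who score survival cohorts (worms,
flies, mice, cells) on a fixed schedule and record, per observation day, how
many subjects died and how many were censored. Even isogenic populations in
a controlled environment differ in how *spread out* their deaths are, and
two cohorts with indistinguishable mean lifespans can have very different
lifespan variances. The usual toolbox (log-rank, Fisher's exact) is nearly
blind to that, so this package pairs the standard tests with three
variance-directed ones.

## Methods at a glance

**Kaplan-Meier.** With `d_j` deaths among `n_j` subjects at risk at the
distinct death times `t_j`, the survival estimate is
`S(t_j) = ∏_{i≤j} (1 − d_i/n_i)`, with Greenwood pointwise variance
`S(t_j)² Σ_{i≤j} d_i/(n_i(n_i−d_i))`. Reported descriptives: the restricted
mean (area under `S` up to the last observed time, with the classic
area-variance SE and a normal-approximation 95% CI) and ages at 25/50/75/90/
100% mortality. The log cumulative hazard curve `ln(−ln S(t))` is linear
under Gompertz mortality; its slope reads as the rate of aging.

**Lifespan length.** Log-rank (Mantel-Cox)
`χ² = (Σ(d_{1i} − e_i))² / Σ v_i` with hypergeometric variance `v_i`; the
Fleming-Harrington `G(ρ,γ)` weighting `w_i = S(t_i−)^ρ (1−S(t_i−))^γ` to
stress early (ρ>0) or late (γ>0) deaths; Fisher's exact test on the
alive/dead 2×2 table at the time the pooled cohort reaches a chosen
mortality (90% by default).

**Hazard shape.** A censored two-sample Kolmogorov-Smirnov test
(`D = sup_t |S₁−S₂|`, permutation-calibrated); Neyman's smooth test with
Legendre-polynomial alternatives and a Schwarz-rule data-driven dimension
whose value describes the difference (1 = constant hazard ratio,
2 = monotonic, 3 = convex/concave); the Chow structural-break F-test on
straight-line fits to two log cumulative hazard curves.

**Lifespan variance.** A survival-time F-test on (censoring-adjusted) death
times, gated by Shapiro-Wilk normality screening; a Wilcoxon rank-sum test
on the sets of partial slopes of the two log cumulative hazard curves; and
a normalized Chow test that centers both curves to mean zero so that only
slopes — the variance-tracking feature — are compared.

**Risk factors.** Cox regression `h_i(t) = h₀(t) exp(β·x_i)` by
Newton-Raphson on the partial likelihood (Breslow or Efron ties), with
model-based and sandwich (robust) standard errors.

All pairwise comparisons are Bonferroni-corrected per method family.

## Input formats

Grouped survival tables are plain text: a `%` line carries the experiment
label, each data row is `time<TAB>deaths<TAB>censored`:

```
% A
16	1	0
17	10	0
18	10	0
```

Subject-level tables for Cox regression: a `%` line naming the fields, then
`time<TAB>status<TAB>covariate...` rows (status 1 = dead, 0 = censored).

## Worked example

Simulate three 120-worm cohorts — A and B share a 20-day mean lifespan but
have SD 2 vs 4 days; B and C share the SD but differ in mean (20 vs 30
days) — then describe and compare them:

```sh
lifespans simulate --triplet --n 120 --seed 7 --out abc.tsv
lifespans describe abc.tsv
```

```
name  n_subjects  n_deaths  restricted_mean  restricted_mean_se  ci95_low  ci95_high  age_at_25pct  age_at_50pct  age_at_75pct  age_at_90pct  age_at_100pct
A     120         120       20.22            0.17                19.88     20.55      19.0          20.0          21.0          23.0          25.0
B     120         120       19.62            0.37                18.9      20.35      16.0          20.0          22.0          24.0          29.0
C     120         120       30.19            0.35                29.51     30.88      27.0          30.0          33.0          35.0          39.0
```

A and B are indistinguishable on the mean (20.2 vs 19.6 days) but B's
percentile ages are visibly more spread out. The tests make that precise:

```sh
lifespans compare abc.tsv --method logrank --method f_test --seed 1
```

```
group1  group2  method   p_value    p_corrected
A       B       logrank  3.12E-01   9.37E-01
A       C       logrank  5.17E-58   1.55E-57
B       C       logrank  8.62E-50   2.58E-49
A       B       f_test   5.22E-16   1.57E-15
A       C       f_test   3.06E-14   9.19E-14
B       C       f_test   5.63E-01   1.00E+00
```

The log-rank test cannot separate A from B (corrected p = 0.94) but the
survival-time F-test can (p = 1.6e-15); for B vs C — same variance,
different mean — the pattern flips exactly. Other methods
(`--method ks|neyman|chow|ranksum|normalized_chow|weighted_logrank|fisher`)
slot into the same matrix; `--compat-pvalues` renders p-values below 1e-10
as `0.00E+00` to mirror legacy report output.

The same operations are available as library functions
(`lifespans.logrank_test`, `lifespans.survival_time_f_test`,
`lifespans.fit_cox`, ...), each returning a `TestResult` or `CoxFit`
object.

## Layout

- `lifespans.io` — "%"-header tab-separated readers/writers
- `lifespans.km` — Kaplan-Meier, descriptives, log cumulative hazard
- `lifespans.location` — log-rank, weighted log-rank, Fisher at mortality
- `lifespans.shape` — censored KS, Neyman smooth, Chow
- `lifespans.variance` — survival-time F, partial-slopes rank-sum, normalized Chow
- `lifespans.cox` — proportional-hazards regression
- `lifespans.simulate` — Gaussian / Gompertz / exponential assay generator
- `lifespans.report`, `lifespans.cli` — pairwise matrices, Bonferroni, CLI

See `docs/methods.md` for modelling assumptions, parameter conventions and
known limitations.
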