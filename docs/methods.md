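# Methods

## Model

The package fits a panel graphical vector autoregression to few-wave,
many-subject item panels. Writing `y_it` for the p-vector of item responses
of subject i at wave t,

```
y_it = μ + m_i + η_it
η_it = B η_{i,t−1} + ζ_it,   η_i1 ~ N(0, Σ_η)   (stationary start)
m_i  ~ N(0, Σ_B),            ζ_it ~ N(0, Σ_ζ)
```

- `B` (temporal network) collects directed lag-1 coefficients; `b[j,i]` is
  the effect of item i at the previous wave on item j at the current wave,
  controlling for all other items and for stable person differences. The
  diagonal holds autoregressions.
- `Σ_ζ` and `Σ_B` are parameterized as Gaussian graphical models via their
  precisions `K = Δ(I − Ω)Δ` with `Δ` positive diagonal; the off-diagonal
  entries of `Ω` are exactly the partial correlations reported as edge
  weights (contemporaneous and between-subjects networks).
- `Σ_η` solves the discrete Lyapunov equation `Σ_η = B Σ_η Bᵀ + Σ_ζ`
  (scipy's solver; an explicit stationarity requirement, spectral radius of
  `B` below one).

Stacking a subject's T waves gives a pT-dimensional Gaussian with mean `μ`
tiled per wave and block covariance `Cov(y_t, y_s) = Σ_B + B^{t−s} Σ_η`
(t ≥ s). Subjects are independent, so the sample mean and denominator-N
covariance of the wide data are sufficient statistics and the deviance is

```
−2 logL = N [ pT log 2π + log|Σ| + tr(S Σ⁻¹) + (m̄−μ̃)ᵀ Σ⁻¹ (m̄−μ̃) ].
```

Assumptions worth stating explicitly: a single stationary mean `μ` shared
across waves (no wave-specific mean structure); unit lags between
consecutive waves even when calendar spacing is unequal (2013→2015→2018→2020
is modeled as three equal lags, matching the single-temporal-network
reporting convention; spacing is carried as metadata only); items treated as
continuous at fit time, the standard practice for 0–3 symptom codes; no
missing-data likelihood — listwise deletion is applied upstream.

## Estimation

Free parameters are `μ`, the unmasked entries of `B`, the unmasked
upper-triangle entries of both `Ω` matrices, and both `Δ` scalings
(optimised as log δ for positivity). Masked edges are held at exactly zero.
The objective is minimised by L-BFGS-B with box bounds (|ω| ≤ 0.99,
|b| ≤ 2, |log δ| ≤ 10) and barrier rejection: parameter points whose GGMs
are not positive definite, whose temporal matrix has spectral radius ≥ 0.999,
or whose implied covariance fails a Cholesky factorisation receive a large
penalty. Tolerances: gradient 1e-8, relative function 1e-12; optional
seeded jittered restarts (default none — the moment-based start below makes
them unnecessary on well-posed problems, and refits from jittered starts
agree to ~1e-4 in deviance).

Starting values come from the block structure of the sample covariance:
`Σ_B` from the average lag ≥ 2 cross-wave block (within-person dependence
has mostly decayed there), the within covariance `W` from diagonal blocks
minus `Σ_B`, `B` from the lag-1 blocks times `W⁻¹` (rescaled if unstable),
`Σ_ζ = W − B W Bᵀ`, each eigenvalue-floored to stay feasible, then
converted to (Ω, Δ).

Standard errors are Wald: the numeric central-difference Hessian of
deviance/2 on the natural parameter scale (statsmodels `approx_hess`),
inverted; a non-positive-definite Hessian marks standard errors unavailable
rather than failing. BIC uses N = subjects as the sample size — subjects,
not subject-waves, are the independent units.

## Model search

1. **Saturated**: all edges free.
2. **Prune**: every free edge (temporal entries including autoregressions,
   off-diagonal Ω entries of both GGMs) with two-sided Wald p ≥ α = 0.05 is
   fixed to zero in one simultaneous pass, then the model is refit from a
   warm start. Means and Δ scalings are never pruned. Simultaneous rather
   than sequential pruning is a deliberate choice: it is the common practice
   for this workflow and cheaper; the two differ only in pathological cases.
3. **Step-up**: each zero-fixed edge is scored by the exact likelihood-ratio
   improvement from freeing it alone (one-at-a-time warm-started refit —
   exact and simple to verify at desk scale p ≤ 10, in place of analytic
   modification indices). The best candidate is freed permanently while its
   χ²(1) p-value is below α **and** the BIC improves. Ties break by LRT,
   then network order (temporal, contemporaneous, between), then row-major
   edge order.
4. **Selection**: minimal BIC among {saturated, pruned, step-up}; ties go to
   fewer free parameters, then the earlier pipeline stage.

The whole pipeline is deterministic given the data and the seed (restart
jitter is the only randomness and is seeded).

## Scale scoring and trend analysis

Items are stored as raw frequency codes 0–3; the two reverse-keyed items
(5 and 8) contribute `3 − code` at scoring time, so raw and scored data are
never mixed. Totals range 0–30; total ≥ 10 classifies depression.
Prevalence uses the Wald interval `p̂ ± z√(p̂(1−p̂)/n)` with the exact normal
quantile (≈1.959964), clipped to [0,1]; report percentages round half-up to
two decimals. The Cochran–Armitage statistic uses centered wave scores
(default: wave ranks 1..T; calendar years available) and is z-scaled with a
two-sided normal p-value; it is invariant to affine score rescaling but not
to score spacing, which is why both score choices are exposed. No
continuity correction is applied.

One caveat for repeated-measures panels: the classical Cochran–Armitage
variance treats waves as independent samples. When the same N subjects are
measured at every wave the statistic ignores the within-person correlation,
so published trend statistics computed with correlated-data adjustments will
not match the classical value computed from the same per-wave proportions.
The implementation here is the classical independent-samples form (verified
against R's `stats::prop.trend.test`), and its value on any printed
prevalence table should be read with that in mind.

## Synthetic data generator

The generator emulates a four-wave ageing-cohort depression panel. Defaults:
N = 1393, T = 4 waves labelled 2013/2015/2018/2020, p = 10 items with
reverse items {5, 8}; sparse networks (edge density 0.15, cross-lags of
magnitude 0.1–0.25 with mostly positive sign, autoregressions 0.2–0.35,
GGM edges drawn similarly with positive-definiteness ensured by position
redraws and, failing that, proportional shrinkage); `δ_ζ = 1`, `δ_B = 1.2`,
giving a between-person variance share around 0.4 — realistic for stable
symptom traits. Item thresholds are placed at the normal quantiles of
cumulative probabilities (0.55, 0.80, 0.92) of each item's stationary
latent scale, producing the right-skewed code marginals (~55/25/12/8%)
typical of community symptom data; the implied bin probabilities are
available in closed form for testing. Baseline ages are drawn from a shifted
gamma (60 + Gamma(2.2, 3.6), i.e. mean ≈ 68), and binary covariates mirror
the cohort composition (54.63% male, 80.11% married). Reverse items are
flipped at file-writing time so raw files exercise the reverse-scoring path.
MCAR masking, when requested, is applied last.

Named scenarios fix the network structure with an internal structure seed so
that the run seed controls sampling only: `default`, `null` (all edges and
autoregressions zero), `recovery` (continuous-mode p = 6 testbed with six
cross-lags of magnitude 0.2–0.28, autoregressions 0.3, five GGM edges of
0.25–0.35 per network), and `trend`. The trend scenario adds per-wave
uniform latent mean shifts (0.139, 0.139, 0.190, 0.339 marginal-SD units),
calibrated once by large-N simulation so wave prevalences sit near
(0.37, 0.37, 0.42, 0.57) and then frozen. Trend-injected truths are flagged
non-stationary and the pipeline warns when fitting them: the single-μ model
absorbs a mean trend into its covariance estimates.

What the generator does **not** emulate: informative missingness and
attrition, item-response-theory measurement, demographic joint
distributions, or floor effects beyond what thresholds induce. Passing
recovery tests therefore demonstrates correctness of the estimator under
the model's own assumptions (plus threshold discretisation), not robustness
to real-survey features such as mode effects or panel conditioning.

## Validation sizes

Tests and the acceptance script validate at desk scale, chosen to make the
Monte-Carlo noise small relative to the assertions: likelihood oracle on
20-subject fixtures against a generic multivariate-normal density;
stationary covariance against fixed-point iteration on 100 random stable
systems (agreement < 1e-10); implied moments against a 200,000-subject
simulation (3 Monte-Carlo SEs entrywise); parameter recovery over 20
replicates of the p = 6, T = 4, N = 2000 scenario (sign recovery and mean
absolute temporal error); Wald-z calibration pooled over 30 null-model
replicates at N = 1000; ordinalization sign preservation over 8 replicates
at N = 1500.

## Known limitations

- Ordinal items are fitted as continuous; edge weights on coded data are
  attenuated relative to the latent truth (signs of strong edges survive —
  this is quantified in the test suite, not assumed).
- Wald pruning and LRT step-up are greedy; they carry no guarantee of
  finding the global BIC optimum over all masks.
- The numeric Hessian is O(k²) deviance evaluations; at p = 10 saturated
  (220 free parameters) standard errors take noticeably longer than the fit
  itself.
- A single μ across waves means mean trends masquerade as covariance
  structure; analyse trends with the prevalence tools, not the network
  model, or model the trend explicitly upstream.
- No survey weights, imputation, or FIML for missing data (listwise
  deletion only, by design).
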