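# panelgvar

Longitudinal symptom-network analysis for multi-wave panel studies, built
around the **panel graphical vector autoregression (panel-GVAR)** model. The
package targets the workflow used in epidemiological studies of late-life
depression: score the 10-item Center for Epidemiological Studies Depression
scale (CESD-10) across survey waves, track depression prevalence over time,
and decompose the symptom dynamics into three networks —

- a **temporal network** `B`: directed lag-1 coefficients, `b[j,i]` is the
  effect of symptom *i* at wave *t−1* on symptom *j* at wave *t* (the
  diagonal holds autoregressions);
- a **contemporaneous network** `Ω_ζ`: partial correlations of the
  within-wave innovation residuals;
- a **between-subjects network** `Ω_B`: partial correlations of the stable
  person-level symptom means.

For item vector `y_it` (p items, T waves, N subjects):

```
y_it = μ + m_i + η_it,      η_it = B η_{i,t−1} + ζ_it,
m_i  ~ N(0, Σ_B),           ζ_it ~ N(0, Σ_ζ),
```

with both covariances parameterized as Gaussian graphical models through
their precisions, `K = Δ(I − Ω)Δ`, so reported edge weights are partial
correlations. The stacked pT-dimensional Gaussian likelihood is maximised
directly; model search follows the saturated → pruned (Wald, α = 0.05) →
step-up (likelihood-ratio re-addition) pipeline with BIC selection. Node
importance uses **expected influence** (EI; signed edge-weight sums) and its
directed analogues in-EI/out-EI, excluding autoregressive self-loops.

A seeded latent-Gaussian threshold generator emulates a four-wave ageing
cohort (N = 1393, 10 ordinal items coded 0–3, two reverse-keyed items,
optional MCAR missingness), so the full pipeline runs and is tested without
any restricted survey data.

## Worked example

```python
from panelgvar import (PanelGVAR, run_search, scenario, simulate_panel,
                       prevalence_by_wave, cochran_armitage)

# rising-prevalence scenario at study scale (N=1393, four waves)
sim = simulate_panel(scenario("trend", seed=7))
for r in prevalence_by_wave(sim.dataset):
    print(f"{r.wave}: {100*r.prevalence:.2f}% ({100*r.ci_low:.2f}-{100*r.ci_high:.2f})")
res = cochran_armitage([(r.k, r.n) for r in prevalence_by_wave(sim.dataset)])
print(f"Cochran-Armitage z = {res.z:.3f}, p = {res.p_value:.3g}")

# network estimation on a continuous six-item testbed
latent = simulate_panel(scenario("recovery", seed=7)).latent
best, trace = run_search(PanelGVAR(latent, n_items=6, n_waves=4), alpha=0.05)
print(best.summary())
```

prints

```
2013: 36.04% (33.52-38.56)
2015: 34.46% (31.96-36.95)
2018: 40.92% (38.34-43.50)
2020: 57.65% (55.05-60.24)
Cochran-Armitage z = 12.043, p = 2.1e-33

Panel-GVAR results [pruned]
================================================================
subjects: 2000    waves: 4    items: 6
log-likelihood: -76988.565    free parameters: 40
BIC: 154281.165    AIC: 154057.129    converged: True
----------------------------------------------------------------
temporal network: strongest edges
  y3 -> y3: +0.3349 se=0.0203 z=16.51
  ...
```

The per-wave lines give the depression prevalence (CESD-10 total ≥ 10) with
Wald 95% intervals; the positive trend statistic confirms the designed
rise. The summary shows the BIC-selected model: autoregressions near their
generating value 0.3 survive pruning, and `best.centrality()` returns the
EI / in-EI / out-EI tables with ranks.

The same pipeline is available from the shell:

```bash
panelgvar simulate --scenario default --seed 1 --out sim
panelgvar analyze  --scenario trend   --seed 1 --out analysis
panelgvar report   --analysis-dir analysis
```

`analyze` writes the exclusion ledger, prevalence/trend tables, fitted
networks (`edges.csv`), centrality tables, the search trace and a
provenance record.

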