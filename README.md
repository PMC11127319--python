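# dmscore

Hierarchical Bayesian functional-score inference and simulation for
growth-based deep mutational scanning (DMS) screens.

A growth DMS screen tracks thousands of protein variants through rounds of
selection by sequencing the pool at time points `t = 0 … T` across `R`
replicates, giving raw counts `c[v,t,r]` per variant.  The quantity of
interest is each variant's **functional score** β<sub>v</sub> — the slope of
its normalized log-frequency trajectory over the screen (0 for wild-type-like
behavior, negative for depletion, positive for enrichment).  Per-variant
regression is noisy at realistic depths and replicate numbers; `dmscore`
stabilizes the estimates by sharing information across variants at the same
protein position and across variants with similar sequencing coverage.

## The model

Counts are wild-type-normalized and log-transformed with a pseudo-count of ½,

```
m[v,t,r] = log((c[v,t,r]+½)/(c_wt[t,r]+½)) − log((c[v,0,r]+½)/(c_wt[0,r]+½)),
```

so every trajectory starts at 0.  The hierarchical model is

```
m[v,t,r] | β_v, b_v      ~  Normal(β_v·t/T + b_v,  ε²_g(v))
β_v | φ_p(v), σ²_p(v)    ~  Normal(φ_p(v), σ²_p(v))
φ_p ~ Normal(0,1)        σ²_p ~ InvGamma(1,1)       ε²_g ~ InvGamma(1,1)
b_v ~ Normal(0, s_b²)
```

where `p(v)` maps variants to position labels (synonymous variants are spread
over artificial control positions; sparse positions are merged) and `g(v)`
groups variants by mean count so that low-coverage variants share an honestly
large residual variance.  The posterior is sampled either by a blocked Gibbs
sampler exploiting the model's full conjugacy (default) or by an in-package
No-U-Turn sampler; both target the same posterior and are cross-checked in the
test suite.  Significance is summarized by the **local false sign rate**,
`lfsr_v = min(Pr(β_v>0 | data), Pr(β_v<0 | data))`, estimated by counting
posterior draws.

The package also ships a generative screen simulator driven by five
interpretable summary statistics fitted from any real or synthetic screen —
sequencing dispersion η, library dispersion η₀, mutant-group proportions p̂,
variant-effect mixture parameters θ̂, and a Dirichlet concentration α̂ for the
per-position composition of effect groups — plus a benchmarking harness
(rank-FDR curves, sensitivity/FDR tables, Benjamini-Hochberg adjustment).

## Worked example

Simulate a negative-selection screen (800 variants, 40 positions, 3 rounds,
3 replicates, LOF mode at β = −3 holding 30% of variants), fit the model and
call variants:

```python
import numpy as np
from dmscore import (SimConfig, simulate_screen, preprocess_screen,
                     ModelSpec, fit_scores, compute_lfsr)
from dmscore.model import test_variants
from dmscore.simulate import default_summary

summary = default_summary()                      # η=50, η₀=5, LOF ~ N(−3, 0.5²)
sim = simulate_screen(summary, SimConfig(n_positions=40, n_mutants=20, seed=7))
ns = preprocess_screen(sim.screen)               # filter, impute, normalize, group
post = fit_scores(ns, ModelSpec(chains=2, warmup=500, draws=500, seed=7))
table = test_variants(compute_lfsr(post), cutoff=0.05, selection_sign="negative")
print(table.head(5)[["variant_id", "estimate", "se", "raw", "significant"]])
print(f"max split R-hat: {post.diagnostics['rhat_max']:.3f}")
```

prints

```
variant_id  estimate       se  raw  significant
     p7_m1 -5.216057 0.332447  0.0         True
    p9_m11 -4.935065 0.338156  0.0         True
   p40_m11 -4.664417 0.321648  0.0         True
   p10_m11 -4.530793 0.343101  0.0         True
    p6_m14 -4.362851 0.334570  0.0         True
max split R-hat: 1.012
```

The strongest depleters top the ranking (`raw` is the lfsr; 0.0 means every
posterior draw was negative), the posterior standard errors are ~0.33, and the
sampler converged (R-hat ≈ 1.01).  Comparing against the simulation's ground
truth, the posterior means correlate with the true scores at r = 0.986 and the
lfsr < 0.05 calls reach sensitivity 1.000 at an observed FDR of 0.078.

The same workflow is available from the shell:

```bash
dmscore simulate --summary summary.json --out sim/ --seed 7
dmscore fit --counts sim/counts.tsv --config fmt.yml --out scores.tsv
dmscore summary-fit --counts sim/counts.tsv --out fitted_summary.json
dmscore benchmark --scores scores.tsv --truth sim/truth.tsv --out bench/
```

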