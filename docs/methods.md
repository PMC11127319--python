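# Methods

## Scope and data model

`dmscore` analyzes growth-based deep mutational scanning screens given as a
variant × time-point × replicate tensor of raw sequencing counts `c[v,t,r]`,
with `t = 0` the pre-selection library and `t = 1…T` the selection rounds.
A variant is identified by its (position, mutant) pair; mutants are amino
acid substitutions, insertions, or deletions, and a contiguous indel is
annotated at its leftmost residue (an insertion between residues 99 and 100
is position 99; a deletion of 100–110 is position 100).  Missing counts are
carried as NaN throughout and are never conflated with zero.

## Pre-processing

The default pipeline runs, in order:

1. **Filtering** — a variant is dropped from a replicate when strictly more
   than 50% of its T+1 time points are missing there; variants missing from
   every replicate are removed.
2. **Imputation** — remaining missing cells are filled by k-nearest-neighbor
   averaging (k = 10) on log(c+½) profiles within the replicate
   (nan-Euclidean distance over mutually observed time points, neighbor
   average taken on the log scale and transformed back), or by zero-filling.
3. **Normalization** — the log-ratio transform shown in the README, against
   either the wild-type count series (designated rows, else the synonymous
   sum) or the per-column total.  The t = 0 term aligns every trajectory to
   start at exactly 0.
4. **Replicate integration** — a variant dropped in some but not all
   replicates has the missing replicate trajectories filled with the mean of
   its other replicates, on the normalized scale.
5. **Position labels** — synonymous and wild-type rows are spread over
   artificial control positions (sized to the maximum number of
   non-synonymous variants at any real position, partitioned by a seeded
   random shuffle) so that they participate in the positional hierarchy
   without borrowing real-position effects; adjacent real positions with
   fewer than 10 variants are merged left-to-right greedily, each merged
   block labeled by its leftmost residue, with a trailing short block merged
   into its predecessor.
6. **Mean groups** — variants are stably sorted by mean raw count and cut
   into blocks of 25 sharing one residual variance; a trailing block smaller
   than 12.5 is merged into its predecessor.  This encodes the
   mean–variance relationship: low-coverage variants share an honestly
   larger error term.

All thresholds (0.5, k = 10, 25, 10, the normalization method) are exposed
as function arguments and CLI flags with these defaults.

## Inference model

See the README for the full specification.  Notes on the choices that were
genuinely open:

- **Intercept prior scale** `s_b`.  The intercept b_v is a nuisance whose
  job is to absorb the per-variant sampling noise of the shared t = 0
  baseline count, which every post-selection observation of a variant
  inherits (log-scale sd ≈ 1/√c, i.e. 0.1–0.3 at typical per-variant
  depths).  Calibration runs on the package's own simulator show that a
  much tighter scale (e.g. 0.05) forces this shared noise into the slope:
  posterior standard deviations understate the truth by ~40% and ~16% of
  true-null variants reach lfsr < 0.05, versus the ~2–5% expected of a
  calibrated posterior.  The default is therefore `s_b = 0.3` — still a
  strong zero-centered prior relative to effect sizes of order 1 — and the
  scale is configurable.
- **Sampler.**  All full conditionals of the model are conjugate (the
  (β_v, b_v) pair is jointly Gaussian given the variances; φ_p is Gaussian;
  σ²_p and ε²_g are inverse-gamma), so the default engine is a blocked
  Gibbs sampler with exact conditional updates, vectorized across variants.
  Defaults: 4 chains × 1000 warmup + 1000 draws (tests and benchmark sweeps
  use 2 × 400–500, which already give split R-hat < 1.02 at V = 800).  An
  independent No-U-Turn sampler over the unconstrained parameterization
  (non-centered β, log-variances; dual-averaging step size, diagonal mass
  from the second warmup half) is provided both as an alternative engine
  and as a cross-check: the test suite verifies its gradient against finite
  differences and its posterior summaries against the Gibbs engine within
  Monte-Carlo error.
- **Position-unaware variant.**  With `position_aware=False` the φ/σ layer
  is removed and β_v ~ Normal(0, 1) directly, keeping only the variant and
  replicate structure.
- **Convergence handling.**  Split R-hat above 1.05 (any parameter) raises
  a warning and is recorded in the serialized diagnostics, but does not
  abort, so that large benchmark sweeps complete.
- **lfsr.**  Estimated by draw counting without smoothing; with a floor of
  1/(chains × draws) it is exactly 0 when every draw shares one sign.
  Variants are ranked by lfsr with ties broken by |posterior mean|
  descending.  Significance at a cutoff is strict (`lfsr < cutoff`), with
  optional restriction to the direction of selection.

## Summary statistics and the simulator

Five statistics summarize a screen for simulation:

- **η (sequencing dispersion)** — Dirichlet-multinomial MLE on synonymous
  counts at each post-selection time point around their t = 0 proportions,
  log-likelihood summed over all (t ≥ 1, replicate) observations and
  maximized by bounded scalar optimization on log₁₀η over [−3, 6] (a fit at
  the upper bound is flagged "effectively multinomial").  Concentrations
  follow the per-category convention (η · n_categories · proportions), so η
  is a per-category mean concentration.  Per-time-point fits are reported
  for diagnostics.  *Known bias:* because the t = 0 baseline is itself a
  noisy sequencing observation with the same dispersion, the fitted η
  measures the effective between-time-point dispersion, roughly η/2 when
  sequencing noise dominates; simulation inputs may therefore reasonably be
  set somewhat higher than fitted values, and the closure tests compare
  against the effective value.
- **η₀ (library dispersion)** — the same MLE on the t = 0 counts of all
  variants around a uniform composition; η₀ additionally absorbs library
  imbalance and is typically much smaller than η.
- **p̂ (mutant groups)** — per-mutant empirical score densities (bins of
  width 0.1 spanning the observed range padded by one bin), pairwise
  Jensen-Shannon divergence (natural log, bounded by ln 2, 0·log 0 = 0),
  complete-linkage hierarchical clustering cut at 4 groups by default.
- **θ̂ (variant-effect mixture)** — a Gaussian mixture (1–3 components,
  chosen by the number of modes) on non-synonymous scores fixes group
  cutoffs at the posterior-responsibility crossings between mean-ordered
  components; each group's Gaussian is then re-fit on its members.  Scores
  exactly at a cutoff join the lower-index group.  Group identity follows
  the re-fit means: the component nearest 0 is neutral, components whose
  sign matches the direction of selection are LOF, opposite-sign components
  GOF.  Synonymous variants form a separate control group.  Degenerate
  mixture fits are retried with fresh seeded initializations.
- **α̂ (positional composition)** — per real position, the count table over
  (mutant group × variant group) cells is normalized to a composition;
  positions are treated as exchangeable draws from a Dirichlet whose
  concentration is fitted by Minka's fixed-point MLE with moment-matching
  initialization.  Zero cells receive additive smoothing 10⁻⁶ because the
  Dirichlet density is degenerate on the simplex boundary; at least 3
  positions are required.

Naive per-variant scores (pooled OLS of m on t/T, two-sided t-test,
Benjamini-Hochberg adjustment) are the default input to summary fitting:
uncalibrated but unbiased, which is what a distributional summary needs.

The **simulator** mimics the experiment rather than the inference model:
mutants are apportioned to mutant groups by largest-remainder on p̂; each
position draws a (mutant group × variant group) composition from
Dirichlet(α̂) and allocates variant-group labels within each mutant group by
largest remainder (in `position_homogeneous` mode every position instead
draws a single variant group from the α̂ marginal, making the positional
prior correctly specified); LOF/GOF scores are Gaussian draws from θ̂ while
neutral and control variants are exactly 0; scores map to growth rates by
μ_v = sgn(δ)·(β_v/(δ·T·ln2) + 1) with pseudo-passing time Δt = |δ|·ln 2, so
the expected naive slope of the simulated log ratios equals β_v; cells start
from a Dirichlet-multinomial library draw (total 200 cells/variant by
default, concentration η₀ per variant), grow exponentially with Poisson
noise per round, and are sequenced as Dirichlet-multinomial reads (depth
D = 100 per variant, concentration η·V·proportions; a flag switches to the
total-concentration convention η·proportions).  Replicates are independent
biological replicates (library drawn per replicate).  Infinite dispersions
give exact multinomial sampling.  Output is bit-reproducible given
(summary, config, seed).

## What the simulator does and does not emulate

It reproduces the marginal score distribution (neutral + LOF/GOF modes),
library imbalance, sequencing over-dispersion, Poisson growth noise, and —
deliberately — a *violation* of the positional-information assumption in
standard mode, so that passing benchmarks cannot be credited to
prior/simulator alignment.  It does not emulate: position–position
dependence along the protein, codon-level structure or barcode effects,
batch effects between replicates, selection-induced changes in sequencing
depth, or binding/FACS-style selections.  Benchmarks passed on these
simulations therefore support robustness to over-dispersion and library
imbalance, not every feature of real screens.

## Benchmarking conventions

Methods are compared on the rankings they induce (ascending lfsr or
BH-adjusted p, ties by |estimate| descending) because the Bayesian and
frequentist significance scales are not directly comparable.  The rank-FDR
curve reports the true-neutral fraction among the top-k calls for every k;
sensitivity/FDR pairs are reported at cutoffs {0.001, 0.01, 0.05, 0.10}
after excluding calls whose estimated sign opposes the direction of
selection, with FDR undefined (NaN) when nothing is called; and
`sensitivity_at_fdr` matches methods at an observed FDR level for power
comparison.  On real data without ground truth, synonymous variants proxy
for true neutrals.

## Problem sizes used in the tests

The acceptance suite runs at desk scale, chosen so the full test suite
completes in well under a minute of sampling per fit: V = 1000 for the
multinomial-limit closure, V = 800 (2 chains × 500 draws) for posterior
recovery, and V = 300 over 10 seeds at T = 3, R = 1 for the
FDR/sensitivity comparison against the naive method — the single-replicate
regime is where the per-variant regression's residual degrees of freedom
collapse (df = 2) while the hierarchical model keeps power by pooling
residual variance across mean groups, and it is therefore the regime in
which the two methods genuinely separate.

## Known limitations

- The η estimator's baseline-noise bias (above) makes η̂ a lower bound on
  the pure sequencing dispersion; a user-settable multiplier compensates
  when simulating.
- lfsr thresholds do not translate to frequentist FDR levels; at matched
  nominal cutoffs on high-power screens the lfsr < 0.05 rule is more
  liberal than BH < 0.05.  Comparisons should be made at matched observed
  FDR or on full rank curves.
- With very few synonymous variants the control-position construction
  degenerates (single merged control label); with none it is skipped with a
  warning and wild-type normalization requires a designated reference row.
- The model assumes integer-indexed, evenly spaced selection rounds; uneven
  sampling times are not modeled (the regressor is t/T).
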