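# Methods

## Abundance model and simulation

Clonotype copy numbers are treated as i.i.d. draws from the zeta
distribution `P(X = x) = x^(−α)/ζ(α)` on x = 1, 2, 3, …, the discrete
power law with lower bound 1. α > 1 is the evenness parameter: near 1 the
distribution is extremely heavy-tailed (a few clones dominate), large α
pushes nearly all mass onto singletons, i.e. toward uniform relative
abundances. A repertoire of richness S is S independent draws, so by
construction the simulated S equals the richness parameter exactly and the
total copy number N is random.

The default simulation grid crosses α = 1.05…5.00 in steps of 0.05 (80
values) with S = ⌊10^(1+0.25k)⌋, k = 0…20 (21 values from 10 to 10⁶), 100
replicates per cell (`SimulationGrid`). Replicate seeds are a pinned
deterministic function of (base seed, α index, richness index, replicate
index) via `numpy.random.SeedSequence`, reduced mod 2³¹, so any cell can be
re-simulated in isolation.

**Sampler.** Draws use an exact inverse-CDF table for the head of the
distribution — extended until it covers all but `tail_mass = 1e−8` of the
probability or reaches `max_exact = 1e5`, whichever comes first — and, for
uniforms falling beyond the table, the continuous Pareto approximation
`x = ⌊(t + ½)(1 − v)^(−1/(α−1)) + ½⌋` of the conditional tail (t = last
tabulated integer, v the tail-rescaled uniform). The head is exact and at
α ≥ 1.5 carries ≥ 99.7% of the mass; at the grid's lowest α (1.05) roughly
half the draws come from the approximate tail, which is the standard
trade-off for this family of samplers. Both the cutoffs are parameters of
`sample_counts`. ζ(α) and the head table are cached per α. At α ≲ 1.2
individual draws can exceed the int64 range; the vector is then returned in
float64 (the indices depend only on relative abundances and small-count
buckets, both unaffected at these magnitudes).

## The twelve indices

Implemented exactly as defined on the abundance substrate (S, N, `n_i`
= number of clonotypes with exactly i copies, `p_i = x_i/N`):

| index | formula | notes |
|---|---|---|
| S | number of unique clonotypes | pure richness |
| Chao1 | `S + n₁(n₁−1)/(2(n₂+1))` | bias-corrected form; defined for n₂ = 0; ≥ S |
| ACE | `S_abund + S_rare/C + (n₁/C)γ²` | rare threshold 10 (parameter); `C = 1 − n₁/N_rare`; γ² clamped at 0 |
| Shannon | `−Σ pᵢ ln pᵢ` | natural log throughout |
| Inv.Simpson | `1/Σ pᵢ²` | Hill number q = 2 |
| Gini.Simpson | `1 − Σ pᵢ²` | = 1 − 1/Inv.Simpson |
| D3, D4 | `(Σ pᵢ^q)^(1/(1−q))` | Hill numbers q = 3, 4 |
| Pielou | `H / ln S` | undefined at S = 1 |
| Basharin | `(H − (S−1)/(2N)) / ln S` | the only index reading N |
| d50 | `100·k/S`, k = shortest descending prefix with sum ≥ N/2 | reported in percent (flag for fraction) |
| Gini | `Σᵢⱼ|pᵢ−pⱼ| / (2S²·p̄)`, `p̄ = 1/S` | computed by the O(S log S) sorted identity, verified against the double sum |

Degenerate inputs never abort a vector: each index carries a status
(`ok`/`undefined`/`fallback`). Pielou and Basharin are undefined at S = 1;
ACE is undefined when every rare clonotype is a singleton (coverage 0) and
falls back to `S_abund` when there are no rare clonotypes at all. `Σ pᵢ^q`
uses compensated (fsum) summation so the identities hold to ~1e−12 at
S up to 10⁶.

One documented wrinkle: the correction term makes Basharin ≤ Pielou for
p derived from counts, hence J′ ≤ 1; reports of Basharin values up to ~1.2
in the literature cannot arise from this formula as printed. We implement
the formula as printed and enforce no upper bound. Note also that Chao1 and
ACE are *not* invariant to multiplying all counts by a constant (they read
absolute singleton/doubleton structure), unlike the relative-abundance
indices; Basharin is non-invariant through N.

## Reading and preprocessing repertoires

Three TSV dialects are supported (immunoSEQ-style, AIRR, generic); the copy
column is selectable because immunoSEQ exports carry reads (older assay
versions) or templates (newer), which shifts the apparent skewness
substantially. Nonfunctional sequences (out-of-frame / stop codon;
`frame_type != In`, `productive = F`) are removed before analysis.
Duplicate clonotype ids are aggregated by summing counts, since everything
downstream depends only on the count vector.

The evenness exponent α̂ is the zeta-distribution MLE: maximize
`−n ln ζ(α) − α Σ ln xᵢ` by bounded scalar optimization on (1.01, 50],
tolerance 1e−6 (ζ via `scipy.special.zeta`). All-singleton samples are
rejected — the likelihood then increases monotonically in α and the
exponent is unidentifiable.

Outlier screening applies the adjusted boxplot for skewed data on four
per-sample statistics (unique count, median copies, total count, α̂): with
medcouple MC and fences `[Q1 − 1.5e^(−4MC)·IQR, Q3 + 1.5e^(3MC)·IQR]` for
MC ≥ 0 (mirrored otherwise; Tukey's rule at MC = 0), a sample is an outlier
when flagged on at least two statistics. Quartiles use the
linear-interpolation convention (pinned — fence membership depends on it);
zero-IQR criteria flag nothing; the medcouple is the O(n²) pairwise-kernel
statistic (via statsmodels), appropriate for the tens-of-samples cohorts
this targets.

## Subsampling robustness

Downsampling to depth d draws d copies without replacement — the
multivariate hypergeometric over clonotypes. Depth grids take the observed
minimum-to-maximum range with `n_log` log-equally-spaced points (endpoints
included) plus `n_extra` linearly spaced points strictly inside the top
log-interval, where log spacing leaves the widest gaps; the full design
(10 + 4) gives 14 depths. Depths exceeding a sample's total are skipped for
that sample, never clamped. Populations beyond the exact sampler's range
(≥ 1e9 copies, possible at α ≤ 1.5) are handled by peeling the dominant
clones with a clipped normal approximation to their hypergeometric
marginals before exact sampling of the remainder; the approximation error
is O(1/√d) on clones carrying ~10⁹ copies and does not touch exact-range
repertoires.

Per index and depth, CV is the sample SD over mean across repeats
(undefined when the mean is 0, e.g. Shannon of a single-clonotype sample),
and RE is `|value − reference|/|reference|` per repeat against the
full-sample reference, medianed over repeats. Dataset summaries take
medians over all (sample, depth) cells and OLS slopes of CV and RE against
log₁₀ depth (raw-depth fits behind a flag; depths span orders of
magnitude, so the log axis is the meaningful one). The robustness score
ranks indices within each dataset on median CV, |CV slope|, median RE and
|RE slope| (rank 1 = smallest, ties averaged) and sums ranks over datasets;
smaller is more robust.

## Group comparison and variable importance

Mann–Whitney U is two-sided; the exact null is enumerated for tie-free
groups of ≤ 20, otherwise the normal approximation with tie correction is
used. The rank-biserial effect size uses the absolute form
`|1 − 2U/(n₁n₂)|`, which makes the choice of group immaterial; magnitudes
are labelled at 0.1/0.3/0.5/0.7. No multiple-testing correction is applied
by default (an explicit choice — callers comparing many indices can correct
downstream). Correlation matrices (Pearson and Spearman) are
pairwise-complete with columns under 3 finite values dropped.

Variable importance standardizes on *permutation importance* (mean R²
degradation over ≥ 10 shuffles of one predictor, fixed seed) applied to one
of three pluggable regressors on (log₁₀ S, α): a random forest, a spline
basis with pairwise interactions, and an additive per-feature spline model.
Model-specific importance measures (out-of-bag accuracy deltas, GCV
tracking, coefficient magnitudes) are deliberately not reproduced: they are
mutually incomparable, whereas the permutation contract is model-agnostic
and reproducible; the `model_tag` records which regressor was fit. The two
shares are clipped at zero and scaled to sum to 100%.

## What the generator does and does not emulate

The synthetic repertoires reproduce the abundance structure that drives
index behavior — power-law counts with controlled richness and evenness —
but contain no technical noise (no library-preparation or amplification
artifacts, no sequencing error, no template/read conversion effects) and no
sequence-level detail (no CDR3 strings, no V/J usage). Passing tests
therefore demonstrate correctness of the statistics and the qualitative
richness/evenness behavior of the indices, not robustness to
platform-specific measurement error in real immunosequencing data.

## Problem sizes in the shipped tests

The test suite runs the studies at reduced scale, chosen to exercise the
same qualitative contrasts: sampler fidelity and α recovery at 10⁵ draws;
importance analysis on a 14 × 7 grid (α step 0.3, richness 10…10⁴ in
half-decade steps, 10 replicates); robustness on two 20-sample datasets
(α = 1.5 vs 3.5, S = 5000) over 5 depths × 25 repeats. The full-scale
design remains available through `SimulationGrid` defaults and the CLI.

## Known limitations

* The placement of the supplementary depths inside the top log-interval is
  one reasonable reading of "additional upper-range values"; it is a
  parameter (`n_extra`), not a law.
* The tail of the power-law sampler is approximate beyond the exact-CDF
  table, which matters mostly for α < 1.3.
* ACE requires at least one non-singleton rare clonotype; on very shallow
  subsamples it is frequently undefined, and those repeats are excluded
  from CV/RE (tracked via `n_ok`).
* Effect-size and importance analyses assume exactly two groups and two
  predictors respectively, matching their design scope.
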