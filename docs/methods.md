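# Methods

## The factorial interaction model

Each gene is fitted independently by ordinary least squares to

    x = mu + d·[treated] + c·[alt phenotype] + e·[treated ∧ alt] + eps

with 0/1 indicators under reference-level (treatment-contrast) coding. The
design written this way is saturated for a 2 × 2 layout: on balanced data the
fitted cell means equal the observed cell means exactly, and the interaction
`e` is algebraically identical to the difference-of-differences of cell means,
`(mean[alt,drug] − mean[alt,ctrl]) − (mean[ref,drug] − mean[ref,ctrl])`. The
fit is computed for all genes at once from a single `lstsq` factorisation of
the shared design matrix; the residual standard deviation uses n − 4 degrees
of freedom and is reported as 0 when n = 4 (saturated design with one
observation per cell). Genes are ranked on the raw `e` — no standardisation
and no per-gene significance filter — because the downstream enrichment step
consumes only the extreme ranks, and the estimate's sampling spread is common
across genes when the design is shared.

**Reference levels.** The contrasts above depend on which level of each factor
is the reference. The reader takes explicit `treatment_ref` / `phenotype_ref`
arguments; if omitted, the reference is the level that appears first in the
sample sheet. The synthetic generator writes control and the sensitive
phenotype first, so its defaults match the intended coding (treated effect
positive for induced genes, `e` negative for responses dampened in the
non-reference phenotype).

**Tail selection.** The responsive set is the union of the k largest and k
smallest interaction values with k = max(1, floor(fraction·G)) and fraction
0.05 by default — rank-based tails rather than interpolated percentile
thresholds, because the downstream contingency tables need an exact,
deterministic gene count. Boundary ties are broken by gene identifier, and the
bottom tail is filled from genes not already taken by the top tail, so the two
tails are disjoint even when the ranking is fully tied. Fractions must lie in
(0, 0.5); selections whose tails would overlap raise an error rather than
silently shrinking.

## Enrichment statistics

For every gene set the 2 × 2 table (responsive ∩ set, responsive \ set,
set \ responsive, remainder) is formed inside a **universe** of genes. The
default universe is the intersection of measured genes with genes appearing in
at least one set of the collection, which guards against inflated enrichment
when the compendium covers only part of the array; `universe_mode="measured"`
uses all measured genes instead. Both are defensible and the choice is
explicit configuration.

The two-tailed Fisher exact p uses the probability-mass convention (sum of
hypergeometric point masses not exceeding the observed table's, with ~1e-7
relative slack for floating ties), delegated to `scipy.stats.fisher_exact`
and verified in the test suite against an exhaustive enumeration oracle for
every margin combination with universe ≤ 25. Odds ratios are the plain
cross-product `(a·d)/(b·c)`; when any cell is zero the Haldane–Anscombe
half-count correction `((a+½)(d+½))/((b+½)(c+½))` is reported instead so
volcano coordinates are always finite. Directional odds ratios recompute the
table using only the top tail or only the bottom tail, which reveals the
phenotype in which a set's response is preferentially induced.

Transcription factors are called significant at a strict fixed cutoff
(default p < 1e-5), a Bonferroni-style bound appropriate for compendia of
under two thousand factors; pathway collections are corrected with
Benjamini–Hochberg step-up q-values (`statsmodels.multipletests`, checked
against the naive quadratic definition). Sets with fewer than 2 genes in the
universe are emitted with a `too_small` flag and never flagged significant.
The volcano table carries log2 OR and −log10 p (clipped at 300) per set.

## Target-stratified fold changes

Per gene and phenotype, the log2 fold-change is the difference of mean log2
levels, treated minus control — never back-transformed, since the entire
pipeline stays on the log2 scale. The per-gene `delta = fc_ref − fc_alt`
measures how much the drug response is dampened in the non-reference
phenotype; on balanced designs it equals −e exactly (a cross-module identity
the tests enforce to 1e-10). Strata (targets vs non-targets of the factor
under study) are summarised by means with 95% t confidence intervals
(mean ± t(0.975, n−1)·sd/√n) and compared with a two-tailed Welch t-test on
the per-gene deltas (Welch–Satterthwaite degrees of freedom). Strata with
fewer than 2 genes, or with zero variance in both strata and unequal means
(infinite t), are flagged `degenerate` instead of reporting a fabricated
statistic. The `delta_of_deltas` — target mean delta minus non-target mean
delta — is the aggregate estimate of the planted/biological dampening.

## Growth kinetics

Volumes use the ellipsoid caliper formula V = L·W·H·π/6 (mm³). Growth rates
are fitted **per tumor** over all recorded timepoints (optionally windowed by
`day_min`/`day_max`) as the OLS slope of ln V on day; zero-volume points are
excluded from the log fit with a logged count, and the endpoint fold-increase
is last/first recorded volume. Fitting per tumor (rather than per group) gives
one endpoint per animal, which is what the two-way ANOVA needs. That ANOVA
(`endpoint ~ vector * treatment`, Type II sums of squares, equal to Type I/III
for the interaction on balanced data) tests whether the perturbation changes
the drug's effect; each cell must contain at least two tumors. When the model
is saturated (zero residual variance) the interaction F is undefined; the
implementation returns F = 0, p = 1 when the interaction sum of squares is
also zero, and F = ∞, p = 0 otherwise, rather than dividing by zero.
Repeated-measures ANOVA over time is deliberately out of scope: it requires
covariance-structure assumptions the endpoint analysis avoids.

## Synthetic data

`simulate_experiment` draws per-gene truth directly from the factorial model,
so the generator's parameters are exactly the estimands of the fit:

| parameter | default | meaning (log2 units unless noted) |
|---|---|---|
| n_genes | 10,000 | measured genes, ~array scale |
| n_tfs × targets_per_tf | 50 × 200 | compendium size and set size |
| reps_per_cell | 2 | → 8 samples, the profiled design |
| baseline mean ± sd | 8.0 ± 1.5 | typical log2 intensity spread |
| treatment_effect d★ | 1.0 | induction of active-TF targets |
| dampening δ★ | 0.6 | subtracted from d★ in the alt phenotype (planted e = −δ★) |
| background_effect_sd | 0.1 | small random d/c/e on background genes |
| noise_sd σ | 0.25 | replicate noise eps |

Background genes receive small random main effects and interactions so the
responsive tails are non-degenerate under the null; the planted interaction is
constant across the active factor's targets (an `effect_spread` parameter,
default 0, adds heterogeneity when wanted). Target sets are an optional shared
pool plus disjoint per-factor blocks, all drawn from one seeded
`numpy.random.default_rng`; identical seeds give bit-identical outputs. With
these defaults, the fitted interaction of a background gene has standard
deviation ≈ sqrt(2σ²) ≈ 0.35, so the planted −0.6 shift puts roughly half the
active factor's targets into the bottom 5% tail — a strong but not trivial
signal, comparable to what a clean biological hit looks like.

What the generator does **not** emulate: probe-level artefacts (saturation,
probe affinity, background), correlated genes, heavy-tailed noise, or
compositional effects. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the model's own assumptions, not
that any particular biological dataset satisfies those assumptions.

`simulate_growth` draws V(t) = v0·e^{kt}·e^{N(0,noise_sd)} per tumor and
reports L = W = H = (6V/π)^{1/3} so the volume formula inverts exactly.

## Preprocessing

Quantile normalization maps each column onto the mean-of-sorted-columns
reference; ties within a column receive the mean of the reference values over
the tied rank range (the common convention), which makes the operation
idempotent. Probe summarization excludes probes mapping to more than one gene,
then averages a gene's remaining probes per sample; unmapped probes are
dropped with a logged count. The default raw-intensity order is
quantile-normalize → log2 → summarize (log-scale means, geometric-mean-style);
summarizing before the transform is available through the standalone
functions, and both steps are skippable when the input is already a gene-level
log2 matrix. Background correction is intentionally not implemented: inputs
are assumed background-corrected or synthetic.

## Numerical and problem-size choices

Monte-Carlo checks use 20 simulated studies at the defaults (~1 s each with
the vectorised fit), 200 random balanced designs for the OLS/cell-mean
identity at 1e-10, an exhaustive Fisher sweep to universe 25, 500 random
p-vectors (lengths 1–200) for the BH identity at 1e-12, and 1000 null 2×2×5
experiments for ANOVA calibration (rejection rate expected in [0.03, 0.07] at
α = 0.05). Result tables are written with 17 significant digits so
write→read round trips are exact; determinism is enforced at the byte level
for whole-pipeline reruns with a fixed seed.

## Known limitations

- The fit assumes homoskedastic Gaussian noise per gene and shares no
  information across genes (no moderated variance); with 2 replicates per
  cell, per-gene significance of `e` would be weak, which is exactly why the
  pipeline ranks rather than tests genes.
- The enrichment universe choice materially affects odds ratios; both
  supported conventions are explicit rather than hidden.
- Identifier namespaces are taken at face value (case-sensitive,
  whitespace-stripped); no gene-symbol aliasing is attempted, so the
  expression matrix and GMT must share a namespace.
- The growth ANOVA treats endpoints as independent Gaussians; longitudinal
  correlation structure is out of scope.
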