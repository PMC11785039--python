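# chemoshift

Analysis pipeline for a recurring question in tumor biology: **when a tumor is
treated with chemotherapy, which transcription factors drive a *different*
transcriptional response in one malignant cell phenotype than in another?**
The motivating setting is colorectal cancer xenografts in which a
stem-like, chemo-resistant compartment (CSC-enriched, "bottom-of-the-crypt")
and a differentiated, chemo-sensitive compartment (CSC-depleted,
"top-of-the-crypt") are profiled side by side, with and without a
topoisomerase poison such as irinotecan — a 2 × 2 factorial expression design.

The package is aimed at computational biologists who have (or can simulate)
such a design and want the full chain from probe intensities to a ranked list
of differentially activated transcription factors, plus the tumor-growth
summaries used to quantify chemo-sensitization *in vivo*.

## The model

For each gene *g*, the log2 expression of sample *r* in treatment *i* and
phenotype *j* is modelled as

```
x_gijr = mu_g + d_gi + c_gj + e_gij + eps_gijr
```

fitted by ordinary least squares under reference-level coding (control
treatment, sensitive phenotype as references), so that per gene:

- `mu` — baseline log2 level in the reference cell,
- `d`  — treatment main effect in the reference phenotype,
- `c`  — phenotype offset under control,
- `e`  — the **interaction**: the difference-of-differences
  `(FC in non-reference phenotype) − (FC in reference phenotype)`,
  i.e. how much the drug response differs between the two phenotypes.

Genes in the top and bottom 5th percentile of the `e` ranking are called
**responsive**. Each transcription factor's annotated target set (GMT format)
is then tested for enrichment among the responsive genes with a two-tailed
Fisher exact test on the 2 × 2 overlap table within a gene universe; odds
ratios use the cross-product with Haldane–Anscombe correction on zero cells.
Transcription factors are flagged at a fixed conservative cutoff p < 10⁻⁵
(Bonferroni-style for a compendium of < 2000 factors); pathway collections
get Benjamini–Hochberg q-values instead. A target/non-target stratified
fold-change summary (means, 95% CIs, Welch t-test) quantifies how much the
drug-induced activation of the top factor's targets is dampened in the
resistant phenotype.

For the *in vivo* arm, caliper series are converted to volumes with
`V = L·W·H·π/6`, each tumor gets an exponential growth rate (OLS slope of
ln V on day) and an endpoint fold-increase, and chemo-sensitization by a
genetic perturbation is tested as the vector × treatment interaction of a
two-way ANOVA on those endpoints.

A synthetic-data generator produces factorial experiments with a planted
"dampened induction" transcription factor and tumor series with known rates,
so every stage is testable without any external download.

## Worked example

```python
import chemoshift as cs

config = cs.SimulationConfig(n_genes=5000, n_tfs=20, targets_per_tf=150, seed=7)
matrix, design, collection, truth = cs.simulate_experiment(config)

results = cs.InteractionModel(matrix, design).fit()
print(results.summary())
selection = results.select_responsive(0.05)
ranked = cs.rank_tfs(cs.enrich_collection(selection, collection, matrix.gene_ids))
top = ranked[0]
print(f"top hit: {top.set_name}  OR={top.odds_ratio:.2f}  p={top.p_value:.3g}")

records = cs.fold_changes(matrix, design, collection[top.set_name].members)
tgt, non, dod = cs.summarize_by_target(records)
print(f"delta-of-deltas = {dod:.3f}  (Welch p = {tgt.welch_p:.3g})")
```

prints

```
Factorial interaction model (treatment-contrast coding)
  genes: 5000   samples: 8
  treatment levels: ('control', 'irinotecan')   phenotype levels: ('NT', 'CSC')
  interaction e: mean=-0.02265  sd=0.3804
  median residual sd: 0.2295
top hit: TF001  OR=7.72  p=2.01e-26
delta-of-deltas = 0.616  (Welch p = 1.09e-49)
```

The generator planted TF001 as the active factor with its targets' 1.0-log2
drug induction dampened by 0.6 log2 units in the resistant phenotype; the
pipeline ranks it first with an overlap odds ratio of 7.7, and the stratified
fold-change analysis recovers the planted dampening (0.616 ≈ 0.6) with an
overwhelming Welch t-test against the non-target background.

The same analysis runs from the shell:

```bash
chemoshift simulate --outdir data --seed 7 --n-genes 5000 --n-tfs 20 --targets-per-tf 150
chemoshift fit-interaction --matrix data/matrix.tsv --sample-sheet data/sample_sheet.tsv \
    --fits-out fits.tsv --selection-out selection.tsv
chemoshift enrich --selection selection.tsv --gmt data/gene_sets.gmt \
    --matrix data/matrix.tsv --out enrichment.tsv
chemoshift run-all --config run.yaml --outdir out   # the whole graph + manifest
```

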