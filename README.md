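# cyclepred

Prediction of cell-cycle-regulated genes from promoter genomic features.

Time-course microarray screens miss periodically expressed genes that are
lowly expressed or lose synchrony, and different screens overlap poorly.
`cyclepred` implements the complementary, expression-free route: classify
genes as cell-cycle regulated from the **regulatory evidence in their
promoters** — transcription-factor binding strengths (ChIP-chip occupancy
ratios, *trans* features) and aggregated motif matching scores (*cis*
features). It targets the budding-yeast setting (hundreds of labeled
periodic/non-periodic genes, ~200 TF and ~540 motif features) but is
agnostic to the organism: any genes × features score tables in TSV form
will do.

## The model

For gene *i* with feature vector *x*ᵢ and label *y*ᵢ ∈ {0, 1} (1 = cell
cycle regulated), the core classifier is a ridge-penalized logistic
regression (PLR):

```
log [ Pr(y=1|x) / Pr(y=0|x) ] = β₀ + xᵀβ
(β₀, β) = argmin  −ℓ(β₀, β) + (λ/2)‖β‖₂²        (intercept unpenalized)
```

fitted by damped Newton/IRLS after a univariate pre-selection screen
(two-sample Student t-test, p < 0.001). Per-coefficient Wald z-scores
(SEs from the inverse penalized Hessian) flag the significant regulators.
Phase specificity (G1/S/G2/M peak) uses the multinomial extension (RMLR,
softmax link, per-class ridge, one-way ANOVA pre-selection at p < 0.01).
Performance is measured by stratified k-fold cross-validation: pooled
out-of-fold ROC/AUC for the binary model and the Hand–Till multi-class
AUC for the phase model,

```
AUC_total = 2 / (|C|(|C|−1)) · Σ_{i<j} [Â(i|j) + Â(j|i)] / 2 .
```

Downstream stages call novel genes (probability > 0.8 among unlabeled
genes), validate the calls (Fisher's exact test on protein–protein
interaction pair counts against known positives, Wilcoxon rank-sum on
periodicity/regulation scores, evidence-set support), and infer a TF→TF
regulatory circuit from quantile-normalized scores using three threshold
criteria (normalization score > 0.9, log₂ occupancy > 2, motif score
> 0.5).

A first-class synthetic-data generator (`cyclepred.synthgen`) produces
datasets with planted "driver" features, enriched PPI graphs and latent
novel positives, so the entire pipeline is testable end-to-end without
external data.

## Worked example

Simulate a desk-scale dataset (700 genes, 60 TF + 120 motif features,
300 positives / 300 negatives, effect-size-3 drivers) and run the whole
pipeline:

```bash
cyclepred simulate --out demo/fixture --seed 7
cyclepred -v run --workdir demo/fixture --out demo/results --seed 7
```

which logs:

```
cyclepred: combined matrix: 700 genes x 180 features
cyclepred: t-test selection kept 11 / 180 features
cyclepred: tf model CV AUC = 0.989
cyclepred: motif model CV AUC = 0.984
cyclepred: combined model CV AUC = 0.998
cyclepred: final model: 3 features significant at p < 0.01
cyclepred: 30 of 100 unlabeled genes called at cutoff 0.80
cyclepred: multinomial phase model: Hand-Till AUC = 1.000, accuracy = 0.993
cyclepred: PPI enrichment: OR = 5.11, p = 2.69e-92
cyclepred: circuit: 95 edges over 9 target TFs
summary written to demo/results/summary.json (combined AUC = 0.998)
```

Reading the numbers: the t-test screen keeps the planted drivers (11 of
180 features at p < 0.001); both feature classes alone discriminate well
(AUC 0.98–0.99) and combining them helps (0.998) — the qualitative
pattern the method is built on. Of the 100 genes left unlabeled, 30
clear the 0.8 probability cutoff (the fixture hides 30 latent true
positives among them), and the called set shows a 5-fold enrichment of
physical interactions with known positives. `demo/results/` also holds
the per-stage TSVs: ROC curves, out-of-fold predictions, the serialized
models with z-scores, called genes with phase probabilities, and the
circuit in DOT/GraphML with a per-candidate criterion report.

Every stage is also available as its own subcommand (`combine`,
`normalize`, `select`, `train`, `evaluate`, `predict`, `phases`,
`enrich`, `circuit`) operating on the same TSV files, and as library
functions (`cyclepred.classify.fit_plr`, `cyclepred.evaluate.kfold_cv`,
…) for programmatic use.

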