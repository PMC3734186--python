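# Methods

## Problem setting

A gene is *cell-cycle regulated* when its transcript level peaks at a
specific mitotic stage (G1, S, G2, M). The package predicts this label —
and the peak phase — from two promoter feature classes measured per gene:

- **trans features**: ChIP-chip occupancy ratios of transcription
  factors in the promoter; strictly positive, right-skewed, larger =
  stronger binding;
- **cis features**: aggregated motif matching scores — the sum of
  per-occurrence match scores of a motif in the promoter, exactly 0 when
  the motif is absent.

Feature tables are plain TSV (genes in rows; header ids prefixed `TF:`
or `M:`). Labels are `pos` / `neg` / `unlabeled` with an optional phase
for positives.

## Binary classifier (PLR)

Ridge-penalized logistic regression minimizing

    L(β₀, β) = −Σᵢ [ yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ) ] + (λ/2) ‖β‖₂²,
    pᵢ = logistic(β₀ + xᵢᵀβ),

with the intercept unpenalized. Solver: damped Newton (IRLS) with step
halving — the objective decreases monotonically, convergence is declared
at gradient max-norm < 1e-6, with a 100-iteration cap (a non-converged
fit is returned flagged). The solver is verified against an independent
dense-grid minimization on two-parameter problems (agreement to 1e-4)
and satisfies the exact duplicate-data/double-λ invariance of the
objective.

**Standardization.** Features are standardized (mean 0, SD 1) on the
training data by default, so a single λ is meaningful across the very
different TF and motif scales; coefficients are reported on the
standardized scale and the constants travel with the model. A
`standardize=False` flag gives the raw-scale fit.

**λ default = 1** on the standardized scale. Cross-validated AUC is flat
over a wide λ range on synthetic data (`evaluate.lambda_grid_auc`
reproduces this sensitivity check), so the default is not critical; it
is CLI-configurable.

**Significant features.** Wald z = β̂ⱼ / SEⱼ with SEs from the inverse of
the *penalized* Hessian at the optimum; two-sided normal p-values,
flagged at p < 0.01. This is one defensible construction among several
(the ridge sandwich estimator is another); it calibrates correctly on
pure-noise features in simulation. Note that exactly duplicated
features split their coefficient but *share* the evidence: each copy's
|z| drops by more than half because the duplicate-difference direction
is supported only by the penalty.

**Pre-selection.** Two-sample pooled-variance Student t-test per feature
(Welch behind a flag), keep p < α with α = 0.001; no multiplicity
correction (raw thresholds are the method's convention). A feature with
zero variance in both classes and equal means gets p = 1. By default
selection runs once on the full labeled set *before* cross-validation —
this replicates the original analysis but leaks selection information
into CV estimates; `--select-within-folds` re-screens inside each
training fold for the unbiased variant. Both modes are deliberate and
documented; the default exists for fidelity, the flag for rigor.

## Phase model (RMLR)

Multinomial logistic regression over (G1, S, G2, M) with softmax link,
per-class ridge (λ/2)Σ‖β_c‖² and unpenalized intercepts. The slope
penalty leaves the common-intercept direction of the softmax flat, so
intercepts are constrained to sum to zero — a pure reparameterization
that changes no probability but makes the Newton system nonsingular.
With two classes the model reproduces the binary PLR probabilities
exactly when the multinomial λ is twice the binary λ (each class carries
half the coefficient difference, so the penalty halves); this
equivalence is tested to 1e-6.

Pre-selection for the phase model is a one-way fixed-effects ANOVA
across phases (keep p < 0.01), applied within positives only. Phase
calls take the argmax class when its probability reaches the `unclear`
threshold (default 0.5; at a tie the earlier class in G1→S→G2→M order
wins, deterministically).

## Evaluation

- **Folds**: stratified k-fold (default k = 10), dealt round-robin per
  class with a single cursor across classes — per-fold class counts are
  within one gene of proportional, and k = n degenerates to exact
  leave-one-out. Seeded and deterministic.
- **ROC/AUC**: pooled out-of-fold scores, threshold-swept curve,
  trapezoidal area; ties get half credit, making the area equal the
  Mann–Whitney concordance estimator (tested exactly on random
  instances). Fold-wise AUC averaging is *not* used; pooling is the
  package's documented choice.
- **Multi-class AUC**: Hand–Till — for each unordered class pair {i, j},
  Â(i|j) ranks genes of classes i and j by their class-i probability;
  the pair score is [Â(i|j)+Â(j|i)]/2 and the total is the mean over
  pairs. Classes with no members are dropped with a warning.
- **Operating point**: (FPR, sensitivity) of a strict `score > cutoff`
  rule on out-of-fold scores, cutoff default 0.8.
- **Precision vs threshold**: fraction of genes whose top phase
  probability reaches t, and accuracy among them; at t = 0 this is plain
  multi-class accuracy.

## Downstream validation

- **Novel calls**: unlabeled genes with probability strictly above the
  cutoff; the remainder form the predicted-negative set.
- **PPI enrichment**: 2×2 table of cross pairs (called × known-positive
  vs predicted-negative × known-positive) split by presence of a
  physical interaction; Fisher's exact test, default alternative
  `greater` (the enrichment direction), sample odds ratio ad/bc. The
  two-sided p sums the probabilities of all tables as or less probable
  than the observed one; a zero margin returns p = 1 with odds ratio NA.
- **Rank-sum comparisons** (periodicity/regulation p-values, expression):
  Wilcoxon rank-sum; exact enumeration when the pooled sample is ≤ 20
  without ties, otherwise the tie-corrected normal approximation without
  continuity correction (so identical samples give exactly p = 1).
- **Evidence support**: a gene is supported when it appears in ≥ 1 of
  the supplied evidence sets (arbitrary named gene lists); called vs
  predicted-negative support is compared by Fisher's exact test.

## Quantile normalization and circuit criteria

To compare binding and motif scores on one scale, the combined matrix is
quantile-normalized: the reference distribution's k-th smallest value is
the mean over columns of each column's k-th smallest value; every column
then takes the reference values in its own rank order. Ties within a
column all receive the mean of the reference values at their tied ranks
(relevant for the exact zeros of motif columns). With this average-ties
convention the transform is exactly idempotent on tie-free data; columns
with heterogeneous tie patterns are perturbed at tie ranks by a second
application, which is why the idempotence property is stated for the
generic (tie-free) case. A single-gene matrix is returned unchanged.

A directed regulator → target edge is emitted when, in the target's
promoter row: (1) the normalization score exceeds 0.9, and (2) for
TF-binding evidence the log₂ occupancy ratio exceeds 2, or (3) for motif
evidence the raw aggregated matching score exceeds 0.5. "Normalization
score > 0.9" is read as a **rank quantile** — the fraction of genes with
a strictly lower normalized value for that feature — i.e. the feature
must rank in the top 10% of promoters; normalized values themselves are
unbounded, so an absolute reading is only available via
`ns_mode="value"`. The log base (default 2) is configurable since the
occupancy transform's base is a convention. TF-binding columns name
their regulator directly; motif columns yield edges only through an
explicit motif → TF map, and unmapped motifs never produce edges.
Repressive relationships curated from the literature (rather than
computed from these criteria) are out of scope.

## Synthetic data

The generator's defaults mirror the study dimensions: 6,229 genes,
203 TF + 539 motif features, 599 positive / 454 negative labels, with
phases drawn at the curated proportions 219/156/100/95. A desk-scale
variant (`scaled_config`: 700 genes, 60 + 120 features, 300/300 labels,
effect size 3) is used for seed sweeps; these are the package's standard
test conditions and are stated as such wherever results are reported.

- **Backgrounds**: TF block log-normal(0, 1) (positive, right-skewed);
  motif block zero with probability `motif_sparsity` (default 0.7), else
  the sum of 1 + Poisson(1) per-occurrence Uniform(0.5, 1) match scores
  (non-negative, right-skewed, exact zeros for absence).
- **Drivers**: `n_drivers_per_phase` features per phase plus the same
  number of global drivers, alternating between the TF and motif blocks.
  A driver shifts its target class (all true positives, or one phase's
  positives) upward by `effect_size` × the background SD of its block.
  TF drivers shift additively. Motif drivers *densify then boost*: the
  motif first becomes more prevalent in target promoters (sparsity
  shrinking toward 0), then gains a constant per-promoter score boost —
  the mean shift is exactly effect_size × SD, scores stay non-negative,
  zeros stay exact, and the mechanism matches how an elevated motif
  actually manifests (more occurrences). A purely additive shift on
  non-zero cells cannot exceed ~0.9 background SDs of standardized
  separation at 70% sparsity, which is why prevalence must move.
  Consequently the motif block's zero rate deviates from
  `motif_sparsity` by the planted cells; `expected_zero_fraction` gives
  the exact expectation for sparsity checks.
- **Latent truth**: a fraction `unlabeled_pos_frac` (default 0.08,
  matching the scale of the real study's novel-call rate) of unlabeled
  genes are true positives with phases and driver signal, so novel-gene
  calling can be scored against the truth file.
- **PPI graph**: independent edges at `ppi_base_rate`, multiplied by
  `ppi_pos_enrichment` (capped at 1) between true positives.
- **Auxiliary scores**: mock periodicity and regulation p-values
  (Beta(1,9) / Beta(1,6) for positives vs Uniform(0,1)) and mock
  expression (log-normal, lower mean for positives) support the
  rank-sum stages. **Evidence sets**: nine mock sources each reporting
  true positives at 6% and negatives at 2.3%, giving ~40% vs ~19%
  support — the contrast the support-enrichment test consumes.

What the generator does *not* emulate: feature–feature correlation
(real TFs co-bind), positional/orientation structure of motifs,
measurement error models of ChIP-chip, time-course expression profiles,
or synchronization loss. Passing tests therefore demonstrate that the
pipeline's statistics behave correctly under planted structure of
controlled strength — not that the real data meet these assumptions.

## Numerical and degenerate-input choices

- Solvers: gradient tolerance 1e-6, iteration cap 100, IRLS weights
  floored at 1e-10; singular penalized Hessian at λ = 0 with collinear
  features raises an error advising λ > 0.
- Constant features: p = 1 in both selection tests (p = 0 when the
  group means differ with zero variance — certainty, not absence, of an
  effect); zero-SD features standardize with divisor 1.
- Empty selection (no feature passes α) falls back to the full matrix
  rather than an unfittable empty design.
- Determinism: every stochastic component takes a seed through
  `numpy.random.default_rng`; identical configuration yields
  byte-identical TSV output.

## Known limitations

- The Wald z construction under ridge is a documented interpretation;
  alternative standard-error constructions give different (typically
  larger) significance sets.
- Default pre-selection on the full labeled set inflates CV AUC
  slightly (by design, for fidelity); use fold-internal selection for
  unbiased estimates.
- The quantile-rank reading of the circuit's "normalization score"
  threshold is an interpretation; both readings are exposed.
- With heavy-tailed (log-normal) feature backgrounds the standardized
  effect of a planted driver fluctuates between seeds; a phase driver's
  Wald p in its one-vs-rest model occasionally lands between 0.01 and
  0.05 even at effect size 3, so driver-recovery rates in seed sweeps
  sit near, not at, 100%.
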