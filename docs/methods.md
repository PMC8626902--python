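# Methods

## Model

Each target gene's expression is modeled as a sparse linear function of
candidate regulators measured in the same samples:

EXPR_g = β₀ + Σᵢ cᵢ·vᵢ + ε,  ε ~ N(0, σ²)

where vᵢ are z-scored regulator values — expression of other genes and TFs,
or the gene's aggregated promoter methylation — and the response is z-scored
too, so coefficients are standardized and comparable across models.  The
model is deliberately linear and per-gene: its purpose is prioritization of
a few interpretable regulators, not maximal predictive accuracy.  The
intercept is estimated even on z-scored data (it is ≈0 but guards against
mean shifts introduced by mean-imputation of missing values) and is never
tested for significance; residual degrees of freedom are n − k − 1.

## Genomic feature construction

All coordinates are 0-based half-open; GTF (1-based closed) is converted on
read.  For a TSS on the + strand the promoter is [tss − 2000, tss + 1000)
and the methylation window [tss − 4000, tss + 1000); − strand windows are
mirrored, [tss − downstream + 1, tss + upstream + 1).  Starts are clamped at
zero.  A TF is a candidate regulator of a gene when any of its peaks shares
at least one base with any promoter of the gene — no minimum overlap
fraction, since binding evidence is point-source.  A gene's methylation
feature is the mean beta value over the *distinct* probes falling in the
union of its methylation windows (a probe in two overlapping windows is
counted once; pooling across TSS windows rather than averaging per-TSS).
TFs are matched to expression columns by exact symbol; unmatched TFs are
dropped with a warning, because TF activity is evaluated through the
expression of the encoding gene.

## Candidate matrices

Five nested matrices per target: M1 (own methylation + same-set genes), M2
(+ own TFs), M3 (+ same-set genes' TFs), M4 (+ other-set genes), M5
(+ other-set TFs), with set-union semantics — a feature keeps the provenance
of its first appearance, and the target's own expression is never a
predictor.  M4 is constructed for provenance but the analysis steps are
M2 → M3 → M5; the M5 step's new candidate group is columns(M5) \ columns(M3)
and therefore includes M4's additions.  Missing-data policy (applied to the
largest analyzed matrix before z-scoring): samples with a missing response
are dropped; features with more than 20% missing values are dropped;
remaining gaps are mean-imputed; zero-variance features are dropped.

## Selection procedure

One random fivefold partition (fold sizes ⌊n/5⌋ or ⌈n/5⌉, at least 10
samples) is drawn per run and reused for every gene, step and strategy, so
fold composition is never a source of between-model variation.  Within a
fold, greedy forward selection adds at each size the candidate whose OLS fit
on the training folds maximizes R² on the held-out fold; ties are broken by
lexicographic feature name; candidates making the training design singular
are skipped at that step.  The path is capped at max_k = min(30,
⌊n_train/10⌋) to keep OLS well-posed.  The fold's subset is the path prefix
with maximal held-out R² (the first maximum, favoring the smaller subset).
The step's consensus is the strict 5-of-5 intersection of fold subsets; an
empty consensus means "no model" at that step and nothing is carried
forward.  With re-evaluation (the default), the consensus is added to the
next step's candidate pool and competes again with the new group; the final
selected set is the last step's consensus.  Without re-evaluation, each
step's consensus is set aside unchallenged and the final set is their union.
The carried set is the full consensus, not only CI-significant features;
significance filtering happens after the final fit.  The lasso variants
replace the fold-wise greedy search with an L1-penalized fit whose penalty
is chosen on the held-out fold over a decreasing logarithmic grid
(10¹ … 10⁻³, 30 points; ties favor the sparser, larger penalty); the fold
subset is the nonzero-coefficient set.

Numerically, the greedy search solves each one-feature-augmented OLS through
cached Gram blocks with a Schur-complement update, vectorized over
candidates; candidates whose Schur complement falls below 10⁻¹⁰ of their
Gram diagonal are treated as collinear and skipped.  This path is verified
exactly (same selections, scores to 10⁻⁹) against an independent
refit-from-scratch greedy in the test suite.

## Inference and model scores

Final models are fitted by OLS on all samples with the consensus features.
Confidence intervals are t-based, c ± t₀.₉₇₅,ₙ₋ₖ₋₁·SE(c) with SE from the
unbiased residual variance (the t form was chosen over the normal
approximation; at the cohort sizes involved the difference is negligible but
t is exact under the model).  Adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1);
models with adjusted R² above 0.6 are flagged as good fits.  BIC uses the
Gaussian profile form n·ln(RSS/n) + p·ln(n) with p = k + 1 (intercept
counted); additive constants are dropped, so only BIC differences between
models on the same response are meaningful.  A zero-residual fit is reported
as BIC = −∞ with a warning.

## Networks and transfer

Significant features become directed edges feature → target weighted by the
coefficient; methylation nodes are namespaced `METH:<gene>` to avoid
collision with the gene's expression node.  Exports (SIF/GraphML/TSV) are
deterministic in node and edge order and round-trip losslessly.  Comparison
against an external ranked edge list reports, per target and pooled, the
fraction of model regulators present in the reference and the Spearman
correlation between |coefficient| and reference score on shared regulators
(undefined below two shared features); both per-target mean and pooled
overlap are reported because the aggregation convention is a genuine choice.
Transfer applies source coefficients and intercept unchanged to the target
cohort's within-cohort z-scored features; R² in the target cohort is
computed against the given predictions (no refit) and may be negative,
which is reported as computed.

## Synthetic cohorts

The generator emulates the shapes of a tumor-cohort analysis at desk scale:
genes on one chromosome with 50 kb spacing and random strand; five
methylation probes per target inside its methylation window, with betas
expit(logit(b₀) + m·1.0 + N(0, 0.3)) clipped to [0.01, 0.99] around a
per-sample latent signal m ~ N(0,1); TF peaks of 100 bp placed across the
TSS of bound genes, plus decoy TFs bound to each target and decoy peaks far
from any promoter; exogenous regulator expression ~ N(0,1).  Default study
conditions: 400 samples, two gene sets of 10 targets + 6 filler genes, and
three planted regulators per target — one visible at the M2 step (own
methylation for about half the targets, otherwise an own-TF or same-set
gene), one entering at M3 (a TF bound to another same-set gene but not the
target), one entering at M5 (an other-set gene).  Planted standardized
coefficient magnitudes are drawn in [0.3, 0.9] and rescaled so Σc² equals
the configured true R² (default 0.7) with unit-variance responses in
expectation; methylation coefficients are negative (repressive), other signs
random; noise sd is √(1 − R²).  Target expression is computed from the
*emitted* data (the z-scored aggregated probe betas, not the latent signal),
so the planted coefficients are exactly recoverable by the pipeline up to
sampling noise.  Regulators are exogenous — no feedback loops — so the
planted model is identifiable; real regulatory networks contain cycles,
shared upstream factors, confounding and non-linearity that the generator
deliberately omits, so passing recovery tests demonstrates correctness of
the machinery, not performance on real cohorts.  An all-noise configuration
(300 samples, ~30 candidates per target, no planted regulators) measures
selection specificity.

## Problem sizes and known behavior

The test suite runs recovery on ten default cohorts (recall ≈ 0.93,
precision ≈ 0.91, coefficient RMSE ≈ 0.026), twenty all-noise cohorts,
1000-fit calibration checks (null significance ≈ 5–7%, CI coverage ≈ 94%),
ten split-cohort transfer replicates (mean adjusted-R² gap ≈ 0.06) and the
five-strategy benchmark on one default cohort; the whole suite takes under
two minutes on one CPU.

Known limitations: with consensus selection over small candidate pools
(tens of features), the all-noise false-model rate is around 11% rather
than vanishing — the greedy criterion picks candidates *by* held-out R², so
fold subsets under pure noise still average ~4 features, fold training sets
share 75% of samples, and a spurious feature co-selected in all five folds
is then not rare.  Re-evaluation across incremental steps suppresses this
(the single-pool variant roughly doubles the rate), and larger candidate
pools reduce it further, but at the ~30-candidate scale specificity is
approximately, not strictly, below 10%.  The lasso variants select notably
more features than the forward variants, and forward selection on all
features at once selects the fewest — the same qualitative ordering the
incremental design is meant to exploit.
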