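# Methods

`isofunc` predicts, for every protein-coding isoform (or gene) and every
Gene Ontology term, the log-odds that the entity carries the function. Two
independent evidence streams are scored per term and then stacked.

## Model

### Coexpression evidence (correlation method)

Genes sharing a function tend to be coexpressed. For a query entity *q*
(gene or isoform) we compute the Spearman correlation of its expression
profile with every reference gene's profile — mid-rank transform per row,
then a Pearson matrix product, so the whole query-by-reference block is two
rank passes and one BLAS call. Rows with zero rank variance (constant
expression) get ρ = 0 and are logged rather than dropped, keeping matrix
shapes stable.

For each GO term *j*, the correlations of *q* with the genes annotated to
*j* are contrasted against the correlations with all non-annotated genes
using a two-sample Wilcoxon rank-sum (Mann–Whitney) z-score:

    z = (W − n₁(n+1)/2) / sqrt( n₁n₂/12 · [ (n+1) − Σ(t³−t)/(n(n−1)) ] )

with W the rank sum of the annotated group, n₁/n₂ the group sizes and t the
tie-group sizes. The sign convention is z > 0 ⇔ annotated genes correlate
stochastically higher. We use the normal approximation without continuity
correction by default (group sizes in practice are ≥10 vs thousands, deep
in the asymptotic regime; a continuity-correction switch exists). When the
query is itself a reference gene, it is removed from its row before
ranking; isoform queries remove their host gene. If a group drops below two
members after exclusion the score is recorded as missing (NaN) with a
warning, never silently zeroed; an all-tied row gives z = 0. The
computation is vectorized over the sparse annotation structure: each query
row is ranked once and all term rank-sums come from one sparse
matrix–vector product.

"Wilcoxon test" here is the two-sample rank-sum test; the one-sample
signed-rank variant does not apply to comparing two independent gene
groups.

### Domain evidence (domain-based regression)

Per GO term, a logistic regression predicts membership from binary Pfam
domain presence with an elastic-net penalty and all domain coefficients
constrained non-negative — a function should be implied by the presence of
domains, not their absence. The objective (glmnet scaling) is

    (1/n) Σᵢ [log(1+exp(ηᵢ)) − yᵢηᵢ] + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²),  β ≥ 0,

with unpenalized, unconstrained intercept. λ is selected over a descending
100-point log-spaced path from λ_max (the smallest λ at which every
coefficient is zero under the constraint: λ_max = maxⱼ (xⱼᵀ(y−ȳ))₊ / (nα))
down by a factor 10⁻⁴, by mean out-of-fold AUROC over 10 class-stratified
folds; ties resolve to the larger λ. The model is then refit on all
entities at the selected λ. Terms with fewer positives than folds reduce
the fold count (minimum 2) with a warning.

The solver (`isofunc._enet`) is an IRLS / cyclic coordinate-descent path
with warm starts, active-set inner cycles and a final full KKT sweep; on
the non-negative orthant the L1 term is linear, so each coordinate update
is a one-sided soft-threshold. Binary columns are walked through CSC index
arrays (only the rows where a domain is present), and the kernel is
numba-compiled. It agrees with an independent box-constrained quasi-Newton
solve of the same smooth objective, and with R glmnet under
`lower.limits = 0`, to ~1e-6 in the tests.

Choices the source description leaves open, fixed here: α = 0.5
(elastic-net proper, between ridge and lasso; configurable), binary
features not standardized (presence/absence already shares a scale, and
standardization would convert absence into penalized negative evidence),
no class weights (imbalance is an evaluation concern), CV folds stratified
by class from a stated seed.

### Stacking (combination method)

Per term, a logistic regression fuses the z-score and the domain logit on
the quadratic design (1, z, d, z·d, z², d²). Because small terms with a
diagnostic domain are often perfectly separable, the fit is
maximum-a-posteriori with independent Cauchy priors — scale 2.5 on each
standardized non-intercept coefficient and 4× that (10) on the intercept,
the standard weakly-informative recipe — which keeps all coefficients
finite under separation. Non-intercept design columns are standardized by
training moments before the prior applies; the stored moments make
original-scale prediction exact. As prior_scale → ∞ the fit converges to
the unpenalized MLE (checked against statsmodels).

The optimizer is a damped Newton iteration with backtracking line search
(penalized deviance is monotone non-increasing), a Levenberg ridge when the
Cauchy prior makes the Hessian indefinite, convergence at max |score| <
1e-8 or 100 iterations; non-convergence is flagged on the model, never
dropped. Rows with missing z are excluded from the fit and propagate as
missing predictions. The stacker is trained on training-set predictions of
the train-fit component models (the pipeline's flow); out-of-fold stacking
is not implemented.

### Isoform inference

Gene-trained models are applied to isoforms: Spearman correlations of each
isoform against all genes, the same Wilcoxon contrast (host gene excluded),
domain logits from the isoform's own domain annotation, and the stacker on
top. An isoform with expression and domains identical to its
single-isoform gene receives the gene's logits exactly.

Two readouts interpret the final matrix against the prevalence baseline,
the *expected logit* ln(n_annotated / n_not_annotated):

* **gain/loss calls** — Δ = logit − expected logit; an annotated term with
  Δ strictly below the lower threshold is *lost*, a non-annotated term with
  Δ strictly above the upper threshold is *gained* (defaults ∓3, i.e. about
  a 20-fold odds shift; both thresholds are user-set, and Δ exactly at a
  threshold is unchanged).
* **principal-isoform consistency** — for each term and each annotated gene
  with ≥2 isoforms, does a principal (APPRIS-style) isoform attain the
  maximum logit (ties count as top)? A term fulfils the hypothesis under a
  chosen aggregation over its genes: `any-gene`, `majority` (fraction
  ≥ 0.5, the default) or `all-genes`. The aggregation is exposed because
  the per-gene-to-per-term step is genuinely ambiguous in the field's
  reporting.

## Evaluation protocol

Genes are split uniformly at random into a training set and a held-out test
set (default 400 test genes at benchmark scale; reproducible from a seed).
All three stages are fit on training genes only, scored on test genes, and
only then refit on the complete gene set for isoform prediction — reported
performance is always held-out.

Per term we report AUROC (Mann–Whitney convention, ties half-credit) and
AUPRC (non-interpolated average-precision step curve, tied scores grouped;
its random baseline equals prevalence, the honest yardstick under GO-scale
imbalance). Summaries: medians over terms with defined metrics (terms with
no test positives are excluded and counted), the number of *perfect* terms
(AUROC and AUPRC both 1 within 1e-12), medians by term-size bin — [10,20]
closed, then (20,27], (27,40], (40,64], (64,114], (114,300] — per-ontology
(CC/MF/BP) medians when ontology labels exist, and restricted medians over
terms with 20 < n ≤ 300 for comparison with methods evaluated only on
mid-sized terms.

## Synthetic data generator

`simulate_dataset` draws datasets in which the method's assumptions hold by
construction, with closed-form expectations for checking:

* each term t has a latent sample factor f_t ~ N(0,1); a gene annotated to
  t has latent expression ρ·f_t + σ·ε (loading split across terms for
  multi-term genes), so two same-term genes have expected latent Pearson
  correlation ρ²/(ρ²+σ²) — the moment the tests verify (Spearman of the
  softplus-transformed values is rank-invariant, so it tracks this value
  closely);
* a fraction of terms own a dedicated informative domain, present in
  annotated genes with rate `domain_tpr` (0.9) and in background genes at
  `domain_fpr` (0.01); the remaining domains are functionless background;
* gene TPM is softplus(baseline + latent); isoform TPMs are the gene TPM
  times per-sample softmax usage weights, so gene aggregation inverts the
  generator exactly. The principal isoform keeps a stable high usage score
  (hence the gene's expression signal) with probability
  `principal_fidelity` (0.95) and all gene domains; alternative isoforms
  get volatile usage and drop each domain with `domain_loss_rate` (0.5);
* a truth table records which isoform retains each planted function signal.

Defaults are the standard benchmark: 2,000 genes × 300 samples, 60 terms of
15–40 genes (term modules drawn disjoint when they fit, preserving the
closed form), ρ = 0.5, σ = 1, 40% domain-informative terms, mean 4 isoforms
per gene (1 + Poisson(3), matching a mammalian transcriptome's
isoform-to-gene ratio), seed-deterministic throughout.

What the generator does **not** emulate: correlated GO terms (real
annotations form a DAG with heavy overlap), batch/cancer-type structure,
sequencing noise at the read level, expression-dependent annotation bias,
or isoforms sharing domains across genes. Passing tests therefore show the
machinery recovers planted structure under the model's own assumptions —
not that real-transcriptome performance will match; at these settings the
coexpression recovery problem is in fact easy (held-out AUROC saturates
near 1), which is why the shipped end-to-end checks assert ordering
patterns and calibration rather than matching particular values.

## Numerical choices

* CD solver: parameter tolerance 1e-7, IRLS weight floor 1e-5, ≤12 IRLS
  iterations per λ (warm starts make later path points 1–2 iterations).
* Coefficients below 1e-10 after fitting are truncated to exactly 0 for
  sparsity reporting.
* CV AUROC inside λ selection uses a vectorized rank formula over the whole
  path (identical to the half-credit convention).
* Degenerate inputs: all-zero domain matrix → intercept-only model equal to
  the training log-odds; CV AUROC undefined in every fold → most
  regularized model kept; constant expression rows → ρ = 0, logged.
* The worked-example micro dataset (18 genes, 4 terms, 24 isoforms) plants
  a tie (two identical expression rows), a 2-gene term (whose members lose
  their only peer to self-exclusion → per-row missing z), a singleton term
  (removed by any annotation filter), and an isoform that loses its gene's
  diagnostic domain. Golden outputs are committed and the pipeline
  reproduces them to 1e-9.

## Problem sizes used by the shipped checks

The standard benchmark run (acceptance script and the in-silico performance
test) is the default generator config with 400 held-out genes — about four
minutes end-to-end on one CPU. The null-calibration check repeats a
reduced version (200 genes × 50 samples, 10 terms of 10–15 genes, 10-point
λ path, 3 folds) over 20 seeds. Oracle-equivalence checks use hundreds of
instances of size ≤ 200.

## Known limitations

* No GO-hierarchy reconciliation: terms are predicted independently, so
  child terms can out-score their ancestors.
* One stacking route (training-set predictions); no out-of-fold stacking.
* The Wilcoxon z is carried forward as the evidence score without
  conversion to a p-value; comparisons across terms with very different
  group sizes inherit the statistic's size dependence.
* MAP point estimates only — no posterior uncertainty on the stacker.
* Sparse pair files cannot represent all-negative entities; readers
  zero-fill such rows when an entity universe is supplied (e.g. from the
  expression matrix), and isoforms missing from an input matrix are
  excluded from prediction with a warning.
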