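# Methods

## Model and estimation procedure

The package estimates trait-specific differential co-expression networks
under an additive interaction model for a continuous phenotype *Y* and
standardized expression levels *X₁ … Xₚ*:

    Yᵢ = Σⱼ Xᵢⱼ βⱼ + Σ_{k>j} Xᵢⱼ Xᵢₖ βⱼₖ + Σ_{k>j} αⱼₖ Δⱼₖ(Xᵢⱼ, Xᵢₖ) + εᵢ,
    εᵢ ~ N(0, σ²) i.i.d.

Product terms Xⱼ Xₖ βⱼₖ are *type I* interactions; arbitrary
activation/deactivation mappings Δⱼₖ that operate only in one phenotype tail
are *type II*. The estimation logic rests on a simple dependence argument:
conditioning on the upper or lower tail of *Y* induces, for a true product
pair, correlations of opposite sign and (asymptotically) equal magnitude in
the two tails, provided the pair's columns are zero-mean and independent
before truncation; for a one-sided activation pattern the dependency appears
in one tail only; and for pairs unrelated to *Y* the two tail dependencies
coincide. The sign operator Π turns these three patterns into edge labels.

Two assumptions of that argument fail in real data and drive the design:

* **Main effects** shift the tail means of their genes, breaking the
  zero-mean condition. Step 1 therefore fits the main-effect model (no
  interaction terms) with an elastic net and replaces *Y* by its residual
  before truncation ("residual adjustment").
* **Baseline collinearity** between two genes cannot be "broken" by
  truncation, so the opposite-sign pattern never materializes in plain
  correlations. The *truncated part-correlation* Φⱼₖ = cor_group(Xₖ, ε_{j|k})
  removes the full-sample linear relationship (ε_{j|k} is the residual of
  regressing Xⱼ on Xₖ over *all* samples) before computing within-group
  correlations, restoring the pattern.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `a` | 0.5 | truncation point; low group = values ≤ Q(a), high = values ≥ Q(1−a). 0.5 uses every sample (median split); smaller values sharpen tails but discard the middle |
| `r` | 0.1 | hard threshold below which a dependency entry counts as zero in Π; the one user-facing tuning knob. An alternative Bonferroni rule tests each entry at level α/n_tests |
| `mixing` | 1/3 | elastic-net L1 share for the residual step (glmnet convention λ[(1−α)/2‖β‖² + α‖β‖₁]) |
| `cv_folds` | 10 | folds for selecting λ (CV-minimum, not 1-SE) |
| `orientation` | `max_diff` | Φ is asymmetric (Xⱼ on Xₖ vs Xₖ on Xⱼ); per pair the orientation with the larger \|Φ^high − Φ^low\| is used in both group matrices, keeping the sign logic consistent. `average` averages orientations instead |
| `same_sign` | `zero` | Π for both-nonzero same-sign entries. Such a pattern indicates a phenotype-independent association, so no interaction evidence; `keep_positive` treats it as type I for sensitivity analysis |
| `max_edges_per_type` | 70 | display cap when sparsifying to an edge list |

Conventions: columns are z-scored (n−1 denominator) on the full sample
before anything else and group subsets are never re-standardized; empirical
quantiles use linear interpolation (R type 7); at `a = 0.5` samples are
rank-split with the median sample going to the low group (a choice — the
assignment of the middle sample is not dictated by the model); within-group
correlations re-center within the group.

## Implementation notes

Part-correlations are computed without materializing p² residual vectors:
with full-sample OLS slope b = cov(Xⱼ, Xₖ)/var(Xₖ), every within-group
moment of ε_{j|k} follows from the within-group covariance matrix, so both
orientations cost a few p × p matrix operations (p ≈ 2000 remains easy).
Degenerate entries (zero within-group residual variance) are set to 0 with a
logged warning. The elastic-net and lasso fits use coordinate descent with
fold assignment derived from the explicit seed, making the whole pipeline
deterministic for fixed inputs and seed.

The truncated AUC reported by the benchmark is the standardized
(McClish-transformed) partial area at FPR ≤ 0.2: chance maps to 0.5 and a
perfect ranking to 1.0, and at bound 1.0 it equals the ordinary AUC. The raw
mean-TPR partial area would cap at the bound itself and is not comparable
across bounds.

## Synthetic data

The generator emulates a reverse-phase protein-array cohort: n = 191
individuals × p = 231 proteins by default, standard-normal marginals,
optionally with block-factor correlation (X = √ρ F + √(1−ρ) E). Two
phenotype models provide ground truth:

* **Model A** (no main effects): six product interactions, two ReLU
  activation terms (product kept where it reaches its median, else 0),
  residual noise sd 1.75; six disrupted co-expression pairs are written
  backward into the matrix (upper-tail rows of *Y* get the second pair
  member overwritten as ±first + N(0, 0.25²), cut at the 4/5 quantile); two
  collinearity inductions (source + N(0, 0.25²), r ≈ 0.97) overlay product
  pairs *before* the phenotype is computed.
* **Model B**: Model A plus six main effects of size 2 and an additional
  independent noise term of the same sd.

Index layouts are configurable; `scaled_layout(p)` maps the canonical effect
counts onto small matrices (p ≥ 34) for fast benchmarks. The disruption cut
is configurable because the defining description is internally inconsistent
(4/5 in prose, 2/3 in the displayed condition); 4/5 is the default. Model
B's extra noise term is likewise a documented reading of an ambiguous "+ ε"
(flag `extra_noise`).

What the simulations do **not** emulate: heavy-tailed or skewed expression
marginals, measurement batch structure, realistic (estimated) inter-protein
covariance, and censoring correlated with expression. Passing benchmarks on
these simulations demonstrates the estimator's behavior under its stated
model, not performance on any particular real cohort.

## Benchmark protocol

Per replicate the phenotype (and the phenotype-dependent overwrites) are
re-simulated on a fixed backbone; every unordered pair is scored — by
|Q_sgn| for the network methods (zero wherever Π = 0), by |product-term
coefficient| for the exhaustive lasso reference — and ROC curves are
computed against the 14 planted pairs as positives and all remaining pairs
as negatives. Model A is analyzed on the raw phenotype (no residual step);
Model B with residual adjustment. Default desk scale is n = 1000, p = 60,
5 replicates (minutes on one CPU); the exhaustive lasso dominates the cost
(p(p−1)/2 product columns, guarded by a cap with an explicit override).

## Known limitations

* The sign rules classify, they do not test: with the hard threshold, an
  interaction pair whose part-correlation magnitude stays below r in both
  tails (e.g. a product pair contributing a small share of phenotypic
  variance, or one hidden behind an induced collinearity plus many competing
  terms) is zeroed by Π regardless of sample size — the labeled network is
  conservative by construction, and r trades recall against false labels.
* For a one-sided (disrupted) dependency, the full-sample regression slope
  is itself inflated by the disrupted rows; the part-correlation then shows
  an opposite-signed echo in the clean tail and the pair tends to be labeled
  type I at large n. The plain-correlation (dCCN) labels recover the
  one-sided pattern correctly; for type II classification specifically, the
  dCCN labels are the more faithful readout, while dPCCN remains the better
  *detector* (larger differential score).
* Censored observations must be dropped before network estimation; the
  induced bias is tolerated because the subsequent parametric validation
  (log-rank on the full cohort) filters false positives.
* Differential Gaussian graphical models are intentionally out of scope:
  the metric here is pairwise by design, not conditioned on all other genes.
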