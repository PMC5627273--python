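# Methods

## Model

Expression is analysed on the log2 scale. For gene *g* the observations in
condition–time cell *c* (condition ∈ {PBS, MPL, QS21, AS01}, time ∈
{2h, 4h, 6h} by default) are modelled as

    y_gcr = β_gc + ε_gcr,   ε_gcr ~ N(0, σ²_g),

a balanced one-way layout over the 12 cells. We use the cell-means
parameterisation rather than factorial effect coding: every quantity of
interest is a linear combination of cell means (the effect scores over PBS
θ_M, θ_Q, θ_A; the single-agent comparisons θ_A − θ_M, θ_A − θ_Q; the
additivity deviation D = θ_A − θ_M − θ_Q), and cell means avoid any
ambiguity about coding schemes. The residual variance s²_g pools squared
deviations from the cell means over all cells, with d_g = N − 12 degrees
of freedom (24 for the default 36-sample design). Every cell must contain
at least two replicates and the matrix must be complete — there is no
missing-data rule in this model, so missing values are an input error, not
something to impute. The fit is performed once on the full design and
reused for all contrasts and time points (a single residual variance per
gene); all contrasts of interest are within-time, so this subsumes both
per-time and joint fitting.

## Variance moderation

True gene variances are modelled as draws from a scaled inverse-χ² prior
with d₀ degrees of freedom and scale s₀². Writing
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) (ψ the digamma function), the model
implies E[e] = log s₀² − ψ(d₀/2) + log(d₀/2) and
Var[e] = ψ′(d₀/2) + ψ′(d_g/2), so the prior is estimated by moment
matching: ψ′(d₀/2) = var(e) − ψ′(d_g/2), solved by Newton inversion of the
trigamma function, then s₀² from the mean equation. When the observed
spread does not exceed the sampling component (var(e) ≤ ψ′(d_g/2)) the
prior is degenerate: d₀ = ∞ and every posterior variance equals
s₀² = exp(mean(e)). Genes with s²_g = 0 are excluded from prior estimation
(with a logged warning) but still receive a posterior variance. Moderated
statistics use

    s²_post,g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

and a Student-t reference with d₀ + d_g degrees of freedom (standard
normal when d₀ = ∞). One test cross-checks the whole chain — prior
estimates, moderated t and p — against Bioconductor limma on a shared
dataset; agreement is at the 1e-8 relative level.

## Elementary tests and DEG calling

A *difference* test of contrast w is the moderated t
est / (s_post · √(Σ_c w²_c/n_c)), two-sided. An *equivalence* test is two
one-sided tests (TOST) against the margin interval [−m, m]:

    p = max[ P(T ≤ (est − m)/SE), P(T ≥ (est + m)/SE) ],

declaring the effect confidently inside the interval when p < α. The
default margin is m = 1 log2 unit, chosen to match the fold-change-2
differential-expression threshold: an effect demonstrably inside (−1, 1)
is "null" on the same scale on which ≥ 1 is "present". A zero moderated
SE is handled as a degenerate limit (difference: p = 0 unless the estimate
is 0; equivalence: p = 0 iff |est| < m) with a logged flag.

DEGs are called per time point on the AS01 − PBS contrast with
|log2 FC| ≥ 1 and Benjamini–Hochberg adjusted p < 0.01, BH applied across
genes separately per contrast and time point (the field default for array
DEG calling; the threshold pair is configurable through `DEGCutoffs`).

## Interplay classification

Each AS01 DEG is assigned per time point by intersection-union tests: a
category is a conjunction of elementary statements, its IUT p-value is the
maximum of the component p-values, and the category fires only when that
maximum is below α = 0.05 *and* its sign conditions hold on the point
estimates. The ten default definitions (M, Q, A the effect scores over
PBS; D = A − M − Q; "≈" = TOST, "≠" = difference test):

| category             | conditions                                           |
|----------------------|------------------------------------------------------|
| irrelevance of MPL   | M ≈ 0, A ≈ Q                                         |
| irrelevance of QS-21 | Q ≈ 0, A ≈ M                                         |
| additivity           | M ≠ 0, Q ≠ 0, D ≈ 0                                  |
| synergy              | M ≠ 0, Q ≠ 0, D ≠ 0, sign(D) = sign(A)               |
| antagonism           | M ≠ 0, Q ≠ 0, D ≠ 0, sign(D) = −sign(M + Q)          |
| potentiation by MPL  | M ≈ 0, Q ≠ 0, A − Q ≠ 0, sign(A − Q) = sign(Q)       |
| potentiation by QS-21| Q ≈ 0, M ≠ 0, A − M ≠ 0, sign(A − M) = sign(M)       |
| inhibition by MPL    | M ≈ 0, Q ≠ 0, A − Q ≠ 0, sign(A − Q) = −sign(Q)      |
| inhibition by QS-21  | Q ≈ 0, M ≠ 0, A − M ≠ 0, sign(A − M) = −sign(M)      |
| emergence            | M ≈ 0, Q ≈ 0, A ≠ 0                                  |

Design choices that were genuinely open:

* **Three-state logic.** A contrast is "active" (difference test
  rejects), "null" (equivalence test rejects) or indeterminate. A
  category requiring a null does not fire on a merely non-significant
  contrast — that is exactly what the equivalence machinery buys — so
  indeterminate genes fall to `unclassified`.
* **Antagonism requires both single agents active.** With only one agent
  required, every inhibition-type input (one agent active, combination
  below it) also satisfies antagonism and the ten categories stop being
  pairwise distinguishable even without noise; requiring both restores a
  partition and matches the usual meaning of antagonism (joint response
  below the sum of two real effects). The definitions are a declarative
  table (`DEFAULT_CATEGORIES`), and a disjunctive statement kind
  (`any_difference`, contributing min of the member p-values) is
  implemented and tested, so the one-agent variant is a one-line edit.
* **Exclusive assignment.** When several categories pass, the smallest
  IUT p wins, ties broken by the fixed table order — deterministic and
  reproducible, and it makes the category distribution a partition of the
  DEG list.
* **No extra multiplicity correction** across the classification tests:
  α = 0.05 is applied per elementary test before the IUT, which is itself
  conservative (its p is a maximum).
* **Level control is about effect-asserting categories.** For a truly
  null gene the two irrelevance categories' statements are *true*
  (θ_M = 0 and θ_A − θ_Q = 0), so assigning them is a correct rejection;
  the type-I property tested is that null genes are assigned to
  categories claiming a nonzero effect at ≤ α (measured ≈ 0.01–0.015,
  well under the 0.05 budget, because such assignments need several
  simultaneous rejections).

Category summaries report fractions both over all DEGs (unclassified in
the denominator) and over classified DEGs, since published category
distributions do not always state which denominator they use.

## PCA and enrichment

PCA takes the log2 expression of the union of DEGs across time points,
with samples as observations and gene-wise centring (no scaling), via
SVD; component k explains σ²_k/Σσ² of the variance and the component
count is min(samples − 1, genes). Sign ambiguity is removed by flipping
each loading vector so its largest-magnitude entry is positive. An
alternative feature matrix — per-gene effect scores instead of expression
— is exposed as `pca_mode="effect_scores"` in the pipeline, since either
reading of "reducing the dimensionality of the DEG list" is defensible;
expression is the default.

Loading enrichment ranks genes by |loading| (enrichment is therefore
invariant to sign flips; whether signed or absolute loadings were used in
the original tooling is not documented, and absolute ranks pair naturally
with the AUC effect size) and applies a one-sided Mann–Whitney rank-sum
test of category vs rest, with rank-AUC as effect size (0.5 under
exchangeability) and BH across categories within a component.
Over-representation analysis is the upper-tail hypergeometric test of a
hit list against named gene sets (GMT format), each set intersected with
the universe first, BH across sets — a generic replacement for
proprietary process-network content.

## Synthetic data

The generator emulates the targeted study design: 4 conditions × 3 time
points × 3 replicates (36 arrays), baseline log2 expression
μ_g ~ N(8, 1), gene variances σ²_g ~ scaled-inv-χ²(d₀ = 4, s₀² = 0.05)
(a realistic array-scale noise prior under which moderated inference is
exactly calibrated), and per-category effect triples built from a base
effect δ = 3 log2 units and a deviation δ_extra = 1.5 (e.g. emergence
(0, 0, δ); additivity (δ/2, δ/2, δ); synergy (δ/2, δ/2, δ + δ_extra);
potentiation by QS-21 (δ, 0, δ + δ_extra)). By default 10% of genes are
planted per category. Planted effects are identical at every time point
(classification is within-time, so cross-time coupling is cosmetic); a
per-time multiplier can emulate a time-varying response. Antagonism is
planted with both single agents active, matching the classifier's
definition. All randomness flows from a single integer seed through one
numpy Generator, so datasets are bit-reproducible.

What the generator does **not** emulate: probe-level array artifacts,
batch effects, correlated genes, heavy-tailed or asymmetric noise, and
effects that change category across time. Passing benchmarks therefore
demonstrate correctness and calibration of the statistical machinery
under its own assumptions, not robustness to real-array pathology.

### Benchmark behaviour and a known power limit

At the defaults above (problem sizes chosen to keep the full benchmark
in seconds: G = 3000, five simulation replicates), per-category precision
is ≥ 0.94 and sensitivity 0.87–0.94 — except **additivity**, at ≈ 0.79.
This is a power ceiling, not a defect: additivity requires TOST on D,
whose SE (√(4σ²/3)) is the largest of all contrasts, and the heavy upper
tail of the inverse-χ²(4) variance prior leaves ~5% of genes whose
variance is too large ever to demonstrate |D| < 1 at α = 0.05, with
estimate noise costing the rest. A direct Monte-Carlo evaluation of the
additivity IUT under the generating model gives P(reject) ≈ 0.794, which
the pipeline attains. Raising n_rep, the margin, or δ/σ would lift it;
under the stated conditions ~0.79 is the attainable value.

## Numerical notes

* Trigamma inversion uses Newton iteration from the asymptotic starting
  value 0.5 + 1/x; convergence tolerance 1e-10 (relative).
* All per-gene tests are vectorised across genes; classification of a
  3000-gene × 36-sample dataset takes well under a second.
* Result tables are serialised at 6 significant digits with fixed column
  order, so identical configurations produce byte-identical files; the
  pipeline manifest echoes every parameter plus the seed and package
  version, making a run reproducible from the manifest alone.
* Degenerate inputs fail loudly and early: duplicate ids, non-numeric or
  missing cells, singleton cells, unknown condition labels, all-zero
  variances, constant PCA input.

## Limitations

* Two immunostimulants only; the category table is written for the
  2-component factorial and does not generalise to dose–response
  surfaces or 3-component systems.
* No robust or intensity-trend variants of variance moderation, and no
  spline/time-course modelling; time points are analysed marginally.
* Probe→gene collapsing is not performed — rows are analysed as given,
  since any mapping is annotation-dependent.
* The GEO series-matrix reader parses only the data block; sample
  characteristics are not auto-parsed into a design table (field
  conventions vary too much), so the user supplies the design.
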