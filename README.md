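# adjinterplay

Factorial differential expression and immunostimulant-interplay
classification for combination-adjuvant transcriptomics.

## The problem

Liposomal Adjuvant System AS01 combines two immunostimulants — MPL (a TLR4
agonist) and QS-21 (a *Quillaja saponaria* saponin fraction). When the
draining lymph node of injected mice is profiled by expression array under
four conditions (PBS sham, MPL alone, QS-21 alone, AS01) at several early
time points, the interesting question is not just *which* genes respond to
the combination, but *how* the two components jointly shape each gene's
response: is a gene driven by one component alone, by their sum, by more
than their sum, or only by the combination?

`adjinterplay` implements that analysis as a tested, reusable pipeline:

1. **Per-gene linear models.** Each gene's log2 expression is fit as a
   cell-means model over the condition × time cells; the residual variance
   s²_g (d_g degrees of freedom) is pooled within cells.
2. **Empirical-Bayes moderation.** Gene variances are assumed drawn from a
   scaled inverse-χ² prior (d₀, s₀²), estimated by moment matching on
   log s²_g; tests use the posterior variance
   s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with d₀ + d_g degrees of
   freedom.
3. **DEG calling.** A gene is differentially expressed at a time point
   when its AS01 − PBS contrast satisfies |log2 FC| ≥ 1 (fold change > 2)
   and Benjamini–Hochberg adjusted p < 0.01.
4. **Interplay classification.** With effect scores over PBS
   θ_M, θ_Q, θ_A and the additivity deviation D = θ_A − θ_M − θ_Q, each
   DEG is assigned by an intersection-union test (IUT) — whose p-value is
   the maximum of its component p-values — over moderated difference tests
   ("θ ≠ 0") and TOST equivalence tests within [−1, 1] log2 ("θ ≈ 0"), at
   α = 0.05, to one of ten categories: irrelevance of MPL / of QS-21,
   additivity, synergy, antagonism, potentiation / inhibition by either
   component, and emergence (response only to the combination).
5. **PCA + enrichment.** The DEG-union submatrix is decomposed by PCA
   (samples as observations); interplay categories are tested for
   enrichment among each component's largest-magnitude loadings
   (one-sided rank-sum, rank-AUC effect size). A generic hypergeometric
   over-representation step against user-supplied GMT gene sets replaces
   proprietary pathway content.

A synthetic-data generator plants all ten categories at known effect
sizes, so every stage is benchmarked end to end with no download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_fit_degs.py
python analysis/03_classify_interplay.py
python analysis/04_pca_enrichment.py
python analysis/05_recovery_benchmark.py
```

which prints (seed 1):

```
simulated 3000 genes x 36 samples (3000 planted, seed 1)
variance prior: d0 = 3.87, s0^2 = 0.0506 (residual df 24)
2h: 2946/3000 DEGs (|log2FC| >= 1, adj p < 0.01)
...
PCA on 2992 DEGs x 36 samples: PC1 60.4%, PC2 30.6% (PC1+PC2 90.9%)
PC1: most enriched category = synergy (AUC 0.87, adj p 3.2e-109)
            category  sensitivity  precision
           emergence        0.897      1.000
          additivity        0.790      0.985
             synergy        0.936      0.952
          antagonism        0.927      0.949
...
```

The recovered prior (d₀ ≈ 3.9, s₀² ≈ 0.051) matches the generating values
(4, 0.05); ~98% of planted genes pass the DEG filter; per-category
sensitivity is 0.79–0.94 with precision ≥ 0.95 at the planted effect
sizes (base effect 3 log2 units, deviation 1.5, 3 replicates/cell).

The same pipeline runs on real data from the command line:

```bash
adjinterplay run-all --expression expr.tsv --design design.tsv
adjinterplay run-all --simulate --seed 7 --outdir results/demo
```

Expression input is a genes × samples TSV of log2 intensities (a GEO
series-matrix file is also accepted via `--dialect geo_series_matrix`);
the design TSV maps each sample to condition ∈ {PBS, MPL, QS21, AS01},
time and replicate.

## Layout

- `src/adjinterplay/` — the library: `expr_io` (matrix/design IO),
  `linear_model` (cell-means fit, moderation, contrasts, DEGs),
  `interplay` (TOST, IUT, declarative category table), `pca_enrichment`
  (PCA, loading enrichment, ORA), `synthetic_data` (generator + recovery
  scoring), `pipeline` / `cli` (orchestration).
- `analysis/` — the numbered study drivers above.
- `docs/methods.md` — model details, defaults and limitations.
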