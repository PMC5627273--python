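#!/usr/bin/env python
"""PCA of the DEG-union expression submatrix and interplay-category
enrichment on the leading component loadings.

Reduces the DEG list to principal components (samples as observations,
gene-wise centring), reports the variance explained by PC1/PC2, and tests
which interplay categories concentrate among each component's
largest-magnitude loadings (one-sided rank-sum, rank-AUC effect size, BH
across categories).
"""

import argparse
from pathlib import Path

import pandas as pd

from adjinterplay import (
    align,
    enrich_loadings,
    read_design,
    read_expression,
    run_pca,
    write_table,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path,
                    default=Path("results/analysis/data"))
parser.add_argument("--interplay", type=Path,
                    default=Path("results/analysis/interplay"))
parser.add_argument("--degs", type=Path,
                    default=Path("results/analysis/degs"))
parser.add_argument("--outdir", type=Path,
                    default=Path("results/analysis/pca"))
args = parser.parse_args()

expr = read_expression(args.data / "expression.tsv")
design = read_design(args.data / "design.tsv")
expr, design = align(expr, design)

deg_union: set[str] = set()
calls_frames = []
for path in sorted(args.degs.glob("degs_*.tsv")):
    degs = pd.read_csv(path, sep="\t")
    deg_union |= set(degs.loc[degs["is_deg"], "gene"])
for path in sorted(args.interplay.glob("interplay_calls_*.tsv")):
    calls_frames.append(pd.read_csv(path, sep="\t"))
calls = pd.concat(calls_frames, ignore_index=True)

pca = run_pca(expr.data.loc[sorted(deg_union)])
write_table(pca.scores.reset_index(names="sample"),
            args.outdir / "pca_scores.tsv")
write_table(pca.loadings.reset_index(names="gene"),
            args.outdir / "pca_loadings.tsv")
write_table(pca.var_explained.rename_axis("component").reset_index(),
            args.outdir / "pca_var_explained.tsv")
ve = pca.var_explained
print(f"PCA on {len(deg_union)} DEGs x {pca.scores.shape[0]} samples: "
      f"PC1 {ve.iloc[0]:.1%}, PC2 {ve.iloc[1]:.1%} "
      f"(PC1+PC2 {ve.iloc[:2].sum():.1%})")

categories = {
    name: set(sub["gene"]) & set(pca.loadings.index)
    for name, sub in calls.groupby("category")
    if name != "unclassified"
}
categories = {k: v for k, v in categories.items() if v}
frames = [enrich_loadings(pca, comp, categories) for comp in ("PC1", "PC2")]
enrichment = pd.concat(frames, ignore_index=True)
write_table(enrichment, args.outdir / "loading_enrichment.tsv")
for comp in ("PC1", "PC2"):
    sub = enrichment[enrichment["component"] == comp]
    best = sub.sort_values("p").iloc[0]
    print(f"{comp}: most enriched category = {best['set']} "
          f"(AUC {best['auc']:.2f}, adj p {best['adj_p']:.2g})")
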