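"""PCA of the DEG submatrix and enrichment on component loadings.

Samples are the observations and DEG genes the variables; the matrix is
gene-wise centred (no scaling) and decomposed by SVD, so component k
explains sigma_k^2 / sum sigma^2 of the variance.  Loadings carry a
deterministic sign convention (largest-magnitude entry positive) to remove
the SVD sign ambiguity.

Two enrichment flavours are provided:

* :func:`enrich_loadings` — rank-based enrichment of a gene category among
  the largest-magnitude loadings of a component (one-sided rank-sum test
  with a rank-AUC effect size);
* :func:`ora_hypergeometric` — generic over-representation analysis of a
  hit list against named gene sets (GMT format), the package's stand-in
  for proprietary process-network content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import ExpressionMatrix
from .linear_model import adjust_bh


@dataclass
class PCAResult:
    """Scores (samples x k), loadings (genes x k, orthonormal columns) and
    the fraction of variance explained per component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained: pd.Series

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def run_pca(expr: ExpressionMatrix | pd.DataFrame) -> PCAResult:
    """PCA with samples as observations and genes as variables.

    The input is a genes x samples matrix (the usual expression layout);
    it is transposed internally, gene-wise centred, and decomposed with an
    economy SVD.  The number of components is min(samples - 1, genes).
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    X = data.to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("constant matrix: no variance to decompose")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # sign convention: the largest-|.| entry of each loading vector is positive
    for k in range(n_comp):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    names = [f"PC{k + 1}" for k in range(n_comp)]
    ev = s ** 2
    return PCAResult(
        scores=pd.DataFrame(U * s, index=data.columns, columns=names),
        loadings=pd.DataFrame(Vt.T, index=data.index, columns=names),
        var_explained=pd.Series(ev / ev.sum(), index=names,
                                name="var_explained"),
    )


def enrich_loadings(
    pca: PCAResult,
    component: str,
    categories: dict[str, set[str] | list[str]],
) -> pd.DataFrame:
    """Rank-based enrichment of gene categories in a component's loadings.

    Genes are ranked by decreasing |loading|; each category is compared to
    the remaining genes with a one-sided Mann-Whitney rank-sum test
    (enrichment toward the top).  The effect size is the rank AUC, i.e.
    the probability that a random category gene out-ranks a random
    non-category gene (0.5 under exchangeability).  BH adjustment is
    applied across categories within the component.
    """
    if component not in pca.loadings.columns:
        raise KeyError(f"component {component!r} not in PCA result")
    magnitude = pca.loadings[component].abs()
    universe = set(magnitude.index)
    rows = []
    for name, genes in categories.items():
        genes = set(genes)
        stray = genes - universe
        if stray:
            raise ValueError(
                f"category {name!r} has genes absent from the loadings: "
                f"{sorted(stray)[:5]}"
            )
        if not genes or len(genes) == len(universe):
            rows.append({"set": name, "component": component,
                         "n": len(genes), "auc": np.nan, "p": np.nan})
            continue
        inside = magnitude.loc[list(genes)].to_numpy()
        outside = magnitude.drop(list(genes)).to_numpy()
        res = stats.mannwhitneyu(inside, outside, alternative="greater")
        auc = res.statistic / (len(inside) * len(outside))
        rows.append({"set": name, "component": component,
                     "n": len(genes), "auc": float(auc),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(rows, columns=["set", "component", "n", "auc", "p"])
    valid = out["p"].notna()
    out["adj_p"] = np.nan
    if valid.any():
        out.loc[valid, "adj_p"] = adjust_bh(out.loc[valid, "p"])
    return out


def ora_hypergeometric(
    hits: set[str] | list[str],
    universe: set[str] | list[str],
    gene_sets: dict[str, set[str] | list[str]],
) -> pd.DataFrame:
    """Over-representation analysis via the hypergeometric upper tail.

    For each named set S (intersected with the universe first), the
    p-value is P(X >= |hits & S|) for X hypergeometric with population
    |universe|, |S| successes and |hits| draws.  BH adjustment is applied
    across sets; the result is sorted by ascending p.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n_draw = len(universe), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        overlap = len(hits & in_universe)
        K = len(in_universe)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n_draw)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": overlap,
                     "hits": n_draw, "universe": N, "p": p})
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "hits", "universe", "p"]
    )
    if len(out):
        out["adj_p"] = adjust_bh(out["p"])
        out = out.sort_values(["p", "set"], kind="stable").reset_index(
            drop=True
        )
    else:
        out["adj_p"] = pd.Series(dtype=float)
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets from a GMT file (set, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
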