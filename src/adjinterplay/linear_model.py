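"""Per-gene cell-means linear models with empirical-Bayes moderation.

The factorial experiment is modelled per gene as a balanced one-way layout
over the condition x time cells: the fitted coefficients are the cell means
and the residual variance s_g^2 is the within-cell variance pooled over all
cells, with d_g = N_samples - N_cells degrees of freedom.  A cell-means
parameterisation is used rather than factorial effect coding: every
contrast of interest (effect scores over PBS, deviations from additivity)
is a linear combination of cell means, and cell means avoid any
coding-scheme ambiguity.

Variance moderation follows the classical hierarchical model in which the
true gene variances sigma_g^2 are drawn from a scaled inverse-chi-square
prior with d0 degrees of freedom and scale s0^2.  The prior is estimated by
moment matching on e_g = log s_g^2 - psi(d_g/2) + log(d_g/2), whose mean
and variance have closed forms under the model (psi is the digamma
function); the posterior variance

    s_post,g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in every test statistic, and the reference distribution
gains the prior degrees of freedom (Student t with d0 + d_g df; standard
normal when d0 is infinite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expr_io import DesignTable, ExpressionMatrix

logger = logging.getLogger(__name__)

Cell = tuple[str, str]  # (condition, time)


@dataclass
class ModelFit:
    """Per-gene cell means plus pooled residual variance.

    Attributes
    ----------
    coef
        genes x cells DataFrame of cell means (log2 units); columns are a
        MultiIndex of (condition, time).
    sigma2
        Residual variance per gene (log2^2 units).
    df_resid
        Residual degrees of freedom, identical for all genes in a complete
        design: N_samples - N_cells.
    cell_sizes
        Replicate count per cell.
    """

    coef: pd.DataFrame
    sigma2: pd.Series
    df_resid: int
    cell_sizes: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coef.index)

    @property
    def cells(self) -> list[Cell]:
        return list(self.coef.columns)

    def times(self) -> list[str]:
        return list(dict.fromkeys(t for _, t in self.coef.columns))


@dataclass
class EBPrior:
    """Scaled inverse-chi-square variance prior (d0, s0^2).

    ``d0 = inf`` means the gene variances are exchangeable with no excess
    spread: every posterior variance equals s0^2.
    """

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s02 > 0):
            raise ValueError("s02 must be positive")

    def posterior_var(self, fit: ModelFit) -> pd.Series:
        """Shrunken variance per gene, a convex blend of s_g^2 and s0^2."""
        if math.isinf(self.d0):
            return pd.Series(self.s02, index=fit.sigma2.index)
        d = fit.df_resid
        return (self.d0 * self.s02 + d * fit.sigma2) / (self.d0 + d)

    def total_df(self, fit: ModelFit) -> float:
        return self.d0 + fit.df_resid


@dataclass
class ContrastSpec:
    """A named linear combination of condition x time cell means."""

    name: str
    weights: dict[Cell, float]
    allow_nonzero_sum: bool = False

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError(f"contrast {self.name!r} has no nonzero weight")
        total = sum(self.weights.values())
        if abs(total) > 1e-12 and not self.allow_nonzero_sum:
            raise ValueError(
                f"contrast {self.name!r} weights sum to {total}, not zero; "
                "set allow_nonzero_sum=True if intended"
            )


@dataclass
class DEGCutoffs:
    """Differential-expression cutoffs: |log2 FC| >= 1 (fold change > 2)
    and BH-adjusted p < 0.01 by default."""

    min_abs_log2fc: float = 1.0
    max_adj_p: float = 0.01

    def __post_init__(self) -> None:
        if not self.min_abs_log2fc > 0:
            raise ValueError("min_abs_log2fc must be positive")
        if not 0 < self.max_adj_p < 1:
            raise ValueError("max_adj_p must be in (0, 1)")


def fit_cell_means(expr: ExpressionMatrix, design: DesignTable) -> ModelFit:
    """Fit the per-gene cell-means model.

    Cell means are arithmetic means of replicate values; the residual
    variance pools squared deviations from the cell mean across all cells.
    Requires aligned inputs and >= 2 replicates in every cell.
    """
    if expr.sample_ids != design.sample_ids:
        raise ValueError(
            "expression and design are not aligned; call align() first"
        )
    sizes = design.cells()
    singletons = sizes[sizes < 2]
    if len(singletons):
        cell = singletons.index[0]
        raise ValueError(
            f"cell (condition={cell[0]!r}, time={cell[1]!r}) has "
            f"{singletons.iloc[0]} replicate(s); >=2 required"
        )
    values = expr.values
    n_samples = values.shape[1]
    means = {}
    rss = np.zeros(values.shape[0])
    for (cond, time), _ in sizes.items():
        cols = [
            expr.sample_ids.index(s)
            for s in design.samples_in_cell(cond, time)
        ]
        sub = values[:, cols]
        m = sub.mean(axis=1)
        means[(cond, time)] = m
        rss += ((sub - m[:, None]) ** 2).sum(axis=1)
    df_resid = n_samples - len(sizes)
    coef = pd.DataFrame(means, index=expr.gene_ids)
    coef.columns = pd.MultiIndex.from_tuples(
        coef.columns, names=["condition", "time"]
    )
    sigma2 = pd.Series(rss / df_resid, index=expr.gene_ids, name="sigma2")
    return ModelFit(coef=coef, sigma2=sigma2, df_resid=df_resid,
                    cell_sizes=sizes)


def _trigamma_inverse(x: float, tol: float = 1e-10) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration.

    psi' is strictly decreasing with psi'(y) ~ 1/y + 1/(2y^2) for large y
    and ~ 1/y^2 near zero, which gives the starting value.
    """
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_eb_prior(fit: ModelFit) -> EBPrior:
    """Estimate (d0, s0^2) by moment matching on log residual variances.

    With e_g = log s_g^2 - psi(d_g/2) + log(d_g/2), the hierarchical model
    implies var(e) = psi'(d0/2) + psi'(d_g/2) and
    mean(e) = log s0^2 - psi(d0/2) + log(d0/2).  d0 is recovered by
    inverting the trigamma function; when the observed spread does not
    exceed the sampling component psi'(d_g/2), the prior is degenerate
    (d0 = inf) and s0^2 = exp(mean(e)).
    """
    s2 = fit.sigma2.to_numpy()
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise ValueError(
            "all residual variances are zero: degenerate data, "
            "cannot estimate a variance prior"
        )
    if len(positive) < 2:
        raise ValueError("need >=2 genes with positive residual variance")
    if len(positive) < len(s2):
        logger.warning(
            "estimate_eb_prior: excluding %d zero-variance gene(s)",
            len(s2) - len(positive),
        )
    d = fit.df_resid
    e = np.log(positive) - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        return EBPrior(d0=math.inf, s02=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(
        np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return EBPrior(d0=d0, s02=s02)


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def _contrast_moments(
    fit: ModelFit, contrast: ContrastSpec
) -> tuple[np.ndarray, float]:
    """Estimate per gene and the unscaled SE factor sqrt(sum w_c^2 / n_c)."""
    missing = [c for c in contrast.weights if c not in set(fit.cells)]
    if missing:
        raise ValueError(
            f"contrast {contrast.name!r} references cells absent from the "
            f"fit: {missing}"
        )
    est = np.zeros(len(fit.coef))
    unscaled = 0.0
    for cell, w in contrast.weights.items():
        if w == 0:
            continue
        est = est + w * fit.coef[cell].to_numpy()
        unscaled += w ** 2 / fit.cell_sizes[cell]
    return est, math.sqrt(unscaled)


def _t_sf(t: np.ndarray, df: float) -> np.ndarray:
    """Upper-tail probability with normal reference at infinite df."""
    if math.isinf(df):
        return stats.norm.sf(t)
    return stats.t.sf(t, df)


def test_contrast(
    fit: ModelFit, prior: EBPrior, contrast: ContrastSpec
) -> pd.DataFrame:
    """Moderated t-test of a contrast across all genes.

    Returns a DataFrame indexed by gene with columns ``estimate``, ``se``,
    ``t``, ``df_total``, ``p`` (two-sided) and ``adj_p`` (BH across genes
    within this contrast).
    """
    est, unscaled = _contrast_moments(fit, contrast)
    s_post = prior.posterior_var(fit).to_numpy()
    se = np.sqrt(s_post) * unscaled
    df_total = prior.total_df(fit)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * _t_sf(np.abs(t), df_total)
    degenerate = se == 0
    if degenerate.any():
        logger.warning(
            "test_contrast(%s): %d gene(s) with zero moderated variance",
            contrast.name, int(degenerate.sum()),
        )
        t = np.where(degenerate, np.sign(est) * np.inf, t)
        t = np.where(degenerate & (est == 0), 0.0, t)
        p = np.where(degenerate, np.where(est != 0, 0.0, 1.0), p)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "t": t,
            "df_total": df_total,
            "p": p,
            "adj_p": adjust_bh(p),
        },
        index=fit.coef.index,
    )


def effect_contrast(name: str, time: str) -> ContrastSpec:
    """Named interplay contrast at one time point.

    ``M``, ``Q``, ``A`` are the effect scores of MPL, QS-21 and AS01 over
    PBS; ``A_minus_M`` and ``A_minus_Q`` compare the combination to a
    single agent; ``D = A - M - Q`` is the deviation from additivity.
    """
    t = time
    recipes: dict[str, dict[Cell, float]] = {
        "M": {("MPL", t): 1.0, ("PBS", t): -1.0},
        "Q": {("QS21", t): 1.0, ("PBS", t): -1.0},
        "A": {("AS01", t): 1.0, ("PBS", t): -1.0},
        "A_minus_M": {("AS01", t): 1.0, ("MPL", t): -1.0},
        "A_minus_Q": {("AS01", t): 1.0, ("QS21", t): -1.0},
        "D": {("AS01", t): 1.0, ("MPL", t): -1.0, ("QS21", t): -1.0,
              ("PBS", t): 1.0},
    }
    if name not in recipes:
        raise KeyError(
            f"unknown contrast {name!r}; expected one of {sorted(recipes)}"
        )
    return ContrastSpec(name=f"{name}@{t}", weights=recipes[name])


def call_degs(
    fit: ModelFit,
    prior: EBPrior,
    time: str,
    cutoffs: DEGCutoffs | None = None,
) -> pd.DataFrame:
    """Call AS01-vs-PBS differentially expressed genes at one time point.

    A gene is a DEG iff |log2 fold change| >= ``min_abs_log2fc`` and the
    BH-adjusted contrast p-value is below ``max_adj_p``.
    """
    cutoffs = cutoffs or DEGCutoffs()
    res = test_contrast(fit, prior, effect_contrast("A", time))
    table = pd.DataFrame(
        {
            "gene": res.index,
            "time": time,
            "log2fc": res["estimate"].to_numpy(),
            "t": res["t"].to_numpy(),
            "p": res["p"].to_numpy(),
            "adj_p": res["adj_p"].to_numpy(),
        }
    )
    table["is_deg"] = (
        (table["log2fc"].abs() >= cutoffs.min_abs_log2fc)
        & (table["adj_p"] < cutoffs.max_adj_p)
    )
    logger.info(
        "call_degs(%s): %d/%d genes pass |log2fc|>=%g, adj_p<%g",
        time, int(table["is_deg"].sum()), len(table),
        cutoffs.min_abs_log2fc, cutoffs.max_adj_p,
    )
    return table
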