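"""Synthetic factorial expression data with planted interplay structure.

The generator emulates the study design the classifier targets: four
conditions (PBS, MPL, QS21, AS01) x three time points x 3 replicates of
log2-scale expression, with gene-wise variances drawn from a scaled
inverse-chi-square prior (the same hierarchical model the moderation
machinery assumes).  Each planted gene carries effect scores over PBS that
satisfy its category's noise-free definition exactly, so recovery of the
planted labels measures the whole pipeline end to end.

Planted effect triples (theta_M, theta_Q, theta_A), in terms of the base
effect delta and the deviation effect delta_extra:

======================  =========================================
emergence               (0, 0, delta)
additivity              (delta/2, delta/2, delta)
synergy                 (delta/2, delta/2, delta + delta_extra)
antagonism              (delta/2, delta/2, delta - delta_extra)
potentiation_by_QS21    (delta, 0, delta + delta_extra)
inhibition_by_QS21      (delta, 0, delta - delta_extra)
potentiation_by_MPL     (0, delta, delta + delta_extra)
inhibition_by_MPL       (0, delta, delta - delta_extra)
irrelevance_of_MPL      (0, delta, delta)
irrelevance_of_QS21     (delta, 0, delta)
======================  =========================================

Antagonism is planted with both single agents active even though the
classifier only requires one; null genes have all thetas zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_io import CONDITIONS, DesignTable, ExpressionMatrix

NULL_CATEGORY = "null"

#: (theta_M, theta_Q, theta_A) in units of (delta, delta_extra): each entry
#: is a pair (coefficient of delta, coefficient of delta_extra).
CATEGORY_EFFECTS: dict[str, tuple[tuple[float, float], ...]] = {
    "emergence": ((0, 0), (0, 0), (1, 0)),
    "additivity": ((0.5, 0), (0.5, 0), (1, 0)),
    "synergy": ((0.5, 0), (0.5, 0), (1, 1)),
    "antagonism": ((0.5, 0), (0.5, 0), (1, -1)),
    "potentiation_by_QS21": ((1, 0), (0, 0), (1, 1)),
    "inhibition_by_QS21": ((1, 0), (0, 0), (1, -1)),
    "potentiation_by_MPL": ((0, 0), (1, 0), (1, 1)),
    "inhibition_by_MPL": ((0, 0), (1, 0), (1, -1)),
    "irrelevance_of_MPL": ((0, 0), (1, 0), (1, 0)),
    "irrelevance_of_QS21": ((1, 0), (0, 0), (1, 0)),
}

DEFAULT_PROPORTIONS: dict[str, float] = {
    name: 0.1 for name in CATEGORY_EFFECTS
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic factorial experiment.

    Defaults mirror the targeted design: 3 replicates per adjuvant per
    time point, times 2h/4h/6h, log2 array scale with baseline mean 8 and
    sd 1, variance prior d0 = 4 and s0^2 = 0.05, base effect delta = 3
    log2 units with deviation effect 1.5, and 10% of genes planted per
    category.
    """

    n_genes: int = 3000
    proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    delta: float = 3.0
    delta_extra: float = 1.5
    n_rep: int = 3
    times: Sequence[str] = ("2h", "4h", "6h")
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    d0: float = 4.0
    s02: float = 0.05
    time_multipliers: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(CATEGORY_EFFECTS)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if total > 1 + 1e-12:
            raise ValueError(
                f"category proportions sum to {total:.3f} > 1"
            )
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2 (variance estimable)")


@dataclass
class TruthTable:
    """Planted ground truth: one row per gene per time with the planted
    category, effect scores and the true gene variance."""

    data: pd.DataFrame  # gene, category, sigma2, time, theta_M/Q/A

    def category_of(self) -> pd.Series:
        """Planted category per gene (identical across times)."""
        return (
            self.data.drop_duplicates("gene")
            .set_index("gene")["category"]
        )

    def genes_in(self, category: str) -> list[str]:
        return list(
            self.data.loc[self.data["category"] == category, "gene"].unique()
        )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, DesignTable, TruthTable]:
    """Simulate a factorial log2 expression dataset with planted truth.

    Per gene g: baseline mu_g ~ Normal(mu0, sd0^2); variance
    sigma_g^2 = d0 * s0^2 / chi2(d0) (scaled inverse-chi-square); cell
    means PBS = mu_g, MPL = mu_g + theta_M, QS21 = mu_g + theta_Q,
    AS01 = mu_g + theta_A; replicate values add Normal(0, sigma_g^2)
    noise.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = [f"g{i + 1:05d}" for i in range(G)]

    categories = np.full(G, NULL_CATEGORY, dtype=object)
    start = 0
    for name in CATEGORY_EFFECTS:  # fixed insertion order
        frac = config.proportions.get(name, 0.0)
        count = int(np.floor(frac * G))
        categories[start:start + count] = name
        start += count

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    sigma2 = config.d0 * config.s02 / rng.chisquare(config.d0, size=G)

    theta = np.zeros((G, 3))  # columns M, Q, A
    for name, coeffs in CATEGORY_EFFECTS.items():
        mask = categories == name
        for j, (cd, cx) in enumerate(coeffs):
            theta[mask, j] = cd * config.delta + cx * config.delta_extra

    multipliers = {
        t: (config.time_multipliers or {}).get(t, 1.0) for t in config.times
    }

    design_rows = []
    columns: dict[str, np.ndarray] = {}
    truth_rows = []
    cond_offset = {"PBS": None, "MPL": 0, "QS21": 1, "AS01": 2}
    for time in config.times:
        m = multipliers[time]
        for cond in CONDITIONS:
            offset = (
                np.zeros(G) if cond_offset[cond] is None
                else m * theta[:, cond_offset[cond]]
            )
            cell_mean = mu + offset
            for rep in range(1, config.n_rep + 1):
                sample = f"{cond}_{time}_r{rep}"
                noise = rng.normal(0.0, np.sqrt(sigma2))
                columns[sample] = cell_mean + noise
                design_rows.append(
                    {"sample_id": sample, "condition": cond,
                     "time": time, "replicate": rep}
                )
        for g in range(G):
            truth_rows.append(
                {
                    "gene": genes[g],
                    "category": categories[g],
                    "sigma2": sigma2[g],
                    "time": time,
                    "theta_M": m * theta[g, 0],
                    "theta_Q": m * theta[g, 1],
                    "theta_A": m * theta[g, 2],
                }
            )

    expr = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    design = DesignTable(pd.DataFrame(design_rows))
    truth = TruthTable(pd.DataFrame(truth_rows))
    return expr, design, truth


NOT_CALLED = "not_called"


def score_recovery(
    calls: pd.DataFrame, truth: TruthTable
) -> dict[str, pd.DataFrame | pd.Series]:
    """Compare interplay calls with the planted truth.

    Works on (gene, time) pairs.  Genes/times present in the truth but
    absent from the calls table (typically genes that failed the DEG
    filter) are counted as ``not_called``.  Sensitivity is
    called-correctly / planted; precision is called-correctly / called;
    an undefined ratio (zero denominator) is reported as NaN.

    Returns a dict with ``confusion`` (rows = planted categories incl.
    null, columns = called labels), ``sensitivity`` and ``precision``
    (per planted/called category).
    """
    truth_df = truth.data[["gene", "time", "category"]].rename(
        columns={"category": "planted"}
    )
    if len(calls) == 0:
        call_df = pd.DataFrame(columns=["gene", "time", "called"])
    else:
        call_df = calls[["gene", "time", "category"]].rename(
            columns={"category": "called"}
        )
    merged = truth_df.merge(call_df, on=["gene", "time"], how="left")
    merged["called"] = merged["called"].fillna(NOT_CALLED)
    confusion = (
        merged.groupby(["planted", "called"]).size().unstack(fill_value=0)
    )
    planted_names = [
        c for c in list(CATEGORY_EFFECTS) + [NULL_CATEGORY]
        if c in confusion.index
    ]
    confusion = confusion.loc[planted_names]

    sens = {}
    prec = {}
    for name in CATEGORY_EFFECTS:
        planted = int((merged["planted"] == name).sum())
        called = int((merged["called"] == name).sum())
        correct = int(
            ((merged["planted"] == name) & (merged["called"] == name)).sum()
        )
        sens[name] = correct / planted if planted else np.nan
        prec[name] = correct / called if called else np.nan
    return {
        "confusion": confusion,
        "sensitivity": pd.Series(sens, name="sensitivity"),
        "precision": pd.Series(prec, name="precision"),
    }
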