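"""Shared fixtures: small hand-controlled datasets and fitted models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adjinterplay import (
    DesignTable,
    ExpressionMatrix,
    SimulationConfig,
    align,
    estimate_eb_prior,
    fit_cell_means,
    generate_dataset,
)
from adjinterplay.expr_io import CONDITIONS


def make_dataset(
    thetas: dict[str, tuple[float, float, float]],
    sigma: float = 1e-3,
    n_rep: int = 6,
    time: str = "2h",
    baseline: float = 8.0,
    seed: int = 0,
):
    """Build a one-time-point factorial dataset with exact planted effects.

    ``thetas`` maps gene id -> (theta_M, theta_Q, theta_A); replicate
    noise is Normal(0, sigma^2).  Returns (expr, design).
    """
    rng = np.random.default_rng(seed)
    genes = list(thetas)
    columns = {}
    rows = []
    offsets = {"PBS": 0, "MPL": 1, "QS21": 2, "AS01": 3}
    theta_arr = np.array(
        [[0.0, *thetas[g]] for g in genes]
    )  # columns: PBS, M, Q, A offsets over baseline
    for cond in CONDITIONS:
        for rep in range(1, n_rep + 1):
            sample = f"{cond}_{time}_r{rep}"
            mean = baseline + theta_arr[:, offsets[cond]]
            columns[sample] = mean + rng.normal(0.0, sigma, size=len(genes))
            rows.append(
                {"sample_id": sample, "condition": cond, "time": time,
                 "replicate": rep}
            )
    expr = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    design = DesignTable(pd.DataFrame(rows))
    return expr, design


def fitted(expr, design):
    expr, design = align(expr, design)
    fit = fit_cell_means(expr, design)
    return fit, estimate_eb_prior(fit)


@pytest.fixture(scope="session")
def small_sim():
    """A modest planted simulation shared by read-only tests."""
    config = SimulationConfig(n_genes=400, seed=101)
    expr, design, truth = generate_dataset(config)
    expr, design = align(expr, design)
    fit = fit_cell_means(expr, design)
    prior = estimate_eb_prior(fit)
    return {
        "config": config,
        "expr": expr,
        "design": design,
        "truth": truth,
        "fit": fit,
        "prior": prior,
    }


@pytest.fixture()
def toy_expr_design():
    """Three genes with exact, easily hand-checked effects."""
    thetas = {
        "gA": (1.0, 0.5, 3.0),
        "gB": (0.0, 0.0, 0.0),
        "gC": (-2.0, 1.0, -1.0),
    }
    return make_dataset(thetas, sigma=0.05, n_rep=3, seed=7)
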