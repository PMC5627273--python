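"""End-to-end orchestration: ingest -> fit -> DEGs -> interplay -> PCA.

:func:`run_full` runs every stage, writes all result tables under an
output directory, and returns a JSON-serialisable manifest echoing the
parameters, package version and seed, so a run can be reproduced exactly
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .expr_io import (
    ExpressionMatrix,
    align,
    read_design,
    read_expression,
    write_table,
)
from .interplay import classify_table, summarize_categories
from .linear_model import (
    DEGCutoffs,
    call_degs,
    estimate_eb_prior,
    fit_cell_means,
)
from .pca_enrichment import (
    enrich_loadings,
    ora_hypergeometric,
    read_gmt,
    run_pca,
)
from .synthetic_data import (
    SimulationConfig,
    generate_dataset,
    score_recovery,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``expression_path`` + ``design_path``) or ``simulate``
    must be given.  ``pca_mode`` selects the PCA feature matrix: the log2
    expression of the DEG union (``"expression"``, default) or the
    per-gene effect scores (``"effect_scores"``).
    """

    outdir: str | Path = "results/run"
    expression_path: str | Path | None = None
    design_path: str | Path | None = None
    dialect: str = "plain_tsv"
    simulate: SimulationConfig | None = None
    cutoffs: DEGCutoffs = field(default_factory=DEGCutoffs)
    alpha: float = 0.05
    margin: float = 1.0
    pca_mode: str = "expression"
    gmt_path: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.expression_path is not None
        if self.design_path is not None and not has_paths:
            raise ValueError("design_path given without expression_path")
        if has_paths and self.design_path is None:
            raise ValueError("expression_path given without design_path")
        if has_paths == (self.simulate is not None):
            raise ValueError(
                "exactly one of input paths or a simulate block is required"
            )
        if self.pca_mode not in {"expression", "effect_scores"}:
            raise ValueError(f"unknown pca_mode {self.pca_mode!r}")


def _echo(config: RunConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, (list, tuple)):
            return [enc(x) for x in v]
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        return v

    return {
        f.name: enc(getattr(config, f.name))
        for f in dataclasses.fields(config)
    }


def run_full(config: RunConfig) -> dict:
    """Run every pipeline stage and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, table: pd.DataFrame, fmt: str = "tsv") -> None:
        path = outdir / f"{name}.{fmt}"
        write_table(table, path, format=fmt)
        artifacts[name] = str(path)

    truth = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        expr, design, truth = generate_dataset(sim)
        matrix_out = expr.data.reset_index(names="gene")
        emit("expression", matrix_out)
        emit("design", design.data)
        emit("truth", truth.data)
        logger.info("simulate: %d genes x %d samples", *expr.shape)
    else:
        expr = read_expression(config.expression_path, config.dialect)
        design = read_design(config.design_path)

    expr, design = align(expr, design)
    fit = fit_cell_means(expr, design)
    prior = estimate_eb_prior(fit)
    logger.info("prior: d0=%.3g s02=%.4g", prior.d0, prior.s02)

    deg_frames = []
    call_frames = []
    for time in design.times:
        degs = call_degs(fit, prior, time, config.cutoffs)
        emit(f"degs_{time}", degs)
        deg_frames.append(degs)
        deg_genes = degs.loc[degs["is_deg"], "gene"].tolist()
        calls = classify_table(
            fit, prior, time, genes=deg_genes,
            alpha=config.alpha, margin=config.margin,
        )
        emit(f"interplay_calls_{time}", calls)
        call_frames.append(calls)
        logger.info(
            "%s: %d DEGs, %d classified", time, len(deg_genes),
            int((calls["category"] != "unclassified").sum()),
        )
    deg_table = pd.concat(deg_frames, ignore_index=True)
    calls = pd.concat(call_frames, ignore_index=True)
    summary = summarize_categories(calls, deg_table)
    emit("category_summary", summary)
    emit("category_summary_json", summary, fmt="json")

    deg_union = sorted(set(deg_table.loc[deg_table["is_deg"], "gene"]))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _echo(config),
        "n_genes": expr.shape[0],
        "n_samples": expr.shape[1],
        "n_deg_union": len(deg_union),
    }
    if len(deg_union) >= 2 and expr.shape[1] >= 2:
        if config.pca_mode == "expression":
            feature = expr.data.loc[deg_union]
        else:
            from .interplay import compute_effect_scores

            frames = {
                time: compute_effect_scores(fit, time).loc[deg_union]
                for time in design.times
            }
            feature = pd.concat(frames, axis=1)
            feature.columns = [
                f"{theta}_{time}" for time, theta in feature.columns
            ]
        pca = run_pca(feature)
        emit("pca_scores", pca.scores.reset_index(names="sample"))
        emit("pca_loadings", pca.loadings.reset_index(names="gene"))
        emit(
            "pca_var_explained",
            pca.var_explained.rename_axis("component").reset_index(),
        )
        categories = {
            name: set(sub["gene"])
            for name, sub in calls.groupby("category")
            if name != "unclassified" and len(sub)
        }
        categories = {
            k: v & set(pca.loadings.index) for k, v in categories.items()
        }
        categories = {k: v for k, v in categories.items() if v}
        enrich_frames = [
            enrich_loadings(pca, comp, categories)
            for comp in pca.components[:2]
            if categories
        ]
        if enrich_frames:
            emit(
                "loading_enrichment",
                pd.concat(enrich_frames, ignore_index=True),
            )
    else:
        logger.warning("PCA skipped: fewer than 2 DEGs")

    if config.gmt_path is not None and deg_union:
        gene_sets = read_gmt(config.gmt_path)
        ora = ora_hypergeometric(
            set(deg_union), set(expr.gene_ids), gene_sets
        )
        emit("ora", ora)

    if truth is not None:
        report = score_recovery(calls, truth)
        emit(
            "recovery",
            pd.concat(
                [report["sensitivity"], report["precision"]], axis=1
            ).rename_axis("category").reset_index(),
        )
        emit(
            "confusion",
            report["confusion"].rename_axis("planted").reset_index(),
        )

    manifest["artifacts"] = artifacts
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True)
                             + "\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest
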