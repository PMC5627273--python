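#!/usr/bin/env python
"""Classify every AS01 DEG into an MPL x QS-21 interplay category.

For each time point, each DEG is assigned by intersection-union testing
over moderated difference tests and TOST equivalence tests (margin [-1,1]
log2, alpha = 0.05) to one of: irrelevance of MPL / of QS-21, additivity,
synergy, antagonism, potentiation / inhibition by either agent, emergence
(responsive only to the combination) — or left unclassified.  Writes the
per-gene calls and the per-time category distribution.
"""

import argparse
from pathlib import Path

import pandas as pd

from adjinterplay import (
    align,
    call_degs,
    classify_table,
    estimate_eb_prior,
    fit_cell_means,
    read_design,
    read_expression,
    summarize_categories,
    write_table,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path,
                    default=Path("results/analysis/data"))
parser.add_argument("--outdir", type=Path,
                    default=Path("results/analysis/interplay"))
args = parser.parse_args()

expr = read_expression(args.data / "expression.tsv")
design = read_design(args.data / "design.tsv")
expr, design = align(expr, design)
fit = fit_cell_means(expr, design)
prior = estimate_eb_prior(fit)

deg_frames, call_frames = [], []
for time in design.times:
    degs = call_degs(fit, prior, time)
    deg_frames.append(degs)
    genes = degs.loc[degs["is_deg"], "gene"].tolist()
    calls = classify_table(fit, prior, time, genes=genes)
    write_table(calls, args.outdir / f"interplay_calls_{time}.tsv")
    call_frames.append(calls)

summary = summarize_categories(
    pd.concat(call_frames, ignore_index=True),
    pd.concat(deg_frames, ignore_index=True),
)
write_table(summary, args.outdir / "category_summary.tsv")

for time in design.times:
    sub = summary[summary["time"] == time]
    top = sub.sort_values("count", ascending=False).head(3)
    parts = ", ".join(
        f"{r.category} {r.count} ({100 * r.fraction:.0f}%)"
        for r in top.itertuples()
    )
    print(f"{time}: {int(sub['total_degs'].iloc[0])} DEGs; top: {parts}")
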