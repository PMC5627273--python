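#!/usr/bin/env python
"""Score interplay-call recovery against the planted ground truth.

Joins the per-time interplay calls with the generator's truth table and
reports per-category sensitivity and precision plus the full confusion
matrix (planted x called, including unclassified and not-called).
"""

import argparse
from pathlib import Path

import pandas as pd

from adjinterplay import score_recovery, write_table
from adjinterplay.synthetic_data import TruthTable

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path,
                    default=Path("results/analysis/data"))
parser.add_argument("--interplay", type=Path,
                    default=Path("results/analysis/interplay"))
parser.add_argument("--outdir", type=Path,
                    default=Path("results/analysis/recovery"))
args = parser.parse_args()

truth = TruthTable(pd.read_csv(args.data / "truth.tsv", sep="\t"))
calls = pd.concat(
    [pd.read_csv(p, sep="\t")
     for p in sorted(args.interplay.glob("interplay_calls_*.tsv"))],
    ignore_index=True,
)

report = score_recovery(calls, truth)
table = pd.concat(
    [report["sensitivity"], report["precision"]], axis=1
).rename_axis("category").reset_index()
write_table(table, args.outdir / "recovery.tsv")
write_table(report["confusion"].rename_axis("planted").reset_index(),
            args.outdir / "confusion.tsv")

print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.3f}"))
worst = table.set_index("category")["sensitivity"].idxmin()
print(f"weakest category: {worst} "
      f"(sensitivity {table.set_index('category').loc[worst, 'sensitivity']:.3f})")
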