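"""Reading, validating and writing expression matrices and design tables.

The on-disk conventions are deliberately plain:

* expression matrix — tab-separated text, first column the gene/probe id,
  header row the sample ids, body log2-scale intensities;
* design table — tab-separated with columns ``sample_id``, ``condition``,
  ``time``, ``replicate``;
* GEO series-matrix files (SOFT-derived text) are accepted as an alternative
  expression dialect: only the ``!series_matrix_table_begin`` /
  ``!series_matrix_table_end`` block is parsed, sample metadata is not.

Matrices are required complete: a missing value is an error, never imputed,
because the downstream per-gene least-squares fit assumes complete cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Factorial condition labels: sham control, each immunostimulant alone,
#: and the liposomal combination.
CONDITIONS = ("PBS", "MPL", "QS21", "AS01")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    counts = pd.Series(list(ids)).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(
            f"duplicate {what}: {', '.join(map(str, dups.index.tolist()))}"
        )


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 intensities with no missing values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.map(
                lambda v: not isinstance(v, (int, float, np.number))
                or v is True or v is False
            ).to_numpy()
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-numeric cell at gene {self.data.index[r]!r}, "
                    f"sample {self.data.columns[c]!r}"
                )
            values = self.data.astype(float).to_numpy()
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r} (imputation is out of scope)"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class DesignTable:
    """Sample -> (condition, time, replicate) factorial assignment.

    ``time`` labels keep their order of first appearance, which defines the
    ordered time axis used everywhere downstream.
    """

    data: pd.DataFrame
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "time", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(
                f"design table missing columns: {sorted(missing)}"
            )
        self.data = self.data.reset_index(drop=True)
        _check_unique(self.data["sample_id"], "sample ids")
        unknown = set(self.data["condition"]) - set(self.conditions)
        if unknown:
            raise ValidationError(
                f"unknown condition labels: {sorted(unknown)} "
                f"(expected one of {list(self.conditions)})"
            )
        rep = pd.to_numeric(self.data["replicate"], errors="coerce")
        if rep.isna().any() or (rep <= 0).any() or (rep != rep.round()).any():
            raise ValidationError("replicate must be a positive integer")
        self.data["replicate"] = rep.astype(int)
        self.data["time"] = self.data["time"].astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def times(self) -> list[str]:
        """Time labels in order of first appearance."""
        return list(dict.fromkeys(self.data["time"]))

    def cells(self) -> pd.Series:
        """Replicate count per (condition, time) cell."""
        return self.data.groupby(["condition", "time"], sort=False).size()

    def samples_in_cell(self, condition: str, time: str) -> list[str]:
        mask = (self.data["condition"] == condition) & (
            self.data["time"] == time
        )
        return list(self.data.loc[mask, "sample_id"])


def read_expression(
    path: str | Path, dialect: str = "plain_tsv"
) -> ExpressionMatrix:
    """Read a log2 expression matrix.

    Parameters
    ----------
    path
        TSV file (first column gene ids, header sample ids) or a GEO
        series-matrix text file.
    dialect
        ``"plain_tsv"`` or ``"geo_series_matrix"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "geo_series_matrix":
        df = _read_series_matrix_block(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene ids")
    _check_unique(df.columns, "sample ids")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        df[col] = coerced
    return ExpressionMatrix(df)


def _read_series_matrix_block(path: Path) -> pd.DataFrame:
    """Parse only the data block of a GEO series-matrix file."""
    lines = path.read_text().splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines)
            if ln.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, ln in enumerate(lines)
            if ln.startswith("!series_matrix_table_end")
        )
    except StopIteration as exc:
        raise ValidationError(
            f"{path}: no !series_matrix_table_begin/end block found"
        ) from exc
    block = [ln.replace('"', "") for ln in lines[start + 1:end] if ln.strip()]
    rows = [ln.split("\t") for ln in block]
    header = rows[0][1:]
    index = [r[0] for r in rows[1:]]
    body = [r[1:] for r in rows[1:]]
    return pd.DataFrame(body, index=index, columns=header)


def read_design(path: str | Path) -> DesignTable:
    """Read and validate a sample design table (TSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "time": str})
    table = DesignTable(df)
    logger.info(
        "design: %d samples, conditions=%s, times=%s",
        len(table.sample_ids),
        sorted(set(table.data["condition"])),
        table.times,
    )
    return table


def align(
    expr: ExpressionMatrix, design: DesignTable
) -> tuple[ExpressionMatrix, DesignTable]:
    """Reorder matrix columns to the design's sample order.

    Samples present in the matrix but absent from the design are dropped
    with a logged warning; a design sample absent from the matrix is an
    error.
    """
    matrix_samples = set(expr.sample_ids)
    missing = [s for s in design.sample_ids if s not in matrix_samples]
    if missing:
        raise ValidationError(
            f"design samples absent from matrix: {missing}"
        )
    if not design.sample_ids:
        raise ValidationError("empty design: no samples to align")
    dropped = [s for s in expr.sample_ids if s not in set(design.sample_ids)]
    if dropped:
        logger.warning(
            "align: dropping %d matrix sample(s) absent from design: %s",
            len(dropped), dropped,
        )
    aligned = ExpressionMatrix(expr.data.loc[:, design.sample_ids])
    return aligned, design


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    sig_digits: int = 6,
) -> None:
    """Write a result table with a deterministic layout.

    Floats are serialised at ``sig_digits`` significant digits so that
    identical analyses produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        records.to_csv(
            path, sep="\t", index=False, float_format=f"%.{sig_digits}g"
        )
    elif format == "json":
        def _round(v):
            if isinstance(v, (float, np.floating)):
                if np.isnan(v):
                    return None
                return float(f"%.{sig_digits}g" % v)
            if isinstance(v, (np.integer,)):
                return int(v)
            return v

        payload = [
            {k: _round(v) for k, v in row.items()}
            for row in records.to_dict(orient="records")
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")
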