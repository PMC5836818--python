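"""Expression-matrix input/output, probe-to-gene collapse, low-expression filtering.

Expression values are log2-scale normalized intensities (post-RMA or equivalent);
no normalization is performed here.  Two text dialects are supported: plain TSV
(first column ``probe_id``/``gene_id``, remaining columns samples) and the GEO
Series Matrix table section delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` sentinels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeTable",
    "ExpressionParseError",
    "read_expression",
    "write_expression",
    "read_probe_table",
    "concat_cohorts",
    "collapse_probes",
    "filter_low_expression",
    "check_cohort_medians",
]

_SM_BEGIN = "!series_matrix_table_begin"
_SM_END = "!series_matrix_table_end"


class ExpressionParseError(ValueError):
    """Raised when an expression file cannot be parsed; message names the location."""


@dataclass
class ExpressionMatrix:
    """A genes-(or probes-)by-samples log2 expression matrix.

    ``values`` is indexed by feature identifier with sample identifiers as
    columns; ``cohort_of_sample`` assigns every sample to exactly one cohort.
    """

    values: pd.DataFrame
    cohort_of_sample: dict[str, str] = field(default_factory=dict)
    level: str = "gene"  # "gene" after probe collapse, "probe" before

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite real numbers")
        missing = [s for s in self.values.columns if s not in self.cohort_of_sample]
        if missing:
            raise ValueError(f"samples without cohort assignment: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_cohort(self, cohort: str) -> list[str]:
        return [s for s in self.values.columns if self.cohort_of_sample[s] == cohort]

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.cohort_of_sample[s], None)
        return list(seen)


@dataclass
class ProbeTable:
    """Probe-to-gene annotation.  ``probe_id`` values are unique; several probes
    may annotate the same gene."""

    mapping: pd.DataFrame  # columns: probe_id, gene_id

    def __post_init__(self) -> None:
        cols = list(self.mapping.columns)
        if not {"probe_id", "gene_id"}.issubset(cols):
            raise ValueError("probe table needs columns probe_id, gene_id")
        if self.mapping["probe_id"].duplicated().any():
            dup = self.mapping["probe_id"][self.mapping["probe_id"].duplicated()]
            raise ValueError(f"duplicate probe_id(s): {sorted(set(dup))[:5]}")

    def gene_of(self) -> pd.Series:
        return self.mapping.set_index("probe_id")["gene_id"]


def _parse_table(lines: list[str], path: str, first_line_no: int) -> pd.DataFrame:
    if not lines:
        raise ExpressionParseError(f"{path}: empty data section")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise ExpressionParseError(
            f"{path}, line {first_line_no}: malformed header (need an identifier "
            f"column plus at least one sample column): {header!r}"
        )
    ids = [h.strip().strip('"') for h in header]
    body = lines[1:]
    if not body:
        raise ExpressionParseError(f"{path}: empty data section (header only)")
    rows: list[list[float]] = []
    index: list[str] = []
    for offset, line in enumerate(body, start=first_line_no + 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(ids):
            raise ExpressionParseError(
                f"{path}, line {offset}: expected {len(ids)} fields, got {len(parts)}"
            )
        index.append(parts[0].strip().strip('"'))
        vals = []
        for col, cell in zip(ids[1:], parts[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ExpressionParseError(
                    f"{path}, line {offset}, column {col!r}: non-numeric cell {cell!r}"
                ) from None
        rows.append(vals)
    return pd.DataFrame(rows, index=index, columns=ids[1:])


def read_expression(
    path: str | Path, cohort: str, dialect: str = "tsv"
) -> ExpressionMatrix:
    """Read one cohort's expression table.

    ``dialect`` is ``"tsv"`` or ``"series_matrix"``.  The feature level is taken
    from the header of the first column: ``gene_id`` means gene-level, anything
    else (``probe_id``, ``ID_REF``, ...) probe-level.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines(keepends=True)
    if dialect == "tsv":
        table_lines, first_no = lines, 1
    elif dialect == "series_matrix":
        begin = end = None
        for i, line in enumerate(lines):
            if line.strip() == _SM_BEGIN:
                begin = i
            elif line.strip() == _SM_END:
                end = i
        if begin is None or end is None or end <= begin:
            raise ExpressionParseError(
                f"{path}: missing {_SM_BEGIN}/{_SM_END} sentinels"
            )
        table_lines, first_no = lines[begin + 1 : end], begin + 2
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _parse_table(table_lines, str(path), first_no)
    first_col = table_lines[0].split("\t")[0].strip().strip('"').lower()
    level = "gene" if first_col == "gene_id" else "probe"
    if df.index.duplicated().any() and level == "gene":
        dup = df.index[df.index.duplicated()]
        raise ExpressionParseError(f"{path}: duplicate gene_id(s): {sorted(set(dup))[:5]}")
    return ExpressionMatrix(
        values=df, cohort_of_sample={s: cohort for s in df.columns}, level=level
    )


def write_expression(
    m: ExpressionMatrix, path: str | Path, dialect: str = "tsv", float_fmt: str = "%.6f"
) -> None:
    """Write a matrix in either dialect (inverse of :func:`read_expression`)."""
    path = Path(path)
    id_col = "gene_id" if m.level == "gene" else "probe_id"
    header = "\t".join([id_col, *m.values.columns])
    body = "\n".join(
        "\t".join([str(idx), *(float_fmt % v for v in row)])
        for idx, row in zip(m.values.index, m.values.to_numpy())
    )
    table = f"{header}\n{body}\n"
    if dialect == "tsv":
        path.write_text(table, encoding="utf-8")
    elif dialect == "series_matrix":
        path.write_text(f"!Series_title\t\"synthetic\"\n{_SM_BEGIN}\n{table}{_SM_END}\n",
                        encoding="utf-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_probe_table(path: str | Path) -> ProbeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeTable(mapping=df)


def concat_cohorts(matrices: Iterable[ExpressionMatrix]) -> ExpressionMatrix:
    """Join per-cohort matrices sharing one feature index into a meta-set matrix."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to concatenate")
    base = matrices[0].values.index
    for m in matrices[1:]:
        if not base.equals(m.values.index):
            raise ValueError("cohort matrices have different feature indices")
        if m.level != matrices[0].level:
            raise ValueError("cannot mix probe-level and gene-level matrices")
    values = pd.concat([m.values for m in matrices], axis=1)
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()]
        raise ValueError(f"duplicate sample ids across cohorts: {sorted(set(dup))[:5]}")
    cohort_map: dict[str, str] = {}
    for m in matrices:
        cohort_map.update(m.cohort_of_sample)
    return ExpressionMatrix(values=values, cohort_of_sample=cohort_map,
                            level=matrices[0].level)


def collapse_probes(m: ExpressionMatrix, probes: ProbeTable) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For each gene the retained row is the probe with the highest mean log2
    signal across all samples of the matrix; ties break to the
    lexicographically smallest probe_id.  Idempotent on gene-level input with a
    trivial (identity) annotation.
    """
    gene_of = probes.gene_of()
    missing = [p for p in m.values.index if p not in gene_of.index]
    if missing:
        raise ValueError(f"probes absent from annotation: {sorted(missing)[:10]}")
    mean_signal = m.values.mean(axis=1)
    frame = pd.DataFrame(
        {
            "probe_id": m.values.index,
            "gene_id": gene_of.loc[m.values.index].to_numpy(),
            "mean_signal": mean_signal.to_numpy(),
        }
    )
    # highest mean wins; tie -> lexicographically smallest probe_id
    frame = frame.sort_values(
        ["gene_id", "mean_signal", "probe_id"], ascending=[True, False, True]
    )
    chosen = frame.drop_duplicates("gene_id", keep="first")
    out = m.values.loc[chosen["probe_id"]].copy()
    out.index = chosen["gene_id"].to_numpy()
    out = out.sort_index()
    return ExpressionMatrix(values=out, cohort_of_sample=dict(m.cohort_of_sample),
                            level="gene")


def filter_low_expression(
    m: ExpressionMatrix, percentile: float = 0.95, threshold: float = 7.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop stably low-expressed genes.

    A gene is removed iff the ``percentile`` quantile (linear interpolation
    between order statistics, numpy default) of its log2 values across *all*
    samples of the matrix is strictly less than ``threshold``.  Returns the
    filtered matrix and the sorted list of removed gene ids.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).all(axis=1).any():
        bad = [g for g, row in zip(m.values.index, vals) if np.isnan(row).all()]
        raise ValueError(f"genes with all-missing values: {bad[:5]}")
    q = np.quantile(vals, percentile, axis=1, method="linear")
    removed_mask = q < threshold
    removed = sorted(np.asarray(m.values.index)[removed_mask])
    kept = m.values.loc[~removed_mask]
    return (
        ExpressionMatrix(values=kept, cohort_of_sample=dict(m.cohort_of_sample),
                         level=m.level),
        removed,
    )


def check_cohort_medians(m: ExpressionMatrix, max_spread: float = 2.0) -> dict[str, float]:
    """Sanity check that cohorts look jointly normalized.

    Warns (does not fail) if per-cohort overall medians differ by more than
    ``max_spread`` log2 units, which usually means the cohorts were not
    processed on a common scale.  Returns the per-cohort medians.
    """
    medians = {
        c: float(np.median(m.values[m.samples_of_cohort(c)].to_numpy()))
        for c in m.cohorts
    }
    if medians and max(medians.values()) - min(medians.values()) > max_spread:
        warnings.warn(
            f"cohort medians spread exceeds {max_spread} log2 units: {medians}",
            stacklevel=2,
        )
    return medians
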