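"""Structured tab-delimited result files.

A result file carries an 8-row parameter header (one ``# name<TAB>value``
row per query parameter), two summary rows with the number of comparisons
where the target was present and modulated, a column-header row, and one row
per related gene with its annotation fields (empty when unknown), the five
association counts and the four indexes. Index values are printed with six
significant digits, counts as plain integers, and undefined index values as
``NA``; formatting is locale-independent so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .arm import (
    AssociationCounts,
    AssociationIndexes,
    QueryParams,
    QuerySummary,
    ResultRow,
    is_defined,
)
from .store import GeneAnnotation

__all__ = ["write_results", "read_results", "HEADER_PARAMS", "RESULT_COLUMNS"]

PathLike = Union[str, Path]

#: the 8 parameter rows of the file header, in order
HEADER_PARAMS = (
    "target",
    "target_sign",
    "target_lfc_min",
    "gene_lfc_min",
    "adj_p_max",
    "co_pres_min_pct",
    "lift_min",
    "chi2_p_max",
)
SUMMARY_ROWS = ("target_present", "target_modulated")

RESULT_COLUMNS = (
    "gene_symbol",
    "description",
    "chromosome",
    "band",
    "strand",
    "start",
    "end",
    "stable_id",
    "n_tp",
    "n_tp_xp",
    "n_tm_xm",
    "n_tm_xp",
    "n_tp_xm",
    "co_pres",
    "co_expr",
    "lift",
    "chi2_p",
)

_COUNT_FIELDS = ("n_tp", "n_tp_xp", "n_tm_xm", "n_tm_xp", "n_tp_xm")
_INDEX_FIELDS = ("co_pres", "co_expr", "lift", "chi2_p")


def _fmt_index(value: float) -> str:
    return "NA" if not is_defined(value) else f"{value:.6g}"


def _fmt_param(name: str, params: QueryParams) -> str:
    value = getattr(params, name)
    if isinstance(value, str):
        return value
    if name in ("target_sign",):
        return str(int(value))
    return f"{value:.6g}"


def write_results(rows: Sequence[ResultRow], summary: QuerySummary, path: PathLike) -> None:
    """Write query output in the structured result-file layout."""
    params = summary.params
    lines = [f"# {name}\t{_fmt_param(name, params)}" for name in HEADER_PARAMS]
    lines.append(f"# target_present\t{summary.n_target_present}")
    lines.append(f"# target_modulated\t{summary.n_target_modulated}")
    lines.append("\t".join(RESULT_COLUMNS))
    for row in rows:
        ann = row.annotation or GeneAnnotation(row.gene)
        cells = [
            row.gene,
            ann.description,
            ann.chromosome,
            ann.band,
            ann.strand,
            "" if ann.start is None else str(ann.start),
            "" if ann.end is None else str(ann.end),
            ann.stable_id,
        ]
        cells += [str(getattr(row.counts, f)) for f in _COUNT_FIELDS]
        cells += [_fmt_index(getattr(row.indexes, f)) for f in _INDEX_FIELDS]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_results(path: PathLike) -> tuple[dict[str, str], dict[str, int], pd.DataFrame]:
    """Parse a result file back into (params, summary, table).

    Parameter values are returned as strings (as printed); summary counts as
    integers; the table as a DataFrame with numeric count/index columns
    (``NA`` becomes NaN) and string annotation columns.
    """
    text = Path(path).read_text(encoding="utf-8").splitlines()
    n_header = len(HEADER_PARAMS) + len(SUMMARY_ROWS)
    if len(text) < n_header + 1:
        raise ValueError(f"{path}: truncated result file")
    params: dict[str, str] = {}
    summary: dict[str, int] = {}
    for i, line in enumerate(text[:n_header]):
        if not line.startswith("# "):
            raise ValueError(f"{path}: malformed header row {i + 1}: {line!r}")
        name, _, value = line[2:].partition("\t")
        if i < len(HEADER_PARAMS):
            if name != HEADER_PARAMS[i]:
                raise ValueError(f"{path}: expected parameter {HEADER_PARAMS[i]!r}, got {name!r}")
            params[name] = value
        else:
            if name != SUMMARY_ROWS[i - len(HEADER_PARAMS)]:
                raise ValueError(f"{path}: unexpected summary row {name!r}")
            summary[name] = int(value)
    if text[n_header].split("\t") != list(RESULT_COLUMNS):
        raise ValueError(f"{path}: malformed column-header row")
    data: list[list] = []
    for line in text[n_header + 1 :]:
        cells = line.split("\t")
        if len(cells) != len(RESULT_COLUMNS):
            raise ValueError(f"{path}: row with {len(cells)} cells, expected {len(RESULT_COLUMNS)}")
        parsed: list = cells[:8]
        parsed += [int(c) for c in cells[8:13]]
        parsed += [math.nan if c == "NA" else float(c) for c in cells[13:]]
        data.append(parsed)
    table = pd.DataFrame(data, columns=list(RESULT_COLUMNS))
    return params, summary, table
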