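"""Transactional data model for comparison-level differential expression.

The mining engine views a *comparison* -- one pairwise contrast between two
sample groups of an expression experiment -- as a transaction, and the genes
differentially expressed in that comparison as the transaction's items.
This module defines the on-disk and in-memory representation of a corpus of
comparisons (the *comparison store*), the probe-to-gene-symbol mapping, and
the reduction of a gene's per-probe measures in one comparison to the two
flags the mining engine consumes:

``present``
    at least one probe of the gene was measured with an adjusted p value
    passing the significance threshold;
``modulated``
    the gene is present and the log2 fold change of a significant probe
    passes the (possibly directional) LFC threshold.

All flat files are plain tab-delimited UTF-8 text with ``.`` as decimal
separator and no quoting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "ProbeMeasure",
    "ComparisonRecord",
    "ProbeGeneMap",
    "GeneState",
    "GeneAnnotation",
    "gene_state",
    "read_store",
    "write_store",
    "read_probe_map",
    "write_probe_map",
    "read_annotation",
    "write_annotation",
    "STORE_COLUMNS",
    "PROBE_MAP_COLUMNS",
    "ANNOTATION_COLUMNS",
]

STORE_COLUMNS = (
    "comparison_id",
    "dataset_id",
    "oriented",
    "probe_id",
    "lfc",
    "p_value",
    "adj_p",
)
PROBE_MAP_COLUMNS = ("probe_id", "gene_symbol")
ANNOTATION_COLUMNS = (
    "gene_symbol",
    "description",
    "chromosome",
    "band",
    "strand",
    "start",
    "end",
    "stable_id",
)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ProbeMeasure:
    """Differential measures of a single probe within one comparison."""

    probe_id: str
    lfc: float
    p_value: float
    adj_p: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lfc):
            raise ValueError(f"probe {self.probe_id!r}: lfc must be finite, got {self.lfc!r}")
        for name in ("p_value", "adj_p"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ValueError(f"probe {self.probe_id!r}: {name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class ComparisonRecord:
    """One transaction: a comparison's per-probe differential measures.

    ``oriented`` is true when one side of the contrast is a designated
    control group, which gives the sign of ``lfc`` a biological meaning
    (up-/down-regulation relative to control).
    """

    comparison_id: str
    dataset_id: str
    oriented: bool
    measures: tuple[ProbeMeasure, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measures", tuple(self.measures))
        if not self.measures:
            raise ValueError(f"comparison {self.comparison_id!r}: needs at least one measure")
        ids = [m.probe_id for m in self.measures]
        if len(set(ids)) != len(ids):
            dupes = sorted({p for p in ids if ids.count(p) > 1})
            raise ValueError(
                f"comparison {self.comparison_id!r}: duplicate probe ids {dupes}"
            )

    def measure_of(self, probe_id: str) -> Optional[ProbeMeasure]:
        for m in self.measures:
            if m.probe_id == probe_id:
                return m
        return None


class ProbeGeneMap:
    """Many-to-one mapping from probe identifiers to official gene symbols.

    Probes absent from the map are *unmapped*: they stay in the store and may
    surface in result lists as candidate items under their own identifier,
    but they can never be chosen as the target gene.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, str] = dict(entries)
        by_symbol: dict[str, set[str]] = {}
        for probe, symbol in self._entries.items():
            by_symbol.setdefault(symbol, set()).add(probe)
        self._by_symbol = {s: frozenset(ps) for s, ps in by_symbol.items()}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._entries

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeGeneMap) and self._entries == other._entries

    @property
    def entries(self) -> Mapping[str, str]:
        return dict(self._entries)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self._by_symbol)

    def symbol_of(self, probe_id: str) -> Optional[str]:
        return self._entries.get(probe_id)

    def probes_of(self, symbol: str) -> frozenset[str]:
        return self._by_symbol.get(symbol, frozenset())

    @classmethod
    def from_tsv(cls, path: PathLike) -> "ProbeGeneMap":
        return read_probe_map(path)

    def to_tsv(self, path: PathLike) -> None:
        write_probe_map(self, path)


@dataclass(frozen=True)
class GeneState:
    """Presence/modulation flags of one gene within one comparison.

    ``sign`` is the direction (+1/-1) of the qualifying probe with the
    largest absolute LFC, or 0 when the gene is not modulated or the
    direction is undefined.
    """

    present: bool
    modulated: bool
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be one of -1, 0, +1, got {self.sign!r}")
        if self.modulated and not self.present:
            raise ValueError("modulated implies present")
        if self.sign != 0 and not self.modulated:
            raise ValueError("a non-zero sign implies modulated")


@dataclass(frozen=True)
class GeneAnnotation:
    """Optional per-gene annotation carried through to result files.

    Genomic coordinates are 1-based and fully closed; strand is ``+``/``-``.
    """

    gene_symbol: str
    description: str = ""
    chromosome: str = ""
    band: str = ""
    strand: str = ""
    start: Optional[int] = None
    end: Optional[int] = None
    stable_id: str = ""


def _validate_thresholds(adj_p_max: float, lfc_min: float, sign: int) -> None:
    if not (0.0 < adj_p_max <= 1.0):
        raise ValueError(f"adj_p_max must be in (0, 1], got {adj_p_max!r}")
    if lfc_min < 0:
        raise ValueError(f"lfc_min must be non-negative, got {lfc_min!r}")
    if sign not in (-1, 0, 1):
        raise ValueError(f"sign must be one of -1, 0, +1, got {sign!r}")


def _item_probes(gene: str, probe_map: ProbeGeneMap) -> frozenset[str]:
    """Probes addressed by an item name.

    A mapped gene symbol addresses all of its probes; an identifier that is
    not a mapped symbol and not a mapped probe acts as its own single-probe
    item (unmapped probes are retained as candidate items).
    """
    probes = probe_map.probes_of(gene)
    if probes:
        return probes
    if gene in probe_map:
        # a mapped probe id is addressed through its symbol, not directly
        return frozenset()
    return frozenset((gene,))


def gene_state(
    record: ComparisonRecord,
    gene: str,
    probe_map: ProbeGeneMap,
    adj_p_max: float,
    lfc_min: float,
    sign: int = 0,
) -> GeneState:
    """Reduce a gene's probes in one comparison to presence/modulation flags.

    A gene is *present* when any of its probes has ``adj_p <= adj_p_max``
    (inclusive). It is *modulated* when a single probe simultaneously passes
    the significance threshold and the LFC test: ``|lfc| >= lfc_min`` for
    ``sign == 0``, ``lfc >= lfc_min`` for ``sign == +1``, ``lfc <= -lfc_min``
    for ``sign == -1``. A directional test (``sign != 0``) only ever
    qualifies in oriented comparisons, where the sign of the LFC is defined.

    When probes disagree, the reported direction comes from the qualifying
    probe with the largest ``|lfc|`` (ties broken by smallest probe id).
    A gene with no probes in the record is absent: all flags false.
    """
    _validate_thresholds(adj_p_max, lfc_min, sign)
    probes = _item_probes(gene, probe_map)
    measures = [m for m in record.measures if m.probe_id in probes]
    if not measures:
        return GeneState(False, False, 0)

    significant = [m for m in measures if m.adj_p <= adj_p_max]
    present = bool(significant)
    if not present or (sign != 0 and not record.oriented):
        return GeneState(present, False, 0)

    if sign == 0:
        qualifying = [m for m in significant if abs(m.lfc) >= lfc_min]
    elif sign > 0:
        qualifying = [m for m in significant if m.lfc >= lfc_min]
    else:
        qualifying = [m for m in significant if m.lfc <= -lfc_min]
    if not qualifying:
        return GeneState(True, False, 0)

    best = min(qualifying, key=lambda m: (-abs(m.lfc), m.probe_id))
    direction = (best.lfc > 0) - (best.lfc < 0)
    return GeneState(True, True, int(direction))


# ---------------------------------------------------------------------------
# flat-file serialization
# ---------------------------------------------------------------------------

def _read_tsv(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(columns):
        raise ValueError(
            f"{path}: expected header {list(columns)}, found {list(df.columns)}"
        )
    return df


def _numeric_column(df: pd.DataFrame, name: str, path: PathLike) -> pd.Series:
    def parse(value: str) -> float:
        try:
            return float(value)
        except ValueError:
            return math.nan

    values = df[name].map(parse)
    bad = values.isna()
    if bad.any():
        i = int(bad.idxmax())
        line = i + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed {name} value {df[name][i]!r} at line {line}")
    return values


def read_store(path: PathLike) -> list[ComparisonRecord]:
    """Read a comparison-store TSV into a list of :class:`ComparisonRecord`.

    Row order in the file is not significant; records are returned sorted by
    comparison id. Malformed rows and duplicate (comparison, probe) pairs
    raise :class:`ValueError` naming the offending line.
    """
    df = _read_tsv(path, STORE_COLUMNS)
    if df.empty:
        return []
    bad_flag = ~df["oriented"].isin(["0", "1"])
    if bad_flag.any():
        line = int(bad_flag.idxmax()) + 2
        raise ValueError(
            f"{path}: oriented must be 0 or 1, got {df['oriented'][bad_flag.idxmax()]!r} at line {line}"
        )
    numeric = {name: _numeric_column(df, name, path) for name in ("lfc", "p_value", "adj_p")}

    dup = df.duplicated(subset=["comparison_id", "probe_id"])
    if dup.any():
        i = int(dup.idxmax())
        raise ValueError(
            f"{path}: duplicate probe {df['probe_id'][i]!r} in comparison "
            f"{df['comparison_id'][i]!r} at line {i + 2}"
        )
    datasets = df.groupby("comparison_id")["dataset_id"].nunique()
    if (datasets > 1).any():
        cid = datasets[datasets > 1].index[0]
        raise ValueError(f"{path}: comparison {cid!r} spans multiple dataset ids")

    records = []
    frame = df.assign(**numeric)
    for cid, chunk in frame.groupby("comparison_id", sort=True):
        measures = tuple(
            ProbeMeasure(row.probe_id, float(row.lfc), float(row.p_value), float(row.adj_p))
            for row in chunk.itertuples(index=False)
        )
        records.append(
            ComparisonRecord(
                comparison_id=str(cid),
                dataset_id=str(chunk["dataset_id"].iloc[0]),
                oriented=chunk["oriented"].iloc[0] == "1",
                measures=measures,
            )
        )
    return records


def _fmt(value: float) -> str:
    # shortest representation that round-trips the exact float
    return repr(float(value))


def write_store(records: Iterable[ComparisonRecord], path: PathLike) -> None:
    """Write records to the comparison-store TSV dialect.

    Rows are sorted by (comparison_id, probe_id) so repeated writes of the
    same collection are byte-identical.
    """
    lines = ["\t".join(STORE_COLUMNS)]
    for rec in sorted(records, key=lambda r: r.comparison_id):
        flag = "1" if rec.oriented else "0"
        for m in sorted(rec.measures, key=lambda m: m.probe_id):
            lines.append(
                "\t".join(
                    (
                        rec.comparison_id,
                        rec.dataset_id,
                        flag,
                        m.probe_id,
                        _fmt(m.lfc),
                        _fmt(m.p_value),
                        _fmt(m.adj_p),
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_probe_map(path: PathLike) -> ProbeGeneMap:
    df = _read_tsv(path, PROBE_MAP_COLUMNS)
    dup = df.duplicated(subset=["probe_id"])
    if dup.any():
        i = int(dup.idxmax())
        raise ValueError(f"{path}: probe {df['probe_id'][i]!r} mapped twice (line {i + 2})")
    return ProbeGeneMap(dict(zip(df["probe_id"], df["gene_symbol"])))


def write_probe_map(probe_map: ProbeGeneMap, path: PathLike) -> None:
    lines = ["\t".join(PROBE_MAP_COLUMNS)]
    for probe, symbol in sorted(probe_map.entries.items()):
        lines.append(f"{probe}\t{symbol}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotation(path: PathLike) -> dict[str, GeneAnnotation]:
    """Read a gene-annotation TSV into a symbol-keyed dictionary."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    out: dict[str, GeneAnnotation] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.gene_symbol in out:
            raise ValueError(f"{path}: gene {row.gene_symbol!r} annotated twice (line {i + 2})")
        if row.strand not in ("", "+", "-"):
            raise ValueError(f"{path}: strand must be +/-, got {row.strand!r} (line {i + 2})")
        out[row.gene_symbol] = GeneAnnotation(
            gene_symbol=row.gene_symbol,
            description=row.description,
            chromosome=row.chromosome,
            band=row.band,
            strand=row.strand,
            start=int(row.start) if row.start != "" else None,
            end=int(row.end) if row.end != "" else None,
            stable_id=row.stable_id,
        )
    return out


def write_annotation(annotation: Mapping[str, GeneAnnotation], path: PathLike) -> None:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for symbol in sorted(annotation):
        a = annotation[symbol]
        lines.append(
            "\t".join(
                (
                    a.gene_symbol,
                    a.description,
                    a.chromosome,
                    a.band,
                    a.strand,
                    "" if a.start is None else str(a.start),
                    "" if a.end is None else str(a.end),
                    a.stable_id,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
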