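"""Target-constrained association rule mining over comparison transactions.

Given a corpus of pairwise-comparison differential-expression results and a
target gene T, the engine evaluates, for every other gene X measured in the
corpus, rules of the form *IF T is differentially expressed THEN X is
differentially expressed*. Because one item of every rule is fixed and rules
have cardinality 2, no frequent-itemset enumeration is needed: the engine
tallies five counts per candidate over the transactions and derives four
quality indexes.

Counts (over all comparisons):

====================  ====================================================
``n_tp``              target present
``n_tp_xp``           target and X both present
``n_tm_xm``           target and X both modulated
``n_tm_xp``           target modulated and X present
``n_tp_xm``           target present and X modulated
====================  ====================================================

Indexes:

* co-presence ``n_tp_xp / n_tp`` -- a co-measurement filter, screening out
  candidates observed together with the target too rarely for the other
  indexes to be reliable;
* co-expression (the support analogue) ``n_tm_xm / n_tp_xp``;
* Lift ``(n_tp_xp * n_tm_xm) / (n_tp_xm * n_tm_xp)`` -- the ratio of the
  observed joint modulation to that expected under independence,
  conditional on co-presence; 1 marks random association;
* the p value of a 1-df Pearson chi-square independence test (no continuity
  correction) on the 2x2 modulation table over the co-present comparisons.

Quantities whose defining ratio has a zero denominator or a degenerate
margin are *undefined* and carried as NaN; undefined rows never pass a
positive filter threshold.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .store import (
    ComparisonRecord,
    GeneAnnotation,
    ProbeGeneMap,
    gene_state,
)

__all__ = [
    "UNDEFINED",
    "is_defined",
    "AssociationCounts",
    "AssociationIndexes",
    "QueryParams",
    "ResultRow",
    "QuerySummary",
    "count_associations",
    "co_presence",
    "co_expression",
    "lift",
    "chi2_pvalue",
    "compute_indexes",
    "association_table",
    "run_query",
]

#: marker for index values whose defining ratio is degenerate
UNDEFINED = float("nan")


def is_defined(value: float) -> bool:
    """True unless ``value`` is the undefined-marker (NaN)."""
    return not math.isnan(value)


@dataclass(frozen=True)
class AssociationCounts:
    """The five transaction tallies for one target/candidate pair."""

    n_tp: int
    n_tp_xp: int
    n_tm_xm: int
    n_tm_xp: int
    n_tp_xm: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_tp_xp", "n_tm_xm", "n_tm_xp", "n_tp_xm"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_tm_xm > min(self.n_tm_xp, self.n_tp_xm):
            raise ValueError("n_tm_xm cannot exceed n_tm_xp or n_tp_xm")
        if max(self.n_tm_xp, self.n_tp_xm) > self.n_tp_xp:
            raise ValueError("n_tm_xp and n_tp_xm cannot exceed n_tp_xp")
        if self.n_tp_xp > self.n_tp:
            raise ValueError("n_tp_xp cannot exceed n_tp")


@dataclass(frozen=True)
class AssociationIndexes:
    """The four quality indexes for one target/candidate pair."""

    co_pres: float
    co_expr: float
    lift: float
    chi2_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.co_pres <= 1.0):
            raise ValueError(f"co_pres must be in [0, 1], got {self.co_pres!r}")
        if is_defined(self.co_expr) and not (0.0 <= self.co_expr <= 1.0):
            raise ValueError(f"co_expr must be in [0, 1], got {self.co_expr!r}")
        if is_defined(self.lift) and self.lift < 0:
            raise ValueError(f"lift must be non-negative, got {self.lift!r}")
        if is_defined(self.chi2_p) and not (0.0 <= self.chi2_p <= 1.0):
            raise ValueError(f"chi2_p must be in [0, 1], got {self.chi2_p!r}")


@dataclass(frozen=True)
class QueryParams:
    """The full query parameter set.

    ``target_sign``/``gene_sign`` restrict modulation to up- (+1) or
    down-regulation (-1); 0 accepts both directions. Directional tests only
    qualify in oriented comparisons. The defaults are the canonical
    operating point: LFC thresholds 1, adjusted-p 0.05, co-presence 40%,
    Lift 2 and chi-square p 0.05.
    """

    target: str
    target_sign: int = 0
    gene_sign: int = 0
    target_lfc_min: float = 1.0
    gene_lfc_min: float = 1.0
    adj_p_max: float = 0.05
    co_pres_min_pct: float = 40.0
    lift_min: float = 2.0
    chi2_p_max: float = 0.05

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("target gene symbol is required")
        for name in ("target_sign", "gene_sign"):
            if getattr(self, name) not in (-1, 0, 1):
                raise ValueError(f"{name} must be one of -1, 0, +1")
        for name in ("target_lfc_min", "gene_lfc_min", "co_pres_min_pct", "lift_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("adj_p_max", "chi2_p_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")


@dataclass(frozen=True)
class ResultRow:
    """One related gene: its tallies, indexes and optional annotation."""

    gene: str
    counts: AssociationCounts
    indexes: AssociationIndexes
    annotation: Optional[GeneAnnotation] = None


@dataclass(frozen=True)
class QuerySummary:
    """Echo of the query parameters plus the target's own tallies."""

    params: QueryParams
    n_target_present: int
    n_target_modulated: int

    def __post_init__(self) -> None:
        if self.n_target_modulated > self.n_target_present:
            raise ValueError("target cannot be modulated more often than present")


# ---------------------------------------------------------------------------
# indexes
# ---------------------------------------------------------------------------

def co_presence(c: AssociationCounts) -> float:
    """Fraction of target-present comparisons where the candidate is present."""
    if c.n_tp == 0:
        raise ValueError("target never present: co-presence undefined")
    return c.n_tp_xp / c.n_tp


def co_expression(c: AssociationCounts) -> float:
    """Fraction of co-present comparisons where both genes are modulated."""
    if c.n_tp_xp == 0:
        return UNDEFINED
    return c.n_tm_xm / c.n_tp_xp


def lift(c: AssociationCounts) -> float:
    """Observed/expected joint modulation ratio; 1 marks random association."""
    denom = c.n_tp_xm * c.n_tm_xp
    if denom == 0:
        return UNDEFINED
    return (c.n_tp_xp * c.n_tm_xm) / denom


def chi2_pvalue(c: AssociationCounts) -> float:
    """Pearson chi-square independence p value on the co-present 2x2 table.

    The table is built over the ``n_tp_xp`` co-present comparisons -- the
    only regime where modulation of both genes is observable::

        a = n_tm_xm              b = n_tm_xp - n_tm_xm
        c = n_tp_xm - n_tm_xm    d = n_tp_xp - n_tm_xp - n_tp_xm + n_tm_xm

    No continuity correction is applied; the test is two-sided with 1 df.
    A zero marginal total (or an empty table) makes the statistic undefined.
    """
    if c.n_tp_xp == 0:
        return UNDEFINED
    a = c.n_tm_xm
    b = c.n_tm_xp - c.n_tm_xm
    cc = c.n_tp_xm - c.n_tm_xm
    d = c.n_tp_xp - c.n_tm_xp - c.n_tp_xm + c.n_tm_xm
    if min(a, b, cc, d) < 0:
        raise ValueError(f"negative contingency cell from counts {c!r}")
    n = a + b + cc + d
    r1, r2, c1, c2 = a + b, cc + d, a + cc, b + d
    if 0 in (r1, r2, c1, c2):
        return UNDEFINED
    statistic = n * (a * d - b * cc) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2_dist.sf(statistic, df=1))


def compute_indexes(c: AssociationCounts) -> AssociationIndexes:
    return AssociationIndexes(
        co_pres=co_presence(c),
        co_expr=co_expression(c),
        lift=lift(c),
        chi2_p=chi2_pvalue(c),
    )


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_associations(
    records: Sequence[ComparisonRecord],
    target: str,
    candidate: str,
    probe_map: ProbeGeneMap,
    params: QueryParams,
) -> AssociationCounts:
    """Tally the five counts for one target/candidate pair.

    This is the reference, record-at-a-time path: it evaluates
    :func:`~coexmine.store.gene_state` for the target (with the target's
    sign and LFC threshold) and the candidate (with the gene-level ones) in
    every comparison. :func:`run_query` uses an equivalent vectorized path.
    """
    _check_target_usable(records, target, probe_map)
    n_tp = n_tp_xp = n_tm_xm = n_tm_xp = n_tp_xm = 0
    for rec in records:
        t = gene_state(rec, target, probe_map, params.adj_p_max, params.target_lfc_min, params.target_sign)
        if not t.present:
            continue
        x = gene_state(rec, candidate, probe_map, params.adj_p_max, params.gene_lfc_min, params.gene_sign)
        n_tp += 1
        n_tp_xp += t.present and x.present
        n_tm_xm += t.modulated and x.modulated
        n_tm_xp += t.modulated and x.present
        n_tp_xm += t.present and x.modulated
    return AssociationCounts(n_tp, n_tp_xp, n_tm_xm, n_tm_xp, n_tp_xm)


def _check_target_usable(
    records: Sequence[ComparisonRecord], target: str, probe_map: ProbeGeneMap
) -> None:
    probes = probe_map.probes_of(target)
    if not probes:
        raise ValueError(f"target not usable: {target!r} has no mapped probes")
    measured = any(m.probe_id in probes for rec in records for m in rec.measures)
    if not measured:
        raise ValueError(f"target not usable: {target!r} never measured in the store")


def _state_matrices(
    records: Sequence[ComparisonRecord],
    probe_map: ProbeGeneMap,
    params: QueryParams,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean per-(item, comparison) state matrices for the whole corpus.

    Returns ``(items, present, modulated, target_present, target_modulated)``
    where ``present``/``modulated`` use the gene-level thresholds for every
    item and the target vectors use the target-level ones. Unmapped probes
    appear as items under their own probe id.
    """
    item_index: dict[str, int] = {}
    item_codes: list[int] = []
    comp_codes: list[int] = []
    lfc_list: list[float] = []
    adjp_list: list[float] = []
    oriented_list: list[bool] = []
    for ci, rec in enumerate(records):
        for m in rec.measures:
            item = probe_map.symbol_of(m.probe_id) or m.probe_id
            code = item_index.setdefault(item, len(item_index))
            item_codes.append(code)
            comp_codes.append(ci)
            lfc_list.append(m.lfc)
            adjp_list.append(m.adj_p)
            oriented_list.append(rec.oriented)

    items = list(item_index)
    n_items, n_comps = len(items), len(records)
    ii = np.asarray(item_codes, dtype=np.intp)
    cc = np.asarray(comp_codes, dtype=np.intp)
    lfc = np.asarray(lfc_list, dtype=float)
    adjp = np.asarray(adjp_list, dtype=float)
    oriented = np.asarray(oriented_list, dtype=bool)

    significant = adjp <= params.adj_p_max

    def directional(sign: int, lfc_min: float) -> np.ndarray:
        if sign == 0:
            ok = np.abs(lfc) >= lfc_min
        elif sign > 0:
            ok = (lfc >= lfc_min) & oriented
        else:
            ok = (lfc <= -lfc_min) & oriented
        return significant & ok

    present = np.zeros((n_items, n_comps), dtype=bool)
    present[ii[significant], cc[significant]] = True

    qual_gene = directional(params.gene_sign, params.gene_lfc_min)
    modulated = np.zeros((n_items, n_comps), dtype=bool)
    modulated[ii[qual_gene], cc[qual_gene]] = True

    target_code = item_index.get(params.target)
    if target_code is None:
        t_present = np.zeros(n_comps, dtype=bool)
        t_mod = np.zeros(n_comps, dtype=bool)
    else:
        t_present = present[target_code]
        qual_target = directional(params.target_sign, params.target_lfc_min)
        on_target = ii == target_code
        t_mod = np.zeros(n_comps, dtype=bool)
        t_mod[cc[qual_target & on_target]] = True

    return items, present, modulated, t_present, t_mod


def association_table(
    records: Sequence[ComparisonRecord],
    probe_map: ProbeGeneMap,
    params: QueryParams,
) -> tuple[list[tuple[str, AssociationCounts]], QuerySummary]:
    """Counts for every candidate item (gene symbol or unmapped probe).

    No filtering is applied; this is the raw material :func:`run_query`
    ranks and filters, and is also useful for calibration studies.
    """
    _check_target_usable(records, params.target, probe_map)
    items, present, modulated, t_p, t_m = _state_matrices(records, probe_map, params)
    t_p_i = t_p.astype(np.int64)
    t_m_i = t_m.astype(np.int64)
    n_tp = int(t_p.sum())
    n_tp_xp = present @ t_p_i
    n_tm_xm = modulated @ t_m_i
    n_tm_xp = present @ t_m_i
    n_tp_xm = modulated @ t_p_i
    table = []
    for idx, item in enumerate(items):
        if item == params.target:
            continue
        table.append(
            (
                item,
                AssociationCounts(
                    n_tp,
                    int(n_tp_xp[idx]),
                    int(n_tm_xm[idx]),
                    int(n_tm_xp[idx]),
                    int(n_tp_xm[idx]),
                ),
            )
        )
    summary = QuerySummary(params, n_target_present=n_tp, n_target_modulated=int(t_m.sum()))
    return table, summary


def run_query(
    records: Sequence[ComparisonRecord],
    probe_map: ProbeGeneMap,
    params: QueryParams,
    annotation: Optional[Mapping[str, GeneAnnotation]] = None,
    timing_out: Optional[dict] = None,
) -> tuple[list[ResultRow], QuerySummary]:
    """Mine the corpus for genes co-modulated with the target.

    The filter cascade is applied in order:

    1. co-presence: ``co_pres * 100 >= co_pres_min_pct`` (indexes are never
       reported for under-co-measured candidates);
    2. Lift: defined and ``>= lift_min``; a ``lift_min`` of 0 disables the
       Lift filter;
    3. chi-square: p value defined and ``<= chi2_p_max``.

    Rows are ordered by descending Lift, ties by ascending chi-square p and
    then by symbol. ``timing_out``, when given, receives wall-clock timings
    of the two mining phases.
    """
    t0 = time.perf_counter()
    table, summary = association_table(records, probe_map, params)
    t1 = time.perf_counter()

    rows: list[ResultRow] = []
    if summary.n_target_present == 0:
        # a measured but never-significant target has no mining substrate
        table = []
    for item, counts in table:
        cp = co_presence(counts)
        if cp * 100.0 < params.co_pres_min_pct:
            continue
        li = lift(counts)
        if params.lift_min > 0 and not (is_defined(li) and li >= params.lift_min):
            continue
        chp = chi2_pvalue(counts)
        if not (is_defined(chp) and chp <= params.chi2_p_max):
            continue
        indexes = AssociationIndexes(cp, co_expression(counts), li, chp)
        ann = annotation.get(item) if annotation else None
        rows.append(ResultRow(item, counts, indexes, ann))

    rows.sort(
        key=lambda r: (
            -(r.indexes.lift if is_defined(r.indexes.lift) else -math.inf),
            r.indexes.chi2_p if is_defined(r.indexes.chi2_p) else math.inf,
            r.gene,
        )
    )
    t2 = time.perf_counter()
    if timing_out is not None:
        timing_out["gene_lists_s"] = t1 - t0
        timing_out["rule_generation_s"] = t2 - t1
    return rows, summary
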