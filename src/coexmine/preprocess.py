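"""Build a comparison store from a raw log2 intensity experiment.

The pipeline mirrors how curated expression experiments are turned into
pairwise-comparison transactions:

1. samples are grouped by experimental factor (:class:`ExperimentDesign`);
2. groups with fewer than two samples are dropped (:func:`filter_groups`) --
   a design left with fewer than two groups is unusable;
3. an all-groups-versus-group contrast matrix is enumerated
   (:func:`build_contrast_matrix`), a pair being *oriented* when one side is
   the designated control group;
4. an externally curated selection list restricts the contrasts to those
   with a biological rationale (:func:`apply_selection`);
5. per-probe differential statistics are computed for each retained contrast
   (:func:`differential_expression`): the log2 fold change is the difference
   of group means, the p value comes from a Welch two-sample t test, and
   adjusted p values are Benjamini-Hochberg across all probes of the
   comparison.

The store format also accepts differential statistics computed by external
pipelines (e.g. moderated linear-model fits); this module is one concrete,
self-contained way of producing them.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .store import ComparisonRecord, ProbeMeasure

__all__ = [
    "ExperimentDesign",
    "IntensityMatrix",
    "ContrastPair",
    "filter_groups",
    "build_contrast_matrix",
    "apply_selection",
    "differential_expression",
    "adjust_pvalues",
    "build_store",
    "read_design",
    "read_selection",
    "DESIGN_COLUMNS",
    "SELECTION_COLUMNS",
]

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("dataset_id", "sample_id", "group", "is_control")
SELECTION_COLUMNS = ("dataset_id", "group_a", "group_b")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample grouping of one experiment by experimental factor."""

    dataset_id: str
    groups: Mapping[str, tuple[str, ...]]
    control_group: Optional[str] = None

    def __post_init__(self) -> None:
        groups = {label: tuple(samples) for label, samples in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        seen: set[str] = set()
        for label, samples in groups.items():
            if not samples:
                raise ValueError(f"group {label!r}: empty sample list")
            overlap = seen.intersection(samples)
            if overlap or len(set(samples)) != len(samples):
                raise ValueError(f"group {label!r}: sample lists must be disjoint")
            seen.update(samples)
        if self.control_group is not None and self.control_group not in groups:
            raise ValueError(f"control group {self.control_group!r} not among groups")

    @property
    def usable(self) -> bool:
        """At least two groups are needed to form any contrast."""
        return len(self.groups) >= 2

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for samples in self.groups.values() for s in samples)


@dataclass(frozen=True)
class ContrastPair:
    """An unordered pair of groups to compare.

    When the pair is oriented, ``group_b`` is the control: positive LFC
    means higher expression in ``group_a`` (up-regulation versus control).
    """

    group_a: str
    group_b: str
    oriented: bool = False

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError(f"contrast must involve two distinct groups, got {self.group_a!r}")

    def matches(self, a: str, b: str) -> bool:
        return {self.group_a, self.group_b} == {a, b}


@dataclass
class IntensityMatrix:
    """Log2 intensity values, probes by samples; NaN marks missing values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids in intensity matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in intensity matrix")
        self.values = self.values.astype(float)

    @property
    def probes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @classmethod
    def from_tsv(cls, path: PathLike) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name != "probe_id":
            raise ValueError(f"{path}: first column must be 'probe_id', got {df.index.name!r}")
        return cls(df)

    def to_tsv(self, path: PathLike) -> None:
        df = self.values.copy()
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t", float_format="%.10g", na_rep="")


def filter_groups(design: ExperimentDesign, min_size: int = 2) -> ExperimentDesign:
    """Drop groups with fewer than ``min_size`` samples.

    Groups too small to estimate a within-group variance cannot enter any
    contrast. The returned design may be left unusable (fewer than two
    groups); that is a status queried via :attr:`ExperimentDesign.usable`,
    not an error, so whole experiments can be discarded gracefully.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size!r}")
    kept = {label: s for label, s in design.groups.items() if len(s) >= min_size}
    control = design.control_group if design.control_group in kept else None
    return ExperimentDesign(design.dataset_id, kept, control)


def build_contrast_matrix(design: ExperimentDesign) -> list[ContrastPair]:
    """Enumerate all groups-versus-group contrasts of a usable design.

    For ``k`` groups this yields exactly ``k*(k-1)/2`` unordered pairs in a
    deterministic label-sorted order. A pair involving the control group is
    oriented with the control on the ``group_b`` side.
    """
    if not design.usable:
        raise ValueError(
            f"design {design.dataset_id!r} is unusable: fewer than two groups"
        )
    control = design.control_group
    pairs = []
    for a, b in itertools.combinations(sorted(design.groups), 2):
        if control is not None and control in (a, b):
            other = b if a == control else a
            pairs.append(ContrastPair(other, control, oriented=True))
        else:
            pairs.append(ContrastPair(a, b, oriented=False))
    return sorted(pairs, key=lambda p: (p.group_a, p.group_b))


def apply_selection(
    pairs: Sequence[ContrastPair],
    selection: Iterable[tuple[str, str, str]],
    dataset_id: Optional[str] = None,
) -> list[ContrastPair]:
    """Restrict a contrast matrix to an externally curated selection.

    ``selection`` rows are ``(dataset_id, group_a, group_b)``; the order of
    the two group labels is irrelevant. When ``dataset_id`` is given,
    entries for other datasets are ignored (they belong to other contrast
    matrices); every entry considered must match a pair, otherwise a
    :class:`ValueError` names it.
    """
    out: list[ContrastPair] = []
    for entry in selection:
        ds, a, b = entry
        if dataset_id is not None and ds != dataset_id:
            continue
        matched = [p for p in pairs if p.matches(a, b)]
        if not matched:
            raise ValueError(f"selection entry {tuple(entry)!r} matches no contrast pair")
        out.append(matched[0])
    return out


def adjust_pvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def differential_expression(
    matrix: IntensityMatrix,
    pair: ContrastPair,
    design: ExperimentDesign,
) -> tuple[list[ProbeMeasure], int]:
    """Per-probe differential statistics for one contrast.

    Returns ``(measures, n_omitted)``. For each probe with at least two
    non-missing values on both sides:

    * ``lfc``  -- mean(group_a) - mean(group_b) on the log2 scale (group_b is
      the control when the pair is oriented);
    * ``p_value`` -- Welch unequal-variance two-sample t test;
    * ``adj_p``  -- Benjamini-Hochberg across all reported probes.

    Probes where both groups have zero variance get ``p = 1`` when the means
    agree (no evidence of change) and ``p = 0`` with a logged warning when
    they differ (change without a variance estimate).
    """
    for label in (pair.group_a, pair.group_b):
        if label not in design.groups:
            raise ValueError(f"group {label!r} not in design {design.dataset_id!r}")
    missing = [s for s in design.samples if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"samples missing from intensity matrix: {missing[:5]}")

    A = matrix.values[list(design.groups[pair.group_a])].to_numpy(dtype=float)
    B = matrix.values[list(design.groups[pair.group_b])].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(A), axis=1)
    n_b = np.sum(~np.isnan(B), axis=1)
    keep = (n_a >= 2) & (n_b >= 2)
    n_omitted = int(np.sum(~keep))
    if n_omitted:
        logger.info(
            "%s vs %s: omitted %d probes with <2 usable values in a group",
            pair.group_a,
            pair.group_b,
            n_omitted,
        )
    if not keep.any():
        return [], n_omitted

    A, B = A[keep], B[keep]
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
        var_a = np.nanvar(A, axis=1, ddof=1)
        var_b = np.nanvar(B, axis=1, ddof=1)
    lfc = mean_a - mean_b

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # degenerate zero-variance probes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(result.pvalue, dtype=float)

    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        no_shift = degenerate & (lfc == 0)
        shifted = degenerate & (lfc != 0)
        p[no_shift] = 1.0
        p[shifted] = 0.0
        if shifted.any():
            logger.warning(
                "%s vs %s: %d zero-variance probes with unequal means (p set to 0)",
                pair.group_a,
                pair.group_b,
                int(shifted.sum()),
            )
    p = np.clip(p, 0.0, 1.0)

    adj = adjust_pvalues(p)
    probes = np.asarray(matrix.probes, dtype=object)[keep]
    measures = [
        ProbeMeasure(str(probe), float(l), float(pv), float(av))
        for probe, l, pv, av in zip(probes, lfc, p, adj)
    ]
    return measures, n_omitted


def build_store(
    matrix: IntensityMatrix,
    design: ExperimentDesign,
    selection: Optional[Iterable[tuple[str, str, str]]] = None,
    min_group_size: int = 2,
) -> list[ComparisonRecord]:
    """Run the full preprocessing pipeline for one experiment.

    Returns one :class:`ComparisonRecord` per retained contrast; an unusable
    design (after group filtering) yields an empty list with a logged
    warning, mirroring how experiments without enough replication are
    discarded from a corpus.
    """
    filtered = filter_groups(design, min_group_size)
    if not filtered.usable:
        logger.warning("dataset %s discarded: fewer than two usable groups", design.dataset_id)
        return []
    pairs = build_contrast_matrix(filtered)
    if selection is not None:
        pairs = apply_selection(pairs, selection, dataset_id=design.dataset_id)
    records = []
    for pair in pairs:
        measures, _ = differential_expression(matrix, pair, filtered)
        if not measures:
            logger.warning(
                "dataset %s contrast %s vs %s: no reportable probes, skipped",
                design.dataset_id,
                pair.group_a,
                pair.group_b,
            )
            continue
        records.append(
            ComparisonRecord(
                comparison_id=f"{design.dataset_id}:{pair.group_a}_vs_{pair.group_b}",
                dataset_id=design.dataset_id,
                oriented=pair.oriented,
                measures=tuple(measures),
            )
        )
    return records


def read_design(path: PathLike) -> list[ExperimentDesign]:
    """Read a design TSV (possibly spanning several datasets)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(DESIGN_COLUMNS):
        raise ValueError(f"{path}: expected header {list(DESIGN_COLUMNS)}, found {list(df.columns)}")
    designs = []
    for ds, chunk in df.groupby("dataset_id", sort=True):
        groups: dict[str, list[str]] = {}
        control: Optional[str] = None
        for row in chunk.itertuples(index=False):
            groups.setdefault(row.group, []).append(row.sample_id)
            if row.is_control == "1":
                if control is not None and control != row.group:
                    raise ValueError(f"{path}: dataset {ds!r} has more than one control group")
                control = row.group
            elif row.is_control != "0":
                raise ValueError(f"{path}: is_control must be 0 or 1, got {row.is_control!r}")
        designs.append(
            ExperimentDesign(str(ds), {g: tuple(s) for g, s in groups.items()}, control)
        )
    return designs


def read_selection(path: PathLike) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(SELECTION_COLUMNS):
        raise ValueError(f"{path}: expected header {list(SELECTION_COLUMNS)}, found {list(df.columns)}")
    return [tuple(row) for row in df.itertuples(index=False)]
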