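"""Synthetic comparison stores and raw experiments with known ground truth.

The generator emulates the empirical structure of a heterogeneous corpus of
curated expression comparisons: genes are measured in only a fraction of the
comparisons (platform heterogeneity -> missingness), a present gene is
spuriously modulated at a low background rate, and *planted modules* of
genes co-modulate with a designated driver gene, optionally sharing its
direction. Most comparisons are oriented (have a control group); a minority
are not.

Modulation is simulated at the flag level first and realized as
``(lfc, adj_p)`` pairs second, so the mining engine's canonical thresholds
(``|lfc| >= 1``, ``adj_p <= 0.05``) recover the planted flags exactly:
realized values for non-modulated genes stay strictly inside the
non-qualifying region. This makes the ground truth unambiguous -- a planted
flag is never blurred by realization noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .preprocess import ExperimentDesign, IntensityMatrix
from .store import ComparisonRecord, ProbeGeneMap, ProbeMeasure

__all__ = [
    "CANONICAL_LFC_MIN",
    "CANONICAL_ADJ_P_MAX",
    "PlantedModule",
    "SyntheticSpec",
    "generate_store",
    "generate_experiment",
    "write_truth",
    "TRUTH_COLUMNS",
]

#: the canonical thresholds the realized values are guaranteed to respect
CANONICAL_LFC_MIN = 1.0
CANONICAL_ADJ_P_MAX = 0.05

#: probability that a non-present gene is still measured (non-significantly)
_MEASURED_WHEN_NOT_PRESENT = 0.5

TRUTH_COLUMNS = ("gene_symbol", "planted", "module_id", "concordant_sign")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PlantedModule:
    """A set of genes co-modulated with a designated driver gene.

    Whenever the driver is present and modulated in a comparison, each
    present member modulates with probability ``co_modulation_prob`` and
    shares the driver's direction with probability ``sign_concordance``.
    Members are coupled strictly to the driver: they do not modulate at the
    background rate on their own. The driver itself modulates (when present)
    at ``driver_modulation_rate`` -- the default 0.4 models an actively
    responsive gene, modulated in a substantial minority of the comparisons
    where it is reliably measured.
    """

    driver: str
    members: tuple[str, ...]
    co_modulation_prob: float = 0.9
    sign_concordance: float = 1.0
    driver_modulation_rate: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("a planted module needs at least one member")
        if self.driver in self.members:
            raise ValueError("the driver is not a member of its own module")
        if len(set(self.members)) != len(self.members):
            raise ValueError("module members must be unique")
        for name in ("co_modulation_prob", "sign_concordance", "driver_modulation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic comparison store.

    ``probes_per_gene`` is a (mean, dispersion) pair for a gamma-Poisson
    count of probes per gene (minimum 1); dispersion 0 gives every gene the
    same rounded count. Gene symbols are ``G0000 .. G{n_genes-1:04d}``;
    planted modules must reference symbols from that universe. The seed
    fixes the full output.
    """

    n_comparisons: int = 200
    n_genes: int = 500
    probes_per_gene: tuple[float, float] = (2.0, 0.5)
    presence_rate: float = 0.7
    null_modulation_rate: float = 0.1
    planted_modules: tuple[PlantedModule, ...] = ()
    oriented_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_modules", tuple(self.planted_modules))
        if self.n_comparisons < 1 or self.n_genes < 1:
            raise ValueError("n_comparisons and n_genes must be positive")
        mean, disp = self.probes_per_gene
        if mean < 1 or disp < 0:
            raise ValueError("probes_per_gene mean must be >= 1 and dispersion >= 0")
        for name in ("presence_rate", "null_modulation_rate", "oriented_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    @property
    def gene_symbols(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _probe_counts(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    mean, disp = spec.probes_per_gene
    if disp == 0:
        return np.full(spec.n_genes, max(1, round(mean)), dtype=int)
    extra = mean - 1.0
    if extra <= 0:
        return np.ones(spec.n_genes, dtype=int)
    lam = rng.gamma(shape=1.0 / disp, scale=extra * disp, size=spec.n_genes)
    return 1 + rng.poisson(lam)


def generate_store(
    spec: SyntheticSpec,
) -> tuple[list[ComparisonRecord], ProbeGeneMap, pd.DataFrame]:
    """Generate a comparison store with planted structure.

    Returns ``(records, probe_map, truth)`` where ``truth`` has one row per
    gene with columns ``gene_symbol, planted, module_id, concordant_sign``
    (drivers and members are planted; ``concordant_sign`` echoes the
    module's sign concordance). Identical specs produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_symbols
    gene_index = {g: i for i, g in enumerate(genes)}
    for module in spec.planted_modules:
        unknown = [g for g in (module.driver, *module.members) if g not in gene_index]
        if unknown:
            raise ValueError(f"module genes not in the gene universe: {unknown}")
    claimed: set[str] = set()
    for module in spec.planted_modules:
        overlap = claimed.intersection((module.driver, *module.members))
        if overlap:
            raise ValueError(f"genes claimed by more than one module: {sorted(overlap)}")
        claimed.update((module.driver, *module.members))

    n_c, n_g = spec.n_comparisons, spec.n_genes
    oriented = rng.random(n_c) < spec.oriented_fraction
    present = rng.random((n_c, n_g)) < spec.presence_rate
    modulated = present & (rng.random((n_c, n_g)) < spec.null_modulation_rate)
    sign = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_c, n_g))

    for module in spec.planted_modules:
        di = gene_index[module.driver]
        modulated[:, di] = present[:, di] & (rng.random(n_c) < module.driver_modulation_rate)
        driver_sign = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_c)
        sign[:, di] = driver_sign
        driver_on = present[:, di] & modulated[:, di]
        for member in module.members:
            mi = gene_index[member]
            coupled = present[:, mi] & driver_on
            modulated[:, mi] = coupled & (rng.random(n_c) < module.co_modulation_prob)
            concordant = rng.random(n_c) < module.sign_concordance
            sign[:, mi] = np.where(concordant, driver_sign, -driver_sign)

    # platform heterogeneity: non-present genes are sometimes measured
    # (non-significantly) and sometimes absent from the comparison entirely
    measured = present | (~present & (rng.random((n_c, n_g)) < _MEASURED_WHEN_NOT_PRESENT))

    n_probes = _probe_counts(spec, rng)
    probe_names = [[f"{g}_p{j + 1}" for j in range(n_probes[i])] for i, g in enumerate(genes)]
    probe_map = ProbeGeneMap(
        {p: g for i, g in enumerate(genes) for p in probe_names[i]}
    )

    ci_all, gi_all = np.nonzero(measured)
    n_cells = ci_all.size
    is_present = present[ci_all, gi_all]
    is_mod = modulated[ci_all, gi_all]
    cell_sign = sign[ci_all, gi_all].astype(float)

    # primary-probe realization, kept strictly inside/outside the
    # qualifying region so the canonical thresholds recover the flags
    lfc = rng.uniform(-0.9, 0.9, n_cells)
    lfc[is_mod] = cell_sign[is_mod] * (CANONICAL_LFC_MIN + rng.exponential(0.5, int(is_mod.sum())))
    adj_p = np.where(
        is_present,
        rng.uniform(1e-6, CANONICAL_ADJ_P_MAX, n_cells),
        rng.uniform(CANONICAL_ADJ_P_MAX + 1e-3, 1.0, n_cells),
    )
    p_value = adj_p * rng.uniform(0.05, 1.0, n_cells)

    extra_counts = n_probes[gi_all] - 1
    n_extra = int(extra_counts.sum())
    extra_lfc = rng.normal(0.0, 0.3, n_extra)
    extra_adj = rng.uniform(CANONICAL_ADJ_P_MAX + 1e-3, 1.0, n_extra)

    records: list[ComparisonRecord] = []
    pos = 0
    extra_pos = 0
    for ci in range(n_c):
        measures: list[ProbeMeasure] = []
        while pos < n_cells and ci_all[pos] == ci:
            gi = gi_all[pos]
            names = probe_names[gi]
            measures.append(
                ProbeMeasure(names[0], float(lfc[pos]), float(p_value[pos]), float(adj_p[pos]))
            )
            for j in range(1, len(names)):
                measures.append(
                    ProbeMeasure(
                        names[j],
                        float(extra_lfc[extra_pos]),
                        float(extra_adj[extra_pos] * 0.9),
                        float(extra_adj[extra_pos]),
                    )
                )
                extra_pos += 1
            pos += 1
        if measures:
            records.append(
                ComparisonRecord(
                    comparison_id=f"C{ci:04d}",
                    dataset_id=f"DS{ci // 5:03d}",
                    oriented=bool(oriented[ci]),
                    measures=tuple(measures),
                )
            )

    planted = np.zeros(n_g, dtype=int)
    module_id = np.full(n_g, "", dtype=object)
    concordant = np.full(n_g, np.nan)
    for k, module in enumerate(spec.planted_modules):
        for g in (module.driver, *module.members):
            i = gene_index[g]
            planted[i] = 1
            module_id[i] = f"M{k}"
            concordant[i] = module.sign_concordance
    truth = pd.DataFrame(
        {
            "gene_symbol": genes,
            "planted": planted,
            "module_id": module_id,
            "concordant_sign": concordant,
        }
    )
    return records, probe_map, truth


def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def generate_experiment(
    group_sizes: Mapping[str, int],
    n_probes: int = 100,
    shifts: Optional[Mapping[str, Mapping[str, float]]] = None,
    sigma: float = 0.3,
    control_group: Optional[str] = None,
    dataset_id: str = "SIM",
    seed: int = 0,
) -> tuple[IntensityMatrix, ExperimentDesign]:
    """Generate a raw log2 intensity experiment with planted group shifts.

    Each probe gets a baseline drawn uniformly in [4, 12]; a sample's value
    is baseline + the planted shift of its group (``shifts[group][probe]``,
    default 0) + Gaussian noise of standard deviation ``sigma``. Probe ids
    are ``P0000 ..``; samples are named ``{group}_s{i}``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    if len(group_sizes) < 2:
        raise ValueError("at least two groups are required")
    for label, size in group_sizes.items():
        if size < 2:
            raise ValueError(f"group {label!r} needs at least two samples, got {size}")
    if control_group is not None and control_group not in group_sizes:
        raise ValueError(f"control group {control_group!r} not among groups")

    rng = np.random.default_rng(seed)
    probes = [f"P{i:04d}" for i in range(n_probes)]
    baseline = rng.uniform(4.0, 12.0, n_probes)
    shifts = shifts or {}
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, tuple[str, ...]] = {}
    for label in sorted(group_sizes):
        delta = np.zeros(n_probes)
        for probe, value in shifts.get(label, {}).items():
            delta[probes.index(probe)] = value
        names = tuple(f"{label}_s{i + 1}" for i in range(group_sizes[label]))
        groups[label] = names
        for name in names:
            columns[name] = baseline + delta + rng.normal(0.0, sigma, n_probes)
    matrix = IntensityMatrix(pd.DataFrame(columns, index=probes))
    design = ExperimentDesign(dataset_id, groups, control_group)
    return matrix, design
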