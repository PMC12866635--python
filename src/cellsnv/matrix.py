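"""The cells x SNVs layered count matrix and per-entry allelic calls.

The central data model keeps three aligned layers: variant read counts,
reference read counts, and an *observed* boolean marking (cell, SNV) pairs
for which any read covered the locus.  This preserves the three-way
distinction at the heart of expressed-SNV analysis: a locus with reads but
no variant allele (negative signal, VAF_RNA = 0) is not the same as a locus
with no reads at all (no signal, VAF_RNA undefined).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SNVKey, SNVTable

logger = logging.getLogger(__name__)


class AllelicState(enum.Enum):
    """Per-(cell, SNV) category determined purely by the two read counts."""

    NO_COVERAGE = "no_coverage"
    REF_ONLY = "ref_only"
    VAR_ONLY = "var_only"
    BIALLELIC = "biallelic"


def vaf(n_var: int, n_ref: int) -> float:
    """Expressed variant allele fraction N_VAR / (N_VAR + N_REF).

    Returns NaN when both counts are zero: an uncovered locus has no VAF,
    which is distinct from a covered locus where the variant is absent
    (VAF = 0).
    """
    if n_var < 0 or n_ref < 0:
        raise ValueError("read counts must be nonnegative")
    total = n_var + n_ref
    if total == 0:
        return float("nan")
    return n_var / total


def classify_allelic_state(n_var: int, n_ref: int) -> AllelicState:
    """Map read counts to the four-way allelic state."""
    if n_var < 0 or n_ref < 0:
        raise ValueError("read counts must be nonnegative")
    if n_var == 0 and n_ref == 0:
        return AllelicState.NO_COVERAGE
    if n_var == 0:
        return AllelicState.REF_ONLY
    if n_ref == 0:
        return AllelicState.VAR_ONLY
    return AllelicState.BIALLELIC


@dataclass
class CellSNVMatrix:
    """Cells x SNVs matrix with variant-count, reference-count and observed layers.

    Unobserved entries hold structural zeros in both count layers; the
    boolean layer is the single source of truth for coverage.
    """

    cells: list[str]
    snvs: list[SNVKey]
    var_counts: np.ndarray  # (n_cells, n_snvs) int64
    ref_counts: np.ndarray
    observed: np.ndarray  # bool

    def __post_init__(self) -> None:
        shape = (len(self.cells), len(self.snvs))
        for name in ("var_counts", "ref_counts", "observed"):
            layer = getattr(self, name)
            if layer.shape != shape:
                raise ValueError(f"layer {name} has shape {layer.shape}, expected {shape}")
        depth = self.var_counts + self.ref_counts
        if not np.array_equal(self.observed, depth >= 1):
            raise ValueError("observed layer inconsistent with count layers")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.cells), len(self.snvs)

    @property
    def depth(self) -> np.ndarray:
        return self.var_counts + self.ref_counts

    def vaf_matrix(self) -> np.ndarray:
        """Per-entry VAF_RNA; NaN where unobserved."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.var_counts / self.depth
        v[~self.observed] = np.nan
        return v

    def snv_index(self, snv: SNVKey) -> int:
        try:
            return self._index[snv]
        except AttributeError:
            self._index = {s: j for j, s in enumerate(self.snvs)}
            return self.snv_index(snv)

    def subset_snvs(self, keep: np.ndarray) -> "CellSNVMatrix":
        keep = np.asarray(keep)
        return CellSNVMatrix(
            cells=list(self.cells),
            snvs=[s for s, k in zip(self.snvs, keep) if k] if keep.dtype == bool else [self.snvs[j] for j in keep],
            var_counts=self.var_counts[:, keep].copy(),
            ref_counts=self.ref_counts[:, keep].copy(),
            observed=self.observed[:, keep].copy(),
        )


def build_matrix(table: SNVTable, cell_universe: Sequence[str]) -> CellSNVMatrix:
    """Lay out an SNVTable over a fixed cell universe.

    Records whose barcode falls outside the universe are dropped and logged.
    The matrix covers every cell of the universe (rows of structural zeros
    for cells without records) and every distinct SNV of the table.
    """
    cells = list(dict.fromkeys(cell_universe))
    cell_idx = {bc: i for i, bc in enumerate(cells)}
    snvs = table.snvs
    snv_idx = {s: j for j, s in enumerate(snvs)}
    n_dropped = 0
    var_counts = np.zeros((len(cells), len(snvs)), dtype=np.int64)
    ref_counts = np.zeros_like(var_counts)
    for rec in table.records:
        i = cell_idx.get(rec.barcode)
        if i is None:
            n_dropped += 1
            continue
        j = snv_idx[rec.snv]
        var_counts[i, j] = rec.n_var
        ref_counts[i, j] = rec.n_ref
    if n_dropped:
        logger.info("build_matrix: dropped %d records outside the cell universe", n_dropped)
    observed = (var_counts + ref_counts) >= 1
    if not observed.any():
        raise ValueError("no records remain after restricting to the cell universe")
    return CellSNVMatrix(cells, list(snvs), var_counts, ref_counts, observed)


@dataclass(frozen=True)
class FilterSpec:
    """SNV-level quality filters.

    The per-entry depth filter runs first (entries with fewer than
    ``min_depth`` total reads become unobserved), then SNVs observed in
    fewer than ``min_cells_per_snv`` cells are dropped.  Cells are never
    removed.
    """

    min_cells_per_snv: int = 0
    min_depth: int = 0

    def __post_init__(self) -> None:
        if self.min_cells_per_snv < 0 or self.min_depth < 0:
            raise ValueError("filter thresholds must be nonnegative")


@dataclass
class FilterReport:
    n_entries_removed_by_depth: int = 0
    n_snvs_removed_by_cell_count: int = 0
    removed_snvs: list[SNVKey] = field(default_factory=list)


def apply_filters(m: CellSNVMatrix, f: FilterSpec) -> tuple[CellSNVMatrix, FilterReport]:
    """Apply depth then cell-support filters; monotone and idempotent."""
    report = FilterReport()
    var_counts = m.var_counts.copy()
    ref_counts = m.ref_counts.copy()
    depth = var_counts + ref_counts
    shallow = m.observed & (depth < f.min_depth)
    report.n_entries_removed_by_depth = int(shallow.sum())
    var_counts[shallow] = 0
    ref_counts[shallow] = 0
    observed = (var_counts + ref_counts) >= 1
    support = observed.sum(axis=0)
    keep = support >= f.min_cells_per_snv
    report.n_snvs_removed_by_cell_count = int((~keep).sum())
    report.removed_snvs = [s for s, k in zip(m.snvs, keep) if not k]
    out = CellSNVMatrix(
        cells=list(m.cells),
        snvs=[s for s, k in zip(m.snvs, keep) if k],
        var_counts=var_counts[:, keep],
        ref_counts=ref_counts[:, keep],
        observed=observed[:, keep],
    )
    if not out.snvs:
        logger.warning("apply_filters removed every SNV")
    return out, report


@dataclass
class SNVProfile:
    """Cross-cell summary of one SNV used for origin inference and reporting."""

    snv: SNVKey
    n_cells_covered: int
    n_ref_only: int
    n_var_only: int
    n_biallelic: int
    vaf_values: np.ndarray  # per covered cell, in cell order
    median_vaf_covered: float  # NaN if no covered cell
    median_nvar_expressing: float  # median N_VAR over cells with n_var >= 1; NaN if none

    @property
    def mean_vaf_covered(self) -> float:
        return float(np.mean(self.vaf_values)) if self.n_cells_covered else float("nan")

    @property
    def n_carriers(self) -> int:
        """Cells expressing the variant allele (var_only or biallelic)."""
        return self.n_var_only + self.n_biallelic

    @property
    def median_vaf_carriers(self) -> float:
        carriers = self.vaf_values[self.vaf_values > 0]
        return float(np.median(carriers)) if carriers.size else float("nan")


def per_snv_profile(m: CellSNVMatrix, snv: SNVKey) -> SNVProfile:
    """Tally allelic states and VAFs for one SNV column."""
    try:
        j = m.snv_index(snv)
    except KeyError:
        raise KeyError(f"SNV {snv} not present in matrix") from None
    nv = m.var_counts[:, j]
    nr = m.ref_counts[:, j]
    covered = m.observed[:, j]
    with np.errstate(invalid="ignore"):
        vafs = nv[covered] / (nv[covered] + nr[covered])
    expressing = nv[covered & (nv >= 1)]
    return SNVProfile(
        snv=snv,
        n_cells_covered=int(covered.sum()),
        n_ref_only=int((covered & (nv == 0)).sum()),
        n_var_only=int((covered & (nr == 0) & (nv >= 1)).sum()),
        n_biallelic=int((covered & (nv >= 1) & (nr >= 1)).sum()),
        vaf_values=vafs,
        median_vaf_covered=float(np.median(vafs)) if vafs.size else float("nan"),
        median_nvar_expressing=float(np.median(expressing)) if expressing.size else float("nan"),
    )


def all_profiles(m: CellSNVMatrix) -> list[SNVProfile]:
    return [per_snv_profile(m, s) for s in m.snvs]
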