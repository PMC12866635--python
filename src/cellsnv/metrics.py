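"""Per-cell set-level metrics over a selection of SNVs, and group summaries.

For a cell and a selected SNV set the module reports:

* ``n_snvs`` — number of selected loci where the variant allele is seen
  (N_VAR >= 1); ref-only loci are covered but count as negative signal,
* ``total_nvar`` / ``total_nref`` — summed read counts,
* ``total_vaf`` — pooled VAF_RNA, sum(N_VAR) / sum(N_VAR + N_REF) over the
  covered selected loci,
* ``mean_vaf`` / ``median_vaf`` — per-locus VAF_RNA averaged/median over
  covered loci, VAF = 0 loci included.

Ratio metrics are NaN for cells covering none of the selected loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SNVKey
from .matrix import CellSNVMatrix

#: Metrics whose natural scale is the unit interval (histograms use fixed [0, 1] edges).
VAF_METRICS = ("total_vaf", "mean_vaf", "median_vaf")
COUNT_METRICS = ("n_snvs", "total_nvar", "total_nref")
ALL_METRICS = COUNT_METRICS + VAF_METRICS


def compute_cell_metrics(m: CellSNVMatrix, selection: Sequence[SNVKey] | None = None) -> pd.DataFrame:
    """Per-cell metrics over ``selection`` (default: every SNV in the matrix).

    Returns one row per cell of the matrix, in matrix cell order; ratio
    columns are NaN where the cell covers no selected locus.
    """
    if selection is None:
        selection = m.snvs
    selection = list(selection)
    if not selection:
        raise ValueError("selection of SNVs must be nonempty")
    cols = np.array([m.snv_index(s) for s in selection])
    nv = m.var_counts[:, cols]
    nr = m.ref_counts[:, cols]
    obs = m.observed[:, cols]

    total_nvar = nv.sum(axis=1)
    total_nref = nr.sum(axis=1)
    n_covered = obs.sum(axis=1)
    depth_total = total_nvar + total_nref
    with np.errstate(invalid="ignore", divide="ignore"):
        total_vaf = np.where(depth_total > 0, total_nvar / np.maximum(depth_total, 1), np.nan)
        per_locus_vaf = np.where(obs, nv / np.maximum(nv + nr, 1), np.nan)
    mean_vaf = np.full(len(m.cells), np.nan)
    median_vaf = np.full(len(m.cells), np.nan)
    any_cov = n_covered > 0
    if any_cov.any():
        mean_vaf[any_cov] = np.nanmean(per_locus_vaf[any_cov], axis=1)
        median_vaf[any_cov] = np.nanmedian(per_locus_vaf[any_cov], axis=1)
    return pd.DataFrame(
        {
            "barcode": m.cells,
            "n_snvs": (nv >= 1).sum(axis=1).astype(np.int64),
            "total_nvar": total_nvar.astype(np.int64),
            "total_nref": total_nref.astype(np.int64),
            "total_vaf": total_vaf,
            "mean_vaf": mean_vaf,
            "median_vaf": median_vaf,
        }
    )


def histogram_data(values: Sequence[float], bins: int, kind: str = "vaf") -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and counts for a metric histogram.

    VAF-type metrics use fixed edges over [0, 1] (final bin right-closed, the
    numpy convention); count metrics use integer-aligned edges from 0 to the
    next multiple of the bin width above the observed maximum.  NaN values
    are excluded, so counts sum to the number of defined values.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if kind == "vaf":
        edges = np.linspace(0.0, 1.0, bins + 1)
    else:
        vmax = vals.max() if vals.size else 0.0
        width = max(1, int(np.ceil((vmax + 1) / bins)))
        edges = np.arange(0, (bins + 1) * width, width, dtype=float)[: bins + 1]
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts


@dataclass
class ClusterMetricsSummary:
    """Distribution summary of every per-cell metric within one group of cells."""

    label: str
    n_cells: int
    stats: dict  # metric -> {n, mean, median, iqr}
    histograms: dict  # metric -> (edges, counts)


def summarize_by_group(
    metrics: pd.DataFrame,
    labels: Sequence,
    bins: int = 50,
) -> tuple[dict[str, ClusterMetricsSummary], int]:
    """Summarize per-cell metrics within each group label.

    ``labels`` aligns with the rows of ``metrics``; cells with a missing
    label (None/NaN) are excluded and counted in the second return value.
    Per-metric statistics are computed only over cells where the metric is
    defined.
    """
    labels = pd.Series(list(labels), index=metrics.index)
    unlabeled = labels.isna()
    n_unlabeled = int(unlabeled.sum())
    if n_unlabeled == len(labels):
        raise ValueError("every cell is unlabeled")
    out: dict[str, ClusterMetricsSummary] = {}
    for label, idx in metrics.index[~unlabeled].groupby(labels[~unlabeled]).items():
        sub = metrics.loc[idx]
        stats, hists = {}, {}
        for metric in ALL_METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            stats[metric] = {
                "n": int(defined.size),
                "mean": float(np.mean(defined)) if defined.size else float("nan"),
                "median": float(np.median(defined)) if defined.size else float("nan"),
                "iqr": float(np.subtract(*np.percentile(defined, [75, 25]))) if defined.size else float("nan"),
            }
            kind = "vaf" if metric in VAF_METRICS else "count"
            hists[metric] = histogram_data(vals, bins=bins, kind=kind)
        out[str(label)] = ClusterMetricsSummary(str(label), len(sub), stats, hists)
    return out, n_unlabeled
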