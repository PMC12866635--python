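"""Brute-force per-entry reimplementations used as independent oracles.

Everything here loops over cells and SNVs one entry at a time with scalar
arithmetic, deliberately sharing no code path with the vectorized package.
"""

import math
import statistics


def brute_cell_metrics(m, selection=None):
    selection = list(selection) if selection is not None else list(m.snvs)
    out = []
    for i, bc in enumerate(m.cells):
        vafs = []
        total_nvar = total_nref = n_snvs = 0
        for snv in selection:
            j = m.snvs.index(snv)
            nv, nr = int(m.var_counts[i, j]), int(m.ref_counts[i, j])
            total_nvar += nv
            total_nref += nr
            if nv >= 1:
                n_snvs += 1
            if nv + nr >= 1:
                vafs.append(nv / (nv + nr))
        row = {
            "barcode": bc,
            "n_snvs": n_snvs,
            "total_nvar": total_nvar,
            "total_nref": total_nref,
            "total_vaf": total_nvar / (total_nvar + total_nref) if total_nvar + total_nref else math.nan,
            "mean_vaf": statistics.fmean(vafs) if vafs else math.nan,
            "median_vaf": statistics.median(vafs) if vafs else math.nan,
        }
        out.append(row)
    return out


def brute_profile(m, snv):
    j = m.snvs.index(snv)
    n_ref_only = n_var_only = n_biallelic = 0
    vafs, expressing = [], []
    for i in range(len(m.cells)):
        nv, nr = int(m.var_counts[i, j]), int(m.ref_counts[i, j])
        if nv + nr == 0:
            continue
        vafs.append(nv / (nv + nr))
        if nv >= 1:
            expressing.append(nv)
        if nv == 0:
            n_ref_only += 1
        elif nr == 0:
            n_var_only += 1
        else:
            n_biallelic += 1
    return {
        "n_cells_covered": len(vafs),
        "n_ref_only": n_ref_only,
        "n_var_only": n_var_only,
        "n_biallelic": n_biallelic,
        "vaf_values": vafs,
        "median_vaf_covered": statistics.median(vafs) if vafs else math.nan,
        "median_nvar_expressing": statistics.median(expressing) if expressing else math.nan,
    }


def brute_filter(m, min_depth, min_cells_per_snv):
    """Return (kept SNV indices, per-entry observed after depth filter)."""
    n_cells, n_snvs = len(m.cells), len(m.snvs)
    observed = [[False] * n_snvs for _ in range(n_cells)]
    for i in range(n_cells):
        for j in range(n_snvs):
            depth = int(m.var_counts[i, j]) + int(m.ref_counts[i, j])
            observed[i][j] = depth >= max(min_depth, 1)
    kept = []
    for j in range(n_snvs):
        support = sum(observed[i][j] for i in range(n_cells))
        if support >= min_cells_per_snv:
            kept.append(j)
    return kept, observed
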