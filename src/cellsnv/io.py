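"""Readers and writers for per-cell SNV read-count tables and expression matrices.

Two tab-delimited SNV table dialects are supported:

* the SCReadCounts-style dialect with explicit ``CHROM``/``POS``/``REF``/
  ``ALT``/``ReadGroup``/``SNVCount``/``RefCount`` columns (header names are
  matched case-insensitively against the synonym lists below), and
* a simplified dialect with a single SNV-id column (``chrom:pos:ref>alt`` or
  ``chrom:pos_ref>alt``), a barcode column and the two read counts.

Gene expression is accepted as MatrixMarket triplets with ``features.tsv`` /
``barcodes.tsv`` sidecars (the CellRanger/STARsolo layout) or as a dense TSV
with genes in rows; either way raw nonnegative integer counts are required —
normalization happens downstream.  Positions are 1-based throughout.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Case-insensitive header synonyms for the SCReadCounts-style dialect.
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "chrom": ("chrom", "chr", "chromosome", "#chrom", "#chr"),
    "pos": ("pos", "position", "start", "snvpos"),
    "ref": ("ref", "reference", "ref_allele", "refallele"),
    "alt": ("alt", "alt_allele", "altallele", "variant", "var"),
    "barcode": ("barcode", "readgroup", "read_group", "cb", "cell_barcode", "cellbarcode"),
    "n_var": ("snvcount", "n_var", "nvar", "varcount", "var_count", "variant_count", "variantcount"),
    "n_ref": ("refcount", "n_ref", "nref", "ref_count", "reference_count", "referencecount"),
}


class FormatError(ValueError):
    """A file does not conform to the declared dialect or format."""


class RowError(ValueError):
    """A single data row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True, order=True)
class SNVKey:
    """One genomic variant locus: chromosome, 1-based position, ref/alt alleles.

    Canonical string form is ``"chrom:pos:ref>alt"`` (e.g. ``17:48895725:C>T``);
    the underscore dialect ``"chrom:pos_ref>alt"`` parses to the same key.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"alleles must be single uppercase A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    _PATTERN = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)[:_](?P<ref>[A-Za-z])\s*>\s*(?P<alt>[A-Za-z])$")

    @classmethod
    def parse(cls, text: str) -> "SNVKey":
        """Parse ``chrom:pos:ref>alt`` or ``chrom:pos_ref>alt`` into an SNVKey."""
        m = cls._PATTERN.match(text.strip())
        if m is None:
            raise ValueError(f"unparseable SNV id: {text!r}")
        return cls(m["chrom"], int(m["pos"]), m["ref"].upper(), m["alt"].upper())


@dataclass(frozen=True)
class CellSNVRecord:
    """Variant and reference read counts for one SNV in one cell barcode."""

    snv: SNVKey
    barcode: str
    n_var: int
    n_ref: int

    def __post_init__(self) -> None:
        if self.n_var < 0 or self.n_ref < 0:
            raise ValueError(f"negative read count for {self.snv} / {self.barcode}")
        if not self.barcode:
            raise ValueError(f"empty barcode for {self.snv}")


@dataclass
class SNVTable:
    """An ordered collection of per-(cell, SNV) read-count records.

    ``n_dropped_zero`` counts input rows with ``n_var + n_ref == 0`` ("no read
    counts" loci) that were discarded on load.
    """

    records: list[CellSNVRecord]
    sample_id: str = ""
    provenance: str = ""
    n_dropped_zero: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        # order-insensitive: a table is a set of records
        if not isinstance(other, SNVTable):
            return NotImplemented
        return set(self.records) == set(other.records)

    @property
    def snvs(self) -> list[SNVKey]:
        """Distinct SNV keys in first-appearance order."""
        return list(dict.fromkeys(r.snv for r in self.records))

    @property
    def barcodes(self) -> list[str]:
        """Distinct barcodes in first-appearance order."""
        return list(dict.fromkeys(r.barcode for r in self.records))


def _resolve_columns(header: Sequence[str], required: Iterable[str]) -> dict[str, str]:
    lower = {h.strip().lower(): h for h in header}
    resolved = {}
    for canon in required:
        for syn in COLUMN_SYNONYMS[canon]:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
        else:
            raise FormatError(
                f"missing required column {canon!r} (accepted names: "
                f"{', '.join(COLUMN_SYNONYMS[canon])}); header was {list(header)}"
            )
    return resolved


def _finalize_records(
    rows: list[CellSNVRecord],
    n_zero: int,
    path: str,
    dialect: str,
    sample_id: str,
    dedup_policy: str,
) -> SNVTable:
    seen: dict[tuple[SNVKey, str], int] = {}
    out: list[CellSNVRecord] = []
    for rec in rows:
        key = (rec.snv, rec.barcode)
        if key in seen:
            if dedup_policy == "error":
                raise FormatError(
                    f"duplicate (snv, barcode) pair ({rec.snv}, {rec.barcode}) in {path}; "
                    "pass dedup_policy='sum' to aggregate"
                )
            prev = out[seen[key]]
            out[seen[key]] = CellSNVRecord(rec.snv, rec.barcode, prev.n_var + rec.n_var, prev.n_ref + rec.n_ref)
        else:
            seen[key] = len(out)
            out.append(rec)
    if n_zero:
        logger.info("%s: dropped %d rows with no read counts", path, n_zero)
    return SNVTable(out, sample_id=sample_id, provenance=f"{path} ({dialect})", n_dropped_zero=n_zero)


def read_screadcounts(
    path: str | os.PathLike,
    dedup_policy: Literal["error", "sum"] = "error",
    sample_id: str = "",
) -> SNVTable:
    """Read an SCReadCounts-style tab-delimited per-cell SNV count table.

    Rows whose variant and reference counts are both zero are dropped and
    tallied in :attr:`SNVTable.n_dropped_zero`; extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, COLUMN_SYNONYMS)
    rows: list[CellSNVRecord] = []
    n_zero = 0
    sub = df[[cols[c] for c in ("chrom", "pos", "ref", "alt", "barcode", "n_var", "n_ref")]].to_numpy(dtype=object)
    for i, (chrom, pos, ref, alt, barcode, n_var, n_ref) in enumerate(sub, start=2):  # line 1 is the header
        try:
            pos, n_var, n_ref = int(pos), int(n_var), int(n_ref)
        except (TypeError, ValueError):
            raise RowError(f"non-integer field in ({pos!r}, {n_var!r}, {n_ref!r})", line=i) from None
        if n_var + n_ref == 0:
            n_zero += 1
            continue
        try:
            snv = SNVKey(str(chrom), pos, str(ref).upper(), str(alt).upper())
            rows.append(CellSNVRecord(snv, str(barcode), n_var, n_ref))
        except ValueError as exc:
            raise RowError(str(exc), line=i) from None
    return _finalize_records(rows, n_zero, str(path), "screadcounts", sample_id, dedup_policy)


def read_simple_table(
    path: str | os.PathLike,
    dedup_policy: Literal["error", "sum"] = "error",
    sample_id: str = "",
) -> SNVTable:
    """Read the simplified dialect: SNV-id, barcode, N_VAR, N_REF columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 4:
        raise FormatError(f"simplified dialect needs 4 columns (snv-id, barcode, n_var, n_ref), found {df.shape[1]}")
    rows: list[CellSNVRecord] = []
    n_zero = 0
    for i, (snv_id, barcode, var_s, ref_s) in enumerate(df.iloc[:, :4].to_numpy(dtype=object), start=2):
        try:
            n_var, n_ref = int(var_s), int(ref_s)
        except (TypeError, ValueError):
            raise RowError(f"non-integer count in ({var_s!r}, {ref_s!r})", line=i) from None
        if n_var + n_ref == 0:
            n_zero += 1
            continue
        try:
            snv = SNVKey.parse(str(snv_id))
            rows.append(CellSNVRecord(snv, str(barcode), n_var, n_ref))
        except ValueError as exc:
            raise RowError(str(exc), line=i) from None
    return _finalize_records(rows, n_zero, str(path), "simple", sample_id, dedup_policy)


def write_simple_table(table: SNVTable, path: str | os.PathLike) -> None:
    """Write a table in the simplified dialect; read_simple_table round-trips it."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("SNV\tBarcode\tN_VAR\tN_REF\n")
        for r in table.records:
            fh.write(f"{r.snv}\t{r.barcode}\t{r.n_var}\t{r.n_ref}\n")


def read_expression_matrix(
    dir_or_path: str | os.PathLike,
    format: Literal["mtx_triplet", "dense_tsv"] = "mtx_triplet",
) -> ad.AnnData:
    """Load raw gene counts as an AnnData (cells x genes, barcode order preserved).

    ``mtx_triplet`` expects a directory with ``matrix.mtx`` (genes x cells
    coordinate format) plus ``features.tsv`` and ``barcodes.tsv`` sidecars;
    ``dense_tsv`` expects genes in rows with barcodes in the header.
    """
    p = Path(dir_or_path)
    if format == "mtx_triplet":
        mtx = scipy.io.mmread(p / "matrix.mtx").tocsr()
        features = pd.read_csv(p / "features.tsv", sep="\t", header=None, dtype=str)
        barcodes = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None, dtype=str)
        n_genes, n_cells = mtx.shape
        if len(features) != n_genes or len(barcodes) != n_cells:
            raise FormatError(
                f"matrix is {n_genes} x {n_cells} but sidecars list "
                f"{len(features)} features and {len(barcodes)} barcodes"
            )
        X = mtx.T.tocsr()
        gene_ids = features.iloc[:, 0].tolist()
        cell_ids = barcodes.iloc[:, 0].tolist()
    elif format == "dense_tsv":
        df = pd.read_csv(p, sep="\t", index_col=0)
        X = sp.csr_matrix(df.to_numpy().T)
        gene_ids = df.index.astype(str).tolist()
        cell_ids = df.columns.astype(str).tolist()
    else:
        raise ValueError(f"unknown format {format!r}")
    if X.nnz and X.data.min() < 0:
        raise FormatError("expression counts must be nonnegative")
    data = np.asarray(X.data)
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError("expression values must be raw integer counts")
    if X.nnz == 0:
        logger.warning("%s: expression matrix is all zeros", dir_or_path)
    adata = ad.AnnData(
        X=X.astype(np.int64).astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )
    return adata


def _strip_suffix(barcodes: Iterable[str]) -> dict[str, str]:
    pat = re.compile(r"-\d+$")
    return {bc: pat.sub("", bc) for bc in barcodes}


@dataclass
class BarcodeMatch:
    """Result of harmonizing SNV-table and expression barcodes."""

    matched: list[str]  # in SNV-table naming
    expr_name_of: dict[str, str] = field(default_factory=dict)  # snv name -> expression name
    n_unmatched_snv: int = 0
    n_unmatched_expr: int = 0
    suffix_stripped: str = "none"  # which side had "-<digit>" stripped


def harmonize_barcodes(
    snv_table: SNVTable,
    expr_barcodes: Sequence[str],
    suffix_policy: Literal["keep", "strip", "auto"] = "auto",
) -> BarcodeMatch:
    """Match SNV-table barcodes to expression barcodes, tolerating "-1" suffixes.

    ``auto`` first tries the raw intersection; if empty, it strips a trailing
    ``-<digits>`` from whichever side carries it and retries.  A warning is
    emitted when the overlap covers less than half of either side.
    """
    snv_bcs = list(dict.fromkeys(r.barcode for r in snv_table.records))
    expr_bcs = list(dict.fromkeys(expr_barcodes))
    if not snv_bcs or not expr_bcs:
        raise ValueError("both barcode sets must be nonempty")

    def _match(snv_map: dict[str, str], expr_map: dict[str, str]) -> BarcodeMatch:
        expr_by_norm: dict[str, str] = {}
        for bc, norm in expr_map.items():
            expr_by_norm.setdefault(norm, bc)
        matched, name_of = [], {}
        for bc, norm in snv_map.items():
            if norm in expr_by_norm:
                matched.append(bc)
                name_of[bc] = expr_by_norm[norm]
        return BarcodeMatch(
            matched,
            name_of,
            n_unmatched_snv=len(snv_map) - len(matched),
            n_unmatched_expr=len(expr_map) - len(matched),
        )

    identity_snv = {bc: bc for bc in snv_bcs}
    identity_expr = {bc: bc for bc in expr_bcs}
    if suffix_policy == "strip":
        result = _match(_strip_suffix(snv_bcs), _strip_suffix(expr_bcs))
        result.suffix_stripped = "both"
    else:
        result = _match(identity_snv, identity_expr)
        if suffix_policy == "auto" and not result.matched:
            result = _match(_strip_suffix(snv_bcs), _strip_suffix(expr_bcs))
            result.suffix_stripped = "both"
    if not result.matched:
        raise ValueError(
            "no barcodes shared between SNV table and expression matrix even after "
            "suffix stripping; harmonize manually (suffix_policy='keep'/'strip')"
        )
    frac = len(result.matched) / min(len(snv_bcs), len(expr_bcs))
    if frac < 0.5:
        logger.warning("barcode overlap covers only %.0f%% of the smaller side", 100 * frac)
    return result


METRIC_COLUMNS = ["barcode", "n_snvs", "total_nvar", "total_nref", "total_vaf", "mean_vaf", "median_vaf"]


def write_metrics_table(metrics: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-cell metrics as TSV; undefined ratios serialize as empty fields."""
    df = metrics.loc[:, METRIC_COLUMNS].copy()
    for c in ("n_snvs", "total_nvar", "total_nref"):
        df[c] = df[c].astype(np.int64)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_metrics_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a per-cell metrics TSV written by :func:`write_metrics_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    for c in ("n_snvs", "total_nvar", "total_nref"):
        df[c] = df[c].astype(np.int64)
    return df
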