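"""Synthetic scRNA-seq expression matrices and SNV tables with planted truth.

The generator emits the two inputs the toolkit consumes — a genes x cells
raw count matrix and a per-(cell, SNV) read-count table — with a known
per-SNV origin class and per-cell expression group, so every downstream
recovery claim can be scored against ground truth.

Generative model
----------------
Cells carry a log-normal library-size factor (mean 1).  Gene counts are
gamma-Poisson (negative binomial) around log-normal baseline means; each
expression group elevates its own disjoint block of marker genes by a fixed
fold change, emulating distinct cell types.  SNV locus read depth per cell
is Poisson(lambda * size factor), independent of the gene matrix apart from
the shared size factors.  Given depth D >= 1, the variant read count follows
the planted class:

* ``het``       — Binomial(D, 0.5): balanced biallelic expression
* ``hom``       — D: every read carries the variant
* ``somatic``   — Binomial(D, 0.5) inside a subclone of cell fraction f, 0 elsewhere
* ``rna``       — Binomial(D, e): per-read conversion at low rate e in all cells
* ``bursting``  — per cell a fair coin picks one allele; all reads from it

Cells with D = 0 are omitted from the table, creating genuine "no read
counts" loci.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .io import SNVKey, CellSNVRecord, SNVTable

SNV_CLASSES = ("het", "hom", "somatic", "rna", "bursting")


@dataclass
class SimConfig:
    """Parameters of the synthetic world; defaults are the stated benchmark."""

    n_cells: int = 300
    n_genes: int = 500
    n_expression_groups: int = 3
    n_marker_genes: int = 60  #: marker genes per group (disjoint blocks)
    marker_fold: float = 4.0  #: fold elevation of a group's markers
    libsize_sigma: float = 0.35  #: log-normal sd of the cell size factor (mean 1)
    nb_dispersion: float = 10.0  #: gamma-Poisson shape; larger = closer to Poisson
    coverage_lambda: float = 5.0  #: per-cell mean reads over an SNV locus
    snvs_per_class: dict = field(default_factory=lambda: {c: 50 for c in SNV_CLASSES})
    somatic_fraction: float = 0.2  #: subclone cell fraction f
    rna_rate: float = 0.02  #: per-read conversion rate e
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("need at least one cell and one gene")
        if not 0 < self.somatic_fraction < 1:
            raise ValueError("somatic_fraction must lie in (0, 1)")
        if not 0 <= self.rna_rate < 0.5:
            raise ValueError("rna_rate must lie in [0, 0.5)")
        if any(n < 0 for n in self.snvs_per_class.values()):
            raise ValueError("per-class SNV counts must be nonnegative")
        if sum(self.snvs_per_class.values()) == 0:
            raise ValueError("at least one SNV must be planted")


@dataclass
class GroundTruth:
    """Planted labels: per-SNV class, per-cell group and subclone membership."""

    snv_class: pd.DataFrame  # columns: snv, true_class
    cell_truth: pd.DataFrame  # columns: barcode, expression_group, somatic_subclone


@dataclass
class SyntheticDataset:
    expression: sp.csr_matrix  # genes x cells raw counts
    gene_ids: list[str]
    barcodes: list[str]
    snv_table: SNVTable
    truth: GroundTruth
    config: SimConfig


_BARCODE_ALPHABET = np.array(list("ACGT"))


def _make_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(_BARCODE_ALPHABET, size=14)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset; byte-identical for identical configs."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    barcodes = _make_barcodes(cfg.n_cells, rng)
    size_factors = rng.lognormal(mean=-cfg.libsize_sigma**2 / 2, sigma=cfg.libsize_sigma, size=cfg.n_cells)

    # expression: gamma-Poisson around group-shifted log-normal baselines
    groups = rng.integers(0, cfg.n_expression_groups, size=cfg.n_cells)
    base_mean = rng.lognormal(mean=0.7, sigma=1.0, size=cfg.n_genes)
    n_marker = min(cfg.n_marker_genes, cfg.n_genes // max(cfg.n_expression_groups, 1))
    fold = np.ones((cfg.n_expression_groups, cfg.n_genes))
    for g in range(cfg.n_expression_groups):
        fold[g, g * n_marker : (g + 1) * n_marker] = cfg.marker_fold
    mean = base_mean[None, :] * fold[groups] * size_factors[:, None]  # cells x genes
    lam = rng.gamma(shape=cfg.nb_dispersion, scale=mean / cfg.nb_dispersion)
    counts = rng.poisson(lam)  # cells x genes
    expression = sp.csr_matrix(counts.T)  # genes x cells

    # SNV loci: one synthetic chromosome per class, consecutive positions
    snv_rows: list[CellSNVRecord] = []
    truth_rows = []
    subclone = rng.random(cfg.n_cells) < cfg.somatic_fraction
    for ci, cls in enumerate(SNV_CLASSES):
        for k in range(cfg.snvs_per_class.get(cls, 0)):
            snv = SNVKey(chrom=str(ci + 1), pos=1000 + k, ref="C", alt="T")
            truth_rows.append({"snv": str(snv), "true_class": cls})
            depth = rng.poisson(cfg.coverage_lambda * size_factors)
            if cls == "het":
                n_var = rng.binomial(depth, 0.5)
            elif cls == "hom":
                n_var = depth.copy()
            elif cls == "somatic":
                n_var = np.where(subclone, rng.binomial(depth, 0.5), 0)
            elif cls == "rna":
                n_var = rng.binomial(depth, cfg.rna_rate)
            else:  # bursting: per-cell allele choice, all reads from that allele
                var_allele = rng.random(cfg.n_cells) < 0.5
                n_var = np.where(var_allele, depth, 0)
            n_ref = depth - n_var
            for i in np.flatnonzero(depth >= 1):
                snv_rows.append(CellSNVRecord(snv, barcodes[i], int(n_var[i]), int(n_ref[i])))

    table = SNVTable(snv_rows, sample_id="synthetic", provenance="simulate_dataset")
    truth = GroundTruth(
        snv_class=pd.DataFrame(truth_rows, columns=["snv", "true_class"]),
        cell_truth=pd.DataFrame(
            {"barcode": barcodes, "expression_group": groups, "somatic_subclone": subclone}
        ),
    )
    return SyntheticDataset(expression, [f"GENE{g:04d}" for g in range(cfg.n_genes)], barcodes, table, truth, cfg)


def write_fixtures(dataset: SyntheticDataset, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write a dataset in the package's on-disk formats; all load back losslessly.

    Emits ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, the SNV table
    in the simplified dialect, the two ground-truth TSVs, and the config as
    JSON.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "snv_table": out / "snv_table.tsv",
        "snv_truth": out / "ground_truth_snvs.tsv",
        "cell_truth": out / "ground_truth_cells.tsv",
        "config": out / "sim_config.json",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(dataset.expression), field="integer")
    pd.Series(dataset.gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(dataset.barcodes).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    from .io import write_simple_table

    write_simple_table(dataset.snv_table, paths["snv_table"])
    dataset.truth.snv_class.to_csv(paths["snv_truth"], sep="\t", index=False)
    dataset.truth.cell_truth.to_csv(paths["cell_truth"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(asdict(dataset.config), indent=2) + "\n")
    return paths
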