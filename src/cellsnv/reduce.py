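"""Cell embeddings, transposed-SNV-matrix clustering and sample integration.

The cell pipeline is a fixed, fully seeded workflow over raw counts:
library-size normalization to 10,000 counts per cell, log1p, top 2,000
highly variable genes by dispersion, per-gene standardization, PCA to 30
components, a 15-nearest-neighbor graph, Leiden community detection at
resolution 1.0, and UMAP / t-SNE coordinates in 2 and/or 3 dimensions.

SNVs are clustered through the *transposed SNV matrix*: cells act as
features, each SNV contributing a per-cell VAF block (unobserved entries
encoded as 0) concatenated with a per-cell observed-indicator block so that
"no signal" stays distinguishable from "negative signal".  The same
PCA -> k-NN -> Leiden -> UMAP machinery then groups SNVs with similar
cross-cell expression profiles — e.g. separating homozygous from
heterozygous germline variants.

Multi-sample integration intersects genes, concatenates counts under
sample-prefixed barcodes, and standardizes each gene within each sample
before the joint PCA — a deliberately simple, fully specified alternative
to anchor-based batch correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .matrix import CellSNVMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReduceParams:
    """Pipeline constants; defaults are the package's documented workflow."""

    target_sum: float = 10_000.0
    n_top_genes: int = 2_000
    n_pcs: int = 30
    n_neighbors: int = 15
    resolution: float = 1.0
    methods: tuple[str, ...] = ("umap",)  # any of "umap", "tsne", "pca"
    dims: tuple[int, ...] = (2, 3)


@dataclass
class Embedding:
    """Per-cell coordinates for each (method, dimensionality), plus clusters."""

    barcodes: list[str]
    coordinates: dict  # (method, ndim) -> ndarray (n_cells, ndim)
    clusters: np.ndarray | None = None  # int labels, aligned to barcodes
    annotations: pd.DataFrame | None = None  # optional per-cell columns (cell type, sample id, ...)

    def __post_init__(self) -> None:
        n = len(self.barcodes)
        for key, coords in self.coordinates.items():
            if coords.shape[0] != n:
                raise ValueError(f"coordinates {key} have {coords.shape[0]} rows for {n} barcodes")
        if self.clusters is not None and len(self.clusters) != n:
            raise ValueError("cluster labels misaligned with barcodes")

    def coords(self, method: str = "umap", ndim: int = 2) -> np.ndarray:
        try:
            return self.coordinates[(method, ndim)]
        except KeyError:
            raise KeyError(
                f"no ({method}, {ndim}D) coordinates; available: {sorted(self.coordinates)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"barcode": self.barcodes})
        for (method, ndim), coords in sorted(self.coordinates.items()):
            for k in range(ndim):
                df[f"{method}{ndim}d_{k + 1}"] = coords[:, k]
        if self.clusters is not None:
            df["cluster"] = self.clusters
        if self.annotations is not None:
            df = pd.concat([df, self.annotations.reset_index(drop=True)], axis=1)
        return df


def _preprocessed_pca(adata: ad.AnnData, params: ReduceParams, seed: int, scale_by: str | None = None) -> ad.AnnData:
    """Shared normalize -> log1p -> HVG -> scale -> PCA front end."""
    n_cells, n_genes = adata.shape
    if n_cells <= params.n_pcs:
        raise ValueError(
            f"{n_cells} cells cannot support {params.n_pcs} principal components; lower n_pcs"
        )
    if n_cells < 50:
        logger.warning("embedding %d cells; results below ~50 cells are unreliable", n_cells)
    adata = adata.copy()
    sc.pp.normalize_total(adata, target_sum=params.target_sum)
    sc.pp.log1p(adata)
    n_top = min(params.n_top_genes, n_genes)
    if n_top < n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    if scale_by is None:
        sc.pp.scale(adata, zero_center=True)
    else:
        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        for label in adata.obs[scale_by].unique():
            rows = (adata.obs[scale_by] == label).to_numpy()
            mu = X[rows].mean(axis=0)
            sd = X[rows].std(axis=0)
            sd[sd == 0] = 1.0
            X[rows] = (X[rows] - mu) / sd
        adata.X = X
    sc.tl.pca(adata, n_comps=min(params.n_pcs, adata.n_vars - 1), svd_solver="arpack", random_state=seed)
    return adata


def _graph_cluster_and_embed(adata: ad.AnnData, params: ReduceParams, seed: int) -> Embedding:
    n = adata.n_obs
    sc.pp.neighbors(adata, n_neighbors=min(params.n_neighbors, n - 1), random_state=seed)
    sc.tl.leiden(adata, resolution=params.resolution, random_state=seed, flavor="leidenalg")
    clusters = adata.obs["leiden"].astype(int).to_numpy()
    coordinates: dict = {}
    for ndim in params.dims:
        for method in params.methods:
            if method == "umap":
                sc.tl.umap(adata, n_components=ndim, random_state=seed)
                coordinates[("umap", ndim)] = adata.obsm["X_umap"].copy()
            elif method == "tsne":
                sc.tl.tsne(adata, n_pcs=adata.obsm["X_pca"].shape[1], random_state=seed, n_jobs=1)
                if ndim == 2:  # scanpy t-SNE is 2D; 3D t-SNE via sklearn is out of its surface
                    coordinates[("tsne", 2)] = adata.obsm["X_tsne"].copy()
            elif method == "pca":
                coordinates[("pca", ndim)] = adata.obsm["X_pca"][:, :ndim].copy()
            else:
                raise ValueError(f"unknown reduction method {method!r}")
    return Embedding(
        barcodes=adata.obs_names.tolist(),
        coordinates=coordinates,
        clusters=clusters,
        annotations=adata.obs.drop(columns=["leiden"]).reset_index(drop=True) if adata.obs.shape[1] > 1 else None,
    )


def embed_cells(expr: ad.AnnData, params: ReduceParams | None = None, seed: int = 0) -> Embedding:
    """Embed and cluster cells from raw counts; deterministic given the seed."""
    params = params or ReduceParams()
    adata = _preprocessed_pca(expr, params, seed)
    return _graph_cluster_and_embed(adata, params, seed)


def attach_embedding(precomputed: pd.DataFrame, cells: Sequence[str]) -> Embedding:
    """Adopt an externally computed embedding table (barcode + coordinate columns)."""
    if precomputed.shape[1] < 3:
        raise ValueError("need a barcode column plus at least 2 coordinate columns")
    bc_col = precomputed.columns[0]
    coord_cols = [c for c in precomputed.columns[1:] if pd.api.types.is_numeric_dtype(precomputed[c])]
    if len(coord_cols) < 2:
        raise ValueError("need at least 2 numeric coordinate columns")
    sub = precomputed[precomputed[bc_col].isin(set(cells))]
    if sub.empty:
        raise ValueError("no barcodes of the precomputed embedding match the cell universe")
    ndim = min(len(coord_cols), 3)
    coords = sub[coord_cols[:ndim]].to_numpy(dtype=float)
    return Embedding(barcodes=sub[bc_col].tolist(), coordinates={("precomputed", ndim): coords})


@dataclass
class SNVClusterResult:
    snvs: list
    labels: np.ndarray
    coordinates: np.ndarray  # (n_snvs, 2)
    features: np.ndarray  # the transposed-matrix encoding actually clustered


def snv_feature_matrix(m: CellSNVMatrix) -> np.ndarray:
    """Per-SNV feature vectors: [VAF (unobserved -> 0) | observed indicator] over cells."""
    vafs = m.vaf_matrix()
    vafs = np.nan_to_num(vafs, nan=0.0)
    return np.hstack([vafs.T, m.observed.T.astype(float)])


#: Default Leiden resolution for the transposed-SNV graph.  SNV sets are two
#: orders of magnitude smaller than cell sets, and modularity at resolution
#: 1.0 over-partitions kNN graphs of a few dozen nodes; recovery of planted
#: zygosity classes is stable across resolutions 0.1-0.5.
SNV_CLUSTER_RESOLUTION = 0.3


def cluster_snvs(m: CellSNVMatrix, params: ReduceParams | None = None, seed: int = 0) -> SNVClusterResult:
    """Cluster SNVs by their cross-cell expression profiles (transposed matrix)."""
    params = params or ReduceParams(resolution=SNV_CLUSTER_RESOLUTION)
    if len(m.snvs) < 2:
        raise ValueError("need at least 2 SNVs to cluster")
    X = snv_feature_matrix(m)
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=[str(s) for s in m.snvs]))
    n_comps = min(params.n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(params.n_neighbors, adata.n_obs - 1), random_state=seed)
    sc.tl.leiden(adata, resolution=params.resolution, random_state=seed, flavor="leidenalg")
    sc.tl.umap(adata, n_components=2, random_state=seed)
    return SNVClusterResult(
        snvs=list(m.snvs),
        labels=adata.obs["leiden"].astype(int).to_numpy(),
        coordinates=adata.obsm["X_umap"].copy(),
        features=X,
    )


def integrate_samples(
    exprs: dict[str, ad.AnnData],
    params: ReduceParams | None = None,
    seed: int = 0,
    include: Sequence[str] | None = None,
) -> Embedding:
    """Joint embedding of multiple samples under per-sample gene standardization.

    ``exprs`` maps sample id -> raw-count AnnData.  Barcodes are prefixed
    ``"<sampleid>_"``; the result carries a ``sample_id`` annotation column.
    """
    params = params or ReduceParams()
    if include is not None:
        exprs = {k: v for k, v in exprs.items() if k in set(include)}
    if len(exprs) < 2:
        raise ValueError("integration needs at least 2 samples")
    genes = None
    for adata in exprs.values():
        genes = set(adata.var_names) if genes is None else genes & set(adata.var_names)
    if not genes:
        raise ValueError("no genes shared across samples")
    order = [g for g in next(iter(exprs.values())).var_names if g in genes]
    parts = []
    for sid, adata in exprs.items():
        sub = adata[:, order].copy()
        sub.obs_names = [f"{sid}_{bc}" for bc in sub.obs_names]
        sub.obs["sample_id"] = sid
        parts.append(sub)
    joint = ad.concat(parts, join="inner", merge="same")
    joint.obs["sample_id"] = joint.obs["sample_id"].astype(str)
    adata = _preprocessed_pca(joint, params, seed, scale_by="sample_id")
    return _graph_cluster_and_embed(adata, params, seed)
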