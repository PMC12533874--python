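"""Dataset loading and the filtering / normalisation / HVG pipeline.

Datasets live in :class:`anndata.AnnData` objects throughout the package:
``X`` holds the model input matrix (library-size normalised and log1p after
:func:`filter_and_normalize`), ``layers["counts"]`` the raw counts on the same
spot/gene subset (the ZINB likelihood is evaluated on these),
``obsm["spatial"]`` the 2-D spot coordinates, and ``obs["domain"]`` optional
ground-truth annotations.

Supported on-disk formats: a 10x-style MatrixMarket directory with sidecar
barcode/feature tables plus a coordinate table, an ``.h5ad`` container, or a
directory of plain TSV files (``counts.tsv``, ``coords.tsv``, optional
``labels.tsv``) as written by :func:`dmgcn.synthetic.write_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .errors import ConfigError, DataError

__all__ = ["PreprocessConfig", "load_dataset", "filter_and_normalize", "select_hvg"]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Filtering and normalisation settings.

    ``min_cells`` removes genes expressed in fewer spots than the threshold.
    ``min_genes`` (spots with too few detected genes) and ``min_counts``
    (genes with too few total counts) are optional extra filters used for
    probe-panel platforms with few genes; they default to off.  ``n_hvg``
    highly variable genes are kept by :func:`select_hvg`.
    """

    min_cells: int = 100
    min_genes: int | None = None
    min_counts: int | None = None
    n_hvg: int = 3000
    normalize: bool = True

    def validate(self) -> None:
        for name in ("min_cells", "min_genes", "min_counts"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_hvg < 1:
            raise ConfigError("n_hvg must be >= 1")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if sp.issparse(x) else x, dtype=np.float64)


def _check(adata: ad.AnnData) -> ad.AnnData:
    if adata.n_obs == 0:
        raise DataError("dataset contains 0 spots")
    if adata.n_vars == 0:
        raise DataError("dataset contains 0 genes")
    if adata.obs_names.duplicated().any():
        raise DataError("duplicate spot ids")
    if "spatial" not in adata.obsm:
        raise DataError("no spot coordinates: spatial graph impossible")
    if not np.all(np.isfinite(adata.obsm["spatial"])):
        raise DataError("non-finite spot coordinates")
    return adata


def _load_tsv_dir(path: Path) -> ad.AnnData:
    counts_f, coords_f = path / "counts.tsv", path / "coords.tsv"
    if not counts_f.exists():
        raise DataError(f"missing {counts_f}")
    if not coords_f.exists():
        raise DataError(f"missing coordinate table {coords_f}: spatial graph impossible")
    counts = pd.read_csv(counts_f, sep="\t", index_col=0)
    coords = pd.read_csv(coords_f, sep="\t", index_col=0)
    # spots are matched by id, not by row order
    missing = counts.index.difference(coords.index)
    if len(missing):
        raise DataError(
            f"{coords_f} lacks coordinates for {len(missing)} spots in {counts_f} "
            f"(e.g. {missing[0]!r})"
        )
    coords = coords.loc[counts.index]
    adata = ad.AnnData(
        X=counts.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=counts.index.astype(str)),
        var=pd.DataFrame(index=counts.columns.astype(str)),
    )
    adata.obsm["spatial"] = coords.iloc[:, :2].to_numpy(dtype=np.float64)
    labels_f = path / "labels.tsv"
    if labels_f.exists():
        labels = pd.read_csv(labels_f, sep="\t", index_col=0)
        adata.obs["domain"] = pd.Categorical(
            labels.iloc[:, 0].reindex(counts.index).astype(str)
        )
    log.info("loaded %s: coords matched by spot id from %s", path, coords_f.name)
    return adata


def _load_tenx_mtx(path: Path) -> ad.AnnData:
    import scipy.io as sio

    mtx_f = next((path / n for n in ("matrix.mtx", "matrix.mtx.gz") if (path / n).exists()), None)
    if mtx_f is None:
        raise DataError(f"no matrix.mtx in {path}")
    barcodes_f = path / "barcodes.tsv"
    features_f = next(
        (path / n for n in ("features.tsv", "genes.tsv") if (path / n).exists()), None
    )
    if not barcodes_f.exists() or features_f is None:
        raise DataError(f"missing barcodes.tsv or features.tsv in {path}")
    m = sp.csr_matrix(sio.mmread(mtx_f)).T  # 10x stores genes x barcodes
    if barcodes_f.stat().st_size == 0:
        raise DataError(f"{barcodes_f.name} is empty: dataset has 0 spots")
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(features_f, sep="\t", header=None)
    if m.shape[0] != len(barcodes) or m.shape[1] != len(features):
        raise DataError(
            f"shape mismatch: {mtx_f.name} is {m.T.shape} (genes x spots) but "
            f"{barcodes_f.name} has {len(barcodes)} and {features_f.name} has "
            f"{len(features)} entries"
        )
    if m.shape[0] == 0:
        raise DataError(f"{mtx_f.name} contains 0 spots")
    gene_ids = features.iloc[:, 1] if features.shape[1] > 1 else features.iloc[:, 0]
    adata = ad.AnnData(
        X=m.astype(np.float64),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=gene_ids.astype(str)),
    )
    coords_f = path / "coords.tsv"
    pos_f = path / "tissue_positions_list.csv"
    if coords_f.exists():
        coords = pd.read_csv(coords_f, sep="\t", index_col=0)
    elif pos_f.exists():
        tp = pd.read_csv(pos_f, header=None, index_col=0)
        coords = tp.iloc[:, [3, 2]]  # array_col, array_row
    else:
        raise DataError(f"no coordinate table in {path}: spatial graph impossible")
    missing = adata.obs_names.difference(coords.index)
    if len(missing):
        raise DataError(f"coordinate table lacks {len(missing)} barcodes")
    adata.obsm["spatial"] = coords.loc[adata.obs_names].iloc[:, :2].to_numpy(np.float64)
    return adata


def load_dataset(path: str | Path, format: str = "tsv") -> ad.AnnData:
    """Read a dataset from disk into the package's AnnData convention."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"path does not exist: {path}")
    if format == "tsv":
        adata = _load_tsv_dir(path)
    elif format == "h5ad":
        adata = sc.read_h5ad(path)
        if "spatial" not in adata.obsm:
            for key in ("X_spatial", "coords"):
                if key in adata.obsm:
                    adata.obsm["spatial"] = np.asarray(adata.obsm[key], dtype=np.float64)
                    break
    elif format == "tenx_mtx":
        adata = _load_tenx_mtx(path)
    else:
        raise ConfigError(f"format: unknown dataset format {format!r}")
    if "counts" not in adata.layers:
        adata.layers["counts"] = adata.X.copy()
    return _check(adata)


def filter_and_normalize(adata: ad.AnnData, cfg: PreprocessConfig) -> ad.AnnData:
    """Filter genes/spots on raw counts, then normalise for the encoder.

    Always recomputes from the raw-count layer, so the operation is idempotent:
    genes expressed in fewer than ``cfg.min_cells`` spots are dropped, the
    optional spot/gene filters applied, then (if ``cfg.normalize``) each spot is
    scaled to the median total count and log1p-transformed into ``X``.  Raw
    counts survive in ``layers["counts"]`` for the ZINB likelihood, and
    ``obs["size_factors"]`` records each spot's total relative to the median.
    """
    cfg.validate()
    out = adata.copy()
    out.X = out.layers["counts"].copy() if "counts" in out.layers else out.X
    sc.pp.filter_genes(out, min_cells=cfg.min_cells)
    if cfg.min_counts is not None:
        sc.pp.filter_genes(out, min_counts=cfg.min_counts)
    if cfg.min_genes is not None:
        sc.pp.filter_cells(out, min_genes=cfg.min_genes)
    if out.n_vars == 0:
        raise DataError(
            f"all genes removed by filtering (min_cells={cfg.min_cells}); "
            "lower the thresholds"
        )
    if out.n_obs == 0:
        raise DataError("all spots removed by filtering; lower the thresholds")
    out.layers["counts"] = out.X.copy()
    totals = np.ravel(_dense(out.X).sum(axis=1))
    median = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    out.obs["size_factors"] = np.where(totals > 0, totals / median, 1.0)
    if cfg.normalize:
        sc.pp.normalize_total(out)  # scanpy default: median total per spot
        sc.pp.log1p(out)
    return out


def select_hvg(adata: ad.AnnData, n_hvg: int) -> ad.AnnData:
    """Keep the ``n_hvg`` genes with highest normalised dispersion.

    Uses the Seurat-style mean/dispersion binning from scanpy on the
    (log-normalised) ``X``; ranking ties break by gene order so the selection
    is deterministic.  The raw-count layer is subset alongside.
    """
    if n_hvg > adata.n_vars:
        raise DataError(f"n_hvg={n_hvg} exceeds gene count {adata.n_vars}")
    if n_hvg == adata.n_vars:
        return adata.copy()
    tmp = adata.copy()
    sc.pp.highly_variable_genes(
        tmp, n_top_genes=n_hvg, flavor="seurat", n_bins=min(20, tmp.n_vars)
    )
    disp = np.nan_to_num(
        tmp.var["dispersions_norm"].to_numpy(dtype=np.float64), nan=-np.inf
    )
    raw = np.nan_to_num(tmp.var["dispersions"].to_numpy(dtype=np.float64), nan=-np.inf)
    # raw dispersion breaks ties (degenerate bins can leave norm undefined)
    order = np.lexsort((np.arange(tmp.n_vars), -raw, -disp))
    keep = np.sort(order[:n_hvg])
    return adata[:, keep].copy()
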