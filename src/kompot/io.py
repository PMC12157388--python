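"""Readers/writers for standard single-cell formats and model archives."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .density import DensityEstimate, _DensityModelState
from .expression import ExpressionPredictor
from .state_space import LatentEmbedding

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "read_dataset",
    "save_density",
    "load_density",
    "save_predictor",
    "load_predictor",
]


@dataclass
class Dataset:
    """Validated embedding plus (optional) log-normalized expression."""

    embedding: LatentEmbedding
    expression: np.ndarray | None = None
    gene_ids: np.ndarray | None = None


def read_dataset(
    path,
    *,
    rep: str = "X_latent",
    condition_col: str = "condition",
    layer: str | None = None,
) -> Dataset:
    """Read an H5AD container or a CSV/TSV/MTX directory bundle.

    H5AD: the embedding is taken from ``obsm[rep]`` and the condition from
    ``obs[condition_col]``; expression from ``layers[layer]`` or ``X``.
    Bundle: ``coords.csv`` (index cell_id), ``metadata.tsv`` and optionally
    ``expression.csv`` or ``expression.mtx`` + ``genes.tsv`` + ``cells.tsv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix == ".h5ad":
        return _read_h5ad(path, rep=rep, condition_col=condition_col, layer=layer)
    if path.is_dir():
        return _read_bundle(path, condition_col=condition_col)
    raise ValueError(
        f"unknown input format for {path.name!r}: expected .h5ad or a bundle directory"
    )


def _read_h5ad(path, *, rep, condition_col, layer):
    import anndata as ad

    adata = ad.read_h5ad(path)
    if rep not in adata.obsm:
        raise KeyError(
            f"embedding slot {rep!r} not found in obsm; available: "
            f"{sorted(adata.obsm.keys())}"
        )
    if condition_col not in adata.obs.columns:
        raise KeyError(
            f"condition column {condition_col!r} not found in obs; available: "
            f"{list(adata.obs.columns)}"
        )
    expr = adata.layers[layer] if layer else adata.X
    if expr is not None and hasattr(expr, "toarray"):
        expr = expr.toarray()
    ann_cols = [c for c in adata.obs.columns if c != condition_col]
    embedding = LatentEmbedding(
        coords=np.asarray(adata.obsm[rep], dtype=float),
        cell_ids=adata.obs_names.to_numpy(dtype=object),
        condition=adata.obs[condition_col].astype(str).to_numpy(dtype=object),
        cell_annotations=adata.obs[ann_cols].reset_index(drop=True)
        if ann_cols
        else None,
    )
    return Dataset(
        embedding=embedding,
        expression=np.asarray(expr, dtype=float) if expr is not None else None,
        gene_ids=adata.var_names.to_numpy(dtype=object),
    )


def _read_bundle(path: Path, *, condition_col):
    coords_df = pd.read_csv(path / "coords.csv", index_col=0)
    meta = pd.read_csv(path / "metadata.tsv", sep="\t", dtype={"cell_id": str})
    meta_ids = meta["cell_id"].astype(str).tolist()
    coord_ids = [str(i) for i in coords_df.index]
    missing = sorted(set(coord_ids) ^ set(meta_ids))
    if missing:
        raise ValueError(
            f"cell ids differ between coords.csv and metadata.tsv: {missing[:10]}"
        )
    meta = meta.set_index("cell_id").loc[coord_ids].reset_index()
    if condition_col not in meta.columns:
        raise KeyError(f"condition column {condition_col!r} missing from metadata.tsv")
    ann_cols = [c for c in meta.columns if c not in ("cell_id", condition_col)]
    embedding = LatentEmbedding(
        coords=coords_df.to_numpy(dtype=float),
        cell_ids=np.asarray(coord_ids, dtype=object),
        condition=meta[condition_col].astype(str).to_numpy(dtype=object),
        cell_annotations=meta[ann_cols] if ann_cols else None,
    )

    expression = None
    gene_ids = None
    if (path / "expression.csv").exists():
        expr_df = pd.read_csv(path / "expression.csv", index_col=0)
        expr_df = expr_df.loc[coord_ids]
        expression = expr_df.to_numpy(dtype=float)
        gene_ids = expr_df.columns.to_numpy(dtype=object)
    elif (path / "expression.mtx").exists():
        from scipy.io import mmread

        mat = mmread(path / "expression.mtx")
        expression = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                                dtype=float)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
        gene_ids = genes.iloc[:, 0].to_numpy(dtype=object)
        if len(gene_ids) != expression.shape[1]:
            raise ValueError(
                f"genes.tsv rows ({len(gene_ids)}) != expression columns "
                f"({expression.shape[1]})"
            )
        cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None)
        order = pd.Index(cells.iloc[:, 0].astype(str)).get_indexer(coord_ids)
        if (order < 0).any():
            raise ValueError("cells.tsv does not cover all cells in coords.csv")
        expression = expression[order]
    return Dataset(embedding=embedding, expression=expression, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# model archives (HDF5)


def _write_attr(grp, key, value):
    grp.attrs[key] = value if value is not None else "__none__"


def _read_attr(grp, key):
    v = grp.attrs[key]
    if isinstance(v, bytes):
        v = v.decode()
    return None if v == "__none__" else v


def save_density(estimate: DensityEstimate, path) -> None:
    state = estimate.model_state
    with h5py.File(path, "w") as f:
        f.attrs["kompot_model"] = "density"
        _write_attr(f, "condition", estimate.condition)
        f.attrs["n_cells"] = estimate.n_cells
        f.attrs["intrinsic_dim"] = estimate.intrinsic_dim
        f.create_dataset("predictive_mean", data=estimate.predictive_mean)
        f.create_dataset("predictive_sd", data=estimate.predictive_sd)
        g = f.create_group("state")
        g.attrs["mode"] = state.mode
        g.attrs["lengthscale"] = state.lengthscale
        g.attrs["mean_const"] = state.mean_const
        g.create_dataset("X", data=state.X)
        g.create_dataset("pred_weights", data=state.pred_weights)
        g.create_dataset("var_chol", data=state.var_chol)
        g.create_dataset("var_aux", data=state.var_aux)
        if "train_coords" in state.extras:
            g.create_dataset("train_coords", data=state.extras["train_coords"])
        if "sigma_inv_one" in state.extras:
            g.create_dataset("sigma_inv_one", data=state.extras["sigma_inv_one"])
            g.attrs["one_sigma_one"] = state.extras["one_sigma_one"]


def load_density(path) -> DensityEstimate:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kompot_model") != "density":
            raise ValueError(f"{path} is not a density model archive")
        g = f["state"]
        extras = {}
        if "train_coords" in g:
            extras["train_coords"] = g["train_coords"][()]
        if "sigma_inv_one" in g:
            extras["sigma_inv_one"] = g["sigma_inv_one"][()]
            extras["one_sigma_one"] = float(g.attrs["one_sigma_one"])
        state = _DensityModelState(
            mode=str(g.attrs["mode"]),
            X=g["X"][()],
            lengthscale=float(g.attrs["lengthscale"]),
            intrinsic_dim=float(f.attrs["intrinsic_dim"]),
            n_cells=int(f.attrs["n_cells"]),
            mean_const=float(g.attrs["mean_const"]),
            pred_weights=g["pred_weights"][()],
            var_chol=g["var_chol"][()],
            var_aux=g["var_aux"][()],
            extras=extras,
        )
        return DensityEstimate(
            condition=_read_attr(f, "condition"),
            n_cells=int(f.attrs["n_cells"]),
            intrinsic_dim=float(f.attrs["intrinsic_dim"]),
            predictive_mean=f["predictive_mean"][()],
            predictive_sd=f["predictive_sd"][()],
            model_state=state,
        )


def save_predictor(predictor: ExpressionPredictor, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kompot_model"] = "expression"
        _write_attr(f, "condition", predictor.condition)
        f.attrs["lengthscale"] = predictor.lengthscale
        f.attrs["noise_variance"] = predictor.noise_variance
        f.attrs["jitter"] = predictor.jitter
        f.create_dataset(
            "gene_ids", data=np.asarray(predictor.gene_ids, dtype="S")
        )
        for name in ("landmarks", "landmark_values", "landmark_cov", "gene_means"):
            f.create_dataset(name, data=getattr(predictor, name))
        f.create_dataset("L", data=predictor._L)
        f.create_dataset("LQ", data=predictor._LQ)
        f.create_dataset("W", data=predictor._W)
        f.create_dataset("zero_genes", data=predictor.zero_genes)


def load_predictor(path) -> ExpressionPredictor:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kompot_model") != "expression":
            raise ValueError(f"{path} is not an expression model archive")
        return ExpressionPredictor(
            condition=_read_attr(f, "condition"),
            gene_ids=np.array([s.decode() for s in f["gene_ids"][()]], dtype=object),
            landmarks=f["landmarks"][()],
            lengthscale=float(f.attrs["lengthscale"]),
            noise_variance=float(f.attrs["noise_variance"]),
            jitter=float(f.attrs["jitter"]),
            landmark_values=f["landmark_values"][()],
            landmark_cov=f["landmark_cov"][()],
            gene_means=f["gene_means"][()],
            _L=f["L"][()],
            _LQ=f["LQ"][()],
            _W=f["W"][()],
            zero_genes=f["zero_genes"][()].astype(bool),
        )
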