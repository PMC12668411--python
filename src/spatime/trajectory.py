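"""Normalization, variable-gene selection, embedding, diffusion pseudotime.

Counts are depth-normalized to 10,000 UMIs per cell and log1p-transformed;
the top 3,000 highly variable genes (variance-stabilizing ranking on raw
counts, mitochondrial and ribosomal genes excluded) feed a 30-dimensional
centered PCA embedding. A k=15 nearest-neighbor graph over the embedding
yields a 10-component diffusion map, and diffusion pseudotime from a root
cell is scaled to [0, 1].

PCA stands in for a learned (autoencoder) embedding: the downstream
statistics consume any low-dimensional representation, and single-sample
synthetic data carries no batch structure for a batch-aware model to
absorb. The embedding's ``method`` tag records this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from scipy.sparse.csgraph import connected_components

RIBO_PATTERNS = ("RPS", "RPL", "MRPS", "MRPL")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


# ------------------------------------------------------------ normalization


def normalize_log(counts: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Depth-normalize each cell to ``target_sum`` and log1p-transform.

    Raises on all-zero cells (QC should have removed them), naming the
    first offender.
    """
    totals = np.asarray(counts.X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = counts.obs_names[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total counts; run QC first")
    out = counts.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["target_sum"] = target_sum
    return out


# -------------------------------------------------------------- HVG ranking


def _variance_stabilized_ranking(X: np.ndarray) -> np.ndarray:
    """Standardized variance per gene after regressing the mean-variance
    trend (lowess in log10 space) and clipping standardized counts at
    sqrt(n), computed on raw counts."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    score = np.zeros(X.shape[1])
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 5:
        lx = np.log10(mean[fit_mask])
        ly = np.log10(var[fit_mask])
        smoothed = lowess(ly, lx, frac=0.3, return_sorted=False)
        reg_std = np.sqrt(10.0**smoothed)
        clip_val = np.sqrt(n)
        idx = np.where(fit_mask)[0]
        for pos, g in enumerate(idx):
            z = (X[:, g] - mean[g]) / reg_std[pos]
            np.clip(z, -clip_val, clip_val, out=z)
            score[g] = np.square(z).sum() / (n - 1)
    return score


def select_hvgs(
    counts: ad.AnnData,
    n: int = 3000,
    exclude_patterns: tuple[str, ...] = RIBO_PATTERNS,
    exclude_mito: bool = True,
) -> list[str]:
    """Top-n highly variable genes on raw counts, excluding mitochondrial
    and ribosomal genes. Zero-variance genes are never selected."""
    X = _dense(counts.X).astype(np.float64)
    score = _variance_stabilized_ranking(X)

    names = pd.Index(counts.var_names)
    excluded = np.zeros(counts.n_vars, dtype=bool)
    if exclude_mito:
        if "mt" in counts.var:
            excluded |= counts.var["mt"].to_numpy(bool)
        excluded |= names.str.upper().str.startswith("MT-")
    for pat in exclude_patterns:
        excluded |= names.str.upper().str.startswith(pat.upper())
    score[excluded] = -np.inf
    score[X.var(axis=0) == 0] = -np.inf

    available = int(np.isfinite(score).sum())
    if n > available:
        warnings.warn(
            f"requested {n} HVGs but only {available} eligible genes; using all",
            stacklevel=2,
        )
        n = available
    order = np.argsort(-score, kind="stable")[:n]
    return names[np.sort(order)].tolist()


# ---------------------------------------------------------------- embedding


@dataclass
class Embedding:
    coords: np.ndarray          # cells x d
    method: str
    hvgs: list[str]


def embed(
    norm: ad.AnnData,
    d: int = 30,
    hvgs: list[str] | None = None,
) -> Embedding:
    """Centered principal-component embedding of the (HVG-subset)
    log-normalized matrix with a deterministic sign convention: each
    component's largest-magnitude loading is positive."""
    if d < 2:
        raise ValueError("d must be >= 2")
    X = _dense(norm[:, hvgs].X if hvgs is not None else norm.X).astype(np.float64)
    Xc = X - X.mean(axis=0)
    rank = min(Xc.shape) - 1
    if d > rank:
        warnings.warn(f"d={d} exceeds data rank; reducing to {rank}", stacklevel=2)
        d = rank
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(d), np.argmax(np.abs(Vt[:d]), axis=1)])
    signs[signs == 0] = 1.0
    coords = (U[:, :d] * s[:d]) * signs
    return Embedding(coords=coords, method="pca", hvgs=list(hvgs or norm.var_names))


# --------------------------------------------------------------- pseudotime


@dataclass
class PseudotimeResult:
    t: np.ndarray
    root: int
    n_diffusion_comps: int


def diffusion_pseudotime(
    embedding: Embedding | np.ndarray,
    root: int,
    k: int = 15,
    n_comps: int = 10,
) -> PseudotimeResult:
    """Diffusion pseudotime from a root cell over a k-nearest-neighbor
    graph of the embedding, using an adaptive-bandwidth Gaussian kernel
    diffusion map with ``n_comps`` components, rescaled so t(root)=0 and
    max(t)=1.

    Raises if the kNN graph is disconnected (component sizes listed) or
    the root index is out of range.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = coords.shape[0]
    if not (0 <= root < n):
        raise ValueError(f"root index {root} outside [0, {n})")
    adata = ad.AnnData(X=np.zeros((n, 1), dtype=np.float32))
    adata.obsm["X_emb"] = coords
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_emb", random_state=0)
    n_cc, labels = connected_components(adata.obsp["connectivities"], directed=False)
    if n_cc > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"kNN graph is disconnected ({n_cc} components, sizes {sizes})"
        )
    sc.tl.diffmap(adata, n_comps=n_comps)
    adata.uns["iroot"] = int(root)
    sc.tl.dpt(adata, n_dcs=n_comps)
    t = adata.obs["dpt_pseudotime"].to_numpy(np.float64)
    t = t - t[root]
    tmax = t.max()
    if tmax > 0:
        t = t / tmax
    return PseudotimeResult(t=t, root=int(root), n_diffusion_comps=n_comps)
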