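"""Cell quality control: fixed and MAD-based filters, doublet flagging.

``filter_cells`` removes droplets with fewer than 500 UMIs, with a
log-scale total-UMI or detected-gene count more than three median absolute
deviations from the median, or with a mitochondrial fraction exceeding 8%
(defaults; all configurable).

``detect_doublets`` flags doublets by repeated synthetic-doublet cluster
enrichment: in each iteration, synthetic doublets (sums of two random real
cells) are co-embedded and co-clustered with the real cells, clusters
significantly enriched for synthetic doublets (upper-tail hypergeometric
p < 1e-7) mark their real members, and a cell is called a doublet when
flagged in at least half of 40 iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from scipy.stats import hypergeom

from .config import DoubletParams, QcThresholds
from .trajectory import select_hvgs


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


@dataclass
class QcReport:
    n_input: int
    removed_min_umi: int
    removed_mad_umi: int
    removed_mad_genes: int
    removed_mito: int
    n_kept: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d.update(self.extras)
        return d


def _mad_outliers(values: np.ndarray, k: float) -> np.ndarray:
    """Strict |deviation| > k * MAD on the given values; a zero MAD flags
    nothing (every deviation is 0 or the rule is degenerate)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return np.abs(values - med) > k * mad


def _mad_outliers_masked(values: np.ndarray, keep: np.ndarray, k: float) -> np.ndarray:
    """MAD outlier flags with median/MAD computed over the retained cells."""
    out = np.zeros_like(keep)
    if keep.any():
        med = np.median(values[keep])
        mad = np.median(np.abs(values[keep] - med))
        out[keep] = np.abs(values[keep] - med) > k * mad
    return out


def filter_cells(
    counts: ad.AnnData, thresholds: QcThresholds | None = None
) -> tuple[np.ndarray, QcReport]:
    """Boolean keep-mask over cells plus a per-rule removal report.

    Rules (a cell is removed if it fails any): total UMI < ``min_umi``;
    log1p total UMI or log1p detected genes deviating by more than
    ``mad_k`` MADs from the median; mitochondrial fraction strictly above
    ``mito_max``. All-zero cells are removed by the UMI floor and never
    reach the mito-fraction division (guarded denominator).

    The MAD rules are iterated to a fixed point (medians recomputed over
    the retained cells until no further removal), so the filter is a
    projection: applying it to its own output removes nothing. In
    practice the first pass removes almost everything; later passes only
    pick up borderline cells exposed by the shifted median.
    """
    thresholds = thresholds or QcThresholds()
    X = counts.X
    if sparse.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        total = X.sum(axis=1)
        genes = (X > 0).sum(axis=1)
    if "mt" in counts.var:
        mt_mask = counts.var["mt"].to_numpy(bool)
    else:
        mt_mask = pd.Index(counts.var_names).str.upper().str.startswith("MT-")
    mito_total = (
        np.asarray(X[:, mt_mask].sum(axis=1)).ravel()
        if mt_mask.any()
        else np.zeros_like(total)
    )
    mito_frac = mito_total / np.maximum(total, 1.0)

    fail_floor = total < thresholds.min_umi
    fail_mito = mito_frac > thresholds.mito_max

    keep = ~(fail_floor | fail_mito)
    fail_mad_umi = np.zeros_like(keep)
    fail_mad_genes = np.zeros_like(keep)
    for _ in range(100):  # MAD rules iterated to a fixed point
        new_umi = keep & _mad_outliers_masked(np.log1p(total), keep, thresholds.mad_k)
        new_genes = keep & _mad_outliers_masked(np.log1p(genes), keep, thresholds.mad_k)
        if not (new_umi.any() or new_genes.any()):
            break
        fail_mad_umi |= new_umi
        fail_mad_genes |= new_genes
        keep &= ~(new_umi | new_genes)
    report = QcReport(
        n_input=counts.n_obs,
        removed_min_umi=int(fail_floor.sum()),
        removed_mad_umi=int(fail_mad_umi.sum()),
        removed_mad_genes=int(fail_mad_genes.sum()),
        removed_mito=int(fail_mito.sum()),
        n_kept=int(keep.sum()),
    )
    return keep, report


# ----------------------------------------------------------------- doublets


def flag_enriched_clusters(
    clusters: np.ndarray,
    is_synthetic: np.ndarray,
    p_threshold: float,
) -> np.ndarray:
    """Per-observation flag for membership in a cluster significantly
    enriched for synthetic doublets.

    Enrichment is the upper-tail hypergeometric probability of drawing at
    least the observed number of synthetic doublets in a cluster-sized
    draw from the augmented population; a cluster is flagged only when
    p is strictly below ``p_threshold``.
    """
    clusters = np.asarray(clusters)
    is_synthetic = np.asarray(is_synthetic, dtype=bool)
    flags = np.zeros(clusters.shape[0], dtype=bool)
    M = clusters.shape[0]
    K = int(is_synthetic.sum())
    for cl in np.unique(clusters):
        in_cl = clusters == cl
        n_draw = int(in_cl.sum())
        k_obs = int((in_cl & is_synthetic).sum())
        p = hypergeom.sf(k_obs - 1, M, K, n_draw)  # P(X >= k_obs)
        if p < p_threshold:  # strict <
            flags |= in_cl
    return flags


def _one_doublet_iteration(
    X_real: np.ndarray,
    var: pd.DataFrame,
    params: DoubletParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One round of synthetic-doublet enrichment; returns a boolean flag
    per real cell."""
    n_real = X_real.shape[0]
    n_syn = params.n_synthetic or n_real
    i = rng.integers(0, n_real, n_syn)
    j = rng.integers(0, n_real, n_syn)
    X_syn = X_real[i] + X_real[j]
    X_aug = np.vstack([X_real, X_syn])

    adata = ad.AnnData(X=X_aug.astype(np.float32), var=var.copy())
    n_hvgs = min(params.n_hvgs, adata.n_vars)
    if n_hvgs < params.n_hvgs:
        warnings.warn(
            f"only {adata.n_vars} genes available; using all of them", stacklevel=2
        )
    hvgs = select_hvgs(adata, n=n_hvgs, exclude_patterns=())
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sub = adata[:, hvgs].copy()
    n_pcs = min(params.n_pcs, sub.n_vars - 1, sub.n_obs - 1)
    sc.pp.pca(sub, n_comps=n_pcs, random_state=int(rng.integers(0, 2**31 - 1)))
    sc.pp.neighbors(sub, n_neighbors=params.n_neighbors, use_rep="X_pca",
                    random_state=0)
    sc.tl.leiden(
        sub,
        resolution=params.resolution,
        flavor="igraph",
        n_iterations=2,
        random_state=int(rng.integers(0, 2**31 - 1)),
        directed=False,
    )
    clusters = sub.obs["leiden"].to_numpy()
    is_syn = np.zeros(X_aug.shape[0], dtype=bool)
    is_syn[n_real:] = True
    flags = flag_enriched_clusters(clusters, is_syn, params.cluster_p_threshold)
    return flags[:n_real]


def detect_doublets(
    counts: ad.AnnData, params: DoubletParams | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Iterative synthetic-doublet voting.

    Returns (per-cell doublet boolean, per-iteration tally frame). The
    tally (flag count per iteration) is the logged convergence series a
    user can inspect.
    """
    params = params or DoubletParams()
    X_real = _dense(counts.X).astype(np.float64)
    var = counts.var[[c for c in ("mt",) if c in counts.var]].copy()
    rng = np.random.default_rng(params.seed)
    votes = np.zeros(counts.n_obs, dtype=np.int64)
    tallies = []
    for it in range(params.n_iterations):
        flags = _one_doublet_iteration(X_real, var, params, rng)
        votes += flags
        tallies.append((it, int(flags.sum())))
    is_doublet = votes >= params.voter_threshold * params.n_iterations
    tally = pd.DataFrame(tallies, columns=["iteration", "n_flagged"])
    return is_doublet, tally
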