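"""Cell-type-specific light-response analysis.

Light-responsive genes within one cell type are detected on pseudobulk
profiles by a union of sources: regression of each gene on the first and
second principal-component sample scores of the log-normalized matrix,
regression on time, and an NB pairwise 0 h vs 12 h contrast (reusing the
partitioning machinery).  Differential genes are then grouped into temporal
trend clusters by hierarchical clustering of z-scaled profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .partition import PseudobulkMatrix, bh_adjust, _lrt_per_gene

log = logging.getLogger(__name__)

__all__ = ["LightDEResult", "TrendCluster", "light_de", "trend_cluster"]


@dataclass
class LightDEResult:
    gene: str
    cell_type: str
    source: str  # pc1 | pc2 | linear_time | pairwise_0_12
    statistic: float
    p: float
    padj: float


@dataclass
class TrendCluster:
    cluster_id: int
    members: list
    time_grid: np.ndarray
    trend: np.ndarray


def _log_normalized(pb: PseudobulkMatrix) -> np.ndarray:
    sf = pb.samples["size_factor"].to_numpy(dtype=float)
    return np.log2(pb.counts.to_numpy(dtype=float) / sf[None, :] + 1.0)


def _pc_scores(logmat: np.ndarray, n_pcs=2):
    """Sample scores of the first PCs of the gene-centred matrix.

    The sign of each PC is fixed so that the gene with the largest absolute
    loading has a positive loading (PCA signs are otherwise arbitrary).
    """
    centred = logmat - logmat.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    scores = []
    for k in range(n_pcs):
        sign = np.sign(U[np.argmax(np.abs(U[:, k])), k]) or 1.0
        scores.append(sign * s[k] * Vt[k])
    return scores


def light_de(pb: PseudobulkMatrix, cell_type, alpha=0.05) -> list[LightDEResult]:
    """Light-responsive genes in one cell type (union over sources).

    Requires >=3 time-point samples.  Sources: per-gene linear regression on
    PC1/PC2 sample scores and on time (slope t-tests), plus an NB LRT
    pairwise contrast of 0 h vs 12 h when both time points are present.
    BH adjustment is applied within each source; any significant source
    makes the gene light-responsive.
    """
    mask = (pb.samples["cell_type"] == cell_type).to_numpy()
    sub = pb.subset(mask)
    if sub.samples.shape[0] < 3:
        raise ValueError("need at least 3 pseudobulk samples for the cell type")
    if sub.samples["time_h"].nunique() < 3:
        raise ValueError("need at least 3 distinct time points")
    logmat = _log_normalized(sub)
    genes = list(sub.counts.index)
    time = sub.samples["time_h"].to_numpy(dtype=float)
    pc1, pc2 = _pc_scores(logmat)
    results = []

    def regress(source, x):
        stats, pvals = [], []
        for gi in range(len(genes)):
            y = logmat[gi]
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                stats.append(0.0)
                pvals.append(1.0)
                continue
            fit = scipy.stats.linregress(x, y)
            stats.append(fit.slope / fit.stderr if fit.stderr > 0 else 0.0)
            pvals.append(fit.pvalue if np.isfinite(fit.pvalue) else 1.0)
        padj = bh_adjust(pvals)
        for gi, g in enumerate(genes):
            results.append(LightDEResult(g, cell_type, source, float(stats[gi]),
                                         float(pvals[gi]), float(padj[gi])))

    regress("pc1", pc1)
    regress("pc2", pc2)
    regress("linear_time", time)

    t0 = time == 0.0
    t12 = time == 12.0
    if t0.sum() >= 2 and t12.sum() >= 2:
        keep = t0 | t12
        counts = sub.counts.iloc[:, keep]
        offsets = np.log(sub.samples["size_factor"].to_numpy(dtype=float)[keep])
        is12 = t12[keep].astype(float)
        X_full = np.column_stack([np.ones_like(is12), is12])
        X_red = np.ones_like(is12)[:, None]
        nonzero = counts.sum(axis=1) > 0
        cmat = counts.loc[nonzero].to_numpy(dtype=float)
        stats, pvals, betas, conv = _lrt_per_gene(cmat, X_full, X_red, offsets)
        padj = bh_adjust(pvals)
        for gi, g in enumerate(counts.index[nonzero]):
            results.append(LightDEResult(g, cell_type, "pairwise_0_12",
                                         float(stats[gi]), float(pvals[gi]), float(padj[gi])))
    else:
        warnings.warn("0 h or 12 h samples missing; pairwise source skipped")

    return results


def significant_genes(results, alpha=0.05) -> set:
    """Union of genes significant in any source."""
    return {r.gene for r in results if r.padj < alpha}


def _smooth(grid, y, frac=0.75):
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(grid) < 4:
        return y
    sm = lowess(y, grid, frac=frac, return_sorted=False)
    return sm


def trend_cluster(profiles: pd.DataFrame, min_size=10, target_k=2) -> list[TrendCluster]:
    """Hierarchical trend clusters of time-course expression profiles.

    ``profiles`` is genes x time points (column labels are times in hours).
    Profiles are z-scaled per gene, clustered with complete linkage on
    Euclidean distance, and cut at the smallest number of clusters giving at
    least ``target_k`` clusters of size >= ``min_size``; smaller clusters
    are merged into the nearest large cluster by centroid distance.  Each
    cluster's trend is a locally weighted smooth of its mean profile.
    """
    if profiles.shape[0] < min_size:
        raise ValueError(f"need at least min_size={min_size} genes")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    Z = np.zeros_like(X)
    Z[keep] = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    genes = np.array(profiles.index)
    grid = np.asarray(profiles.columns, dtype=float)

    linkage = sch.linkage(Z, method="complete", metric="euclidean")
    best_labels, best_big = None, 0
    for k in range(target_k, len(genes) + 1):
        labels = sch.fcluster(linkage, t=k, criterion="maxclust")
        sizes = pd.Series(labels).value_counts()
        big = (sizes >= min_size).sum()
        if big >= target_k:
            best_labels, best_big = labels, big
            break
        if big > best_big:
            best_labels, best_big = labels, big
    if best_labels is None:
        best_labels = np.ones(len(genes), dtype=int)
        best_big = 1
    if best_big < target_k:
        log.warning("target_k=%d unreachable; returning %d cluster(s)", target_k, best_big)
    labels = np.asarray(best_labels)

    sizes = pd.Series(labels).value_counts()
    big_ids = sorted(sizes.index[sizes >= min_size])
    if not big_ids:
        big_ids = [sizes.idxmax()]
    centroids = {cid: Z[labels == cid].mean(axis=0) for cid in big_ids}
    for cid in sizes.index:
        if cid in big_ids:
            continue
        members = labels == cid
        c = Z[members].mean(axis=0)
        nearest = min(big_ids, key=lambda b: np.linalg.norm(c - centroids[b]))
        labels[members] = nearest

    clusters = []
    for new_id, cid in enumerate(sorted(set(labels)), start=1):
        members = genes[labels == cid].tolist()
        mean_prof = Z[labels == cid].mean(axis=0)
        clusters.append(
            TrendCluster(new_id, members, grid, np.asarray(_smooth(grid, mean_prof)))
        )
    return clusters
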