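"""Pseudo-bulking and the cell-type partitioning test.

The partitioning test asks, per gene, whether expression differs between two
cell types while controlling for time: a negative-binomial GLM with log link
and log(size-factor) offset, full model ``count ~ cell_type + time_h``
against reduced ``count ~ time_h``, compared by a likelihood-ratio test on
one degree of freedom.  Size factors are DESeq-style median-of-ratios.
Dispersions are per-gene method-of-moments estimates shrunk halfway toward
the across-gene trend (a deliberately simplified take on empirical-Bayes
shrinkage).  Marker detection is a one-vs-rest Wilcoxon rank-sum test on
log-normalized expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "PseudobulkMatrix",
    "PartitionRecord",
    "MarkerRecord",
    "pseudobulk",
    "size_factors",
    "partition_test",
    "dark_partition_test",
    "find_markers",
    "bh_adjust",
]


@dataclass
class PseudobulkMatrix:
    """Summed counts per (cell_type, time_h, batch) group.

    ``counts`` is genes x samples; ``samples`` carries per-sample metadata
    (cell_type, time_h, batch, n_cells, size_factor).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def subset(self, mask) -> "PseudobulkMatrix":
        keep = self.samples.index[mask]
        return PseudobulkMatrix(self.counts[keep], self.samples.loc[keep])


@dataclass
class PartitionRecord:
    gene: str
    cell_a: str
    cell_b: str
    log2fc: float  # a over b
    lrt_stat: float
    p: float
    padj: float
    favoured_cell: str
    converged: bool = True


@dataclass
class MarkerRecord:
    gene: str
    cluster: str
    p: float
    padj: float
    specificity: float
    pct_in: float
    pct_out: float


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (positive), one per sample column.

    Falls back to total-count ratios when too few genes have a finite
    geometric mean (all-zero-heavy matrices).
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    finite = np.isfinite(logmat).all(axis=1)
    if finite.sum() >= 1:
        loggeo = logmat[finite].mean(axis=1)
        sf = np.exp(np.median(logmat[finite] - loggeo[:, None], axis=0))
    else:
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count; cannot normalize")
        sf = totals / np.exp(np.mean(np.log(totals)))
    if (sf <= 0).any() or not np.isfinite(sf).all():
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def pseudobulk(adata, group_by=("cell_type", "time_h", "batch"), min_cells=3) -> PseudobulkMatrix:
    """Sum counts per metadata group; drop groups with < min_cells cells."""
    group_by = list(group_by)
    for key in group_by:
        if key not in adata.obs.columns:
            raise KeyError(f"grouping key '{key}' not in cell metadata")
    X = sp.csr_matrix(adata.X)
    groups = adata.obs.groupby(group_by, observed=True, sort=True).indices
    cols, meta = {}, []
    for key, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if not isinstance(key, tuple):
            key = (key,)
        if len(idx) < min_cells:
            log.warning("dropping group %s with %d < %d cells", key, len(idx), min_cells)
            continue
        name = "|".join(f"{v:g}" if isinstance(v, float) else str(v) for v in key)
        cols[name] = np.asarray(X[idx].sum(axis=0)).ravel().astype(int)
        meta.append(dict(zip(group_by, key), sample=name, n_cells=len(idx)))
    if not cols:
        raise ValueError(f"no group has at least min_cells={min_cells} cells")
    counts = pd.DataFrame(cols, index=adata.var_names)
    samples = pd.DataFrame(meta).set_index("sample")
    samples["size_factor"] = size_factors(counts)
    return PseudobulkMatrix(counts, samples)


# ---------------------------------------------------------------------------
# NB GLM machinery (log link, offset, fixed dispersion)
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _irls(y, X, offset, alpha, max_iter=100, tol=1e-12):
    """IRLS for an NB (or Poisson when alpha ~ 0) GLM with log link.

    Returns (beta, mu, loglik, converged).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    # init from a working response on log(y + 0.5)
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, mu, _nb_loglik(y, mu, alpha), False
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30, 30)), alpha)
        if not np.isfinite(ll):
            return beta, mu, ll_old, False
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            beta = beta_new
            converged = True
            break
        beta, ll_old = beta_new, ll
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    return beta, mu, _nb_loglik(y, mu, alpha), converged


def _dispersion_estimates(counts, X, offsets):
    """Per-gene method-of-moments dispersion from full-model Poisson fits,
    shrunk halfway toward the across-gene mean (the 'trend')."""
    alphas = np.empty(counts.shape[0])
    for gi in range(counts.shape[0]):
        y = counts[gi]
        _, mu, _, _ = _irls(y, X, offsets, alpha=0.0)
        num = np.sum((y - mu) ** 2 - mu)
        den = np.sum(mu**2)
        alphas[gi] = max(num / den, 1e-8) if den > 0 else 1e-8
    trend = float(np.mean(alphas))
    return 0.5 * alphas + 0.5 * trend


def _lrt_per_gene(counts, X_full, X_red, offsets, df=1):
    """Run the NB LRT for every gene; returns (stat, p, beta_full, converged)."""
    n_genes = counts.shape[0]
    alphas = _dispersion_estimates(counts, X_full, offsets)
    stats = np.empty(n_genes)
    pvals = np.empty(n_genes)
    betas = np.empty((n_genes, X_full.shape[1]))
    conv = np.ones(n_genes, dtype=bool)
    for gi in range(n_genes):
        y = counts[gi]
        bf, _, llf, cf = _irls(y, X_full, offsets, alphas[gi])
        br, _, llr, cr = _irls(y, X_red, offsets, alphas[gi])
        betas[gi] = bf
        if not (cf and cr) or not np.isfinite(llf) or not np.isfinite(llr):
            stats[gi], pvals[gi], conv[gi] = 0.0, 1.0, False
            continue
        stat = max(2.0 * (llf - llr), 0.0)
        stats[gi] = stat
        pvals[gi] = scipy.stats.chi2.sf(stat, df)
    return stats, pvals, betas, conv


def _run_partition(pb, cell_a, cell_b, alpha, with_time):
    mask = pb.samples["cell_type"].isin([cell_a, cell_b]).to_numpy()
    sub = pb.subset(mask)
    for ct in (cell_a, cell_b):
        n = int((sub.samples["cell_type"] == ct).sum())
        if n < 2:
            raise ValueError(f"cell type '{ct}' has {n} < 2 pseudobulk samples")
    is_a = (sub.samples["cell_type"] == cell_a).to_numpy().astype(float)
    time = sub.samples["time_h"].to_numpy(dtype=float)
    offsets = np.log(sub.samples["size_factor"].to_numpy(dtype=float))
    intercept = np.ones_like(is_a)
    if with_time:
        X_full = np.column_stack([intercept, is_a, time])
        X_red = np.column_stack([intercept, time])
    else:
        X_full = np.column_stack([intercept, is_a])
        X_red = intercept[:, None]

    counts_df = sub.counts
    nonzero = counts_df.sum(axis=1) > 0
    excluded = list(counts_df.index[~nonzero])
    if excluded:
        log.info("excluding %d all-zero genes", len(excluded))
    counts = counts_df.loc[nonzero].to_numpy(dtype=float)
    genes = list(counts_df.index[nonzero])

    stats, pvals, betas, conv = _lrt_per_gene(counts, X_full, X_red, offsets)
    padj = bh_adjust(pvals)
    records = []
    for gi, g in enumerate(genes):
        l2fc = betas[gi, 1] / np.log(2.0)
        records.append(
            PartitionRecord(
                gene=g,
                cell_a=cell_a,
                cell_b=cell_b,
                log2fc=float(l2fc),
                lrt_stat=float(stats[gi]),
                p=float(pvals[gi]),
                padj=float(padj[gi]),
                favoured_cell=cell_a if l2fc > 0 else cell_b,
                converged=bool(conv[gi]),
            )
        )
    return records, excluded


def partition_test(pb: PseudobulkMatrix, cell_a, cell_b, alpha=0.05):
    """Partitioning test between two cell types with time as covariate.

    Full model ``count ~ cell_type + time_h`` vs reduced ``count ~ time_h``,
    NB likelihood-ratio test on chi2(1), BH adjustment across tested genes.
    Genes with all-zero counts across both cell types are excluded.
    Returns (records, excluded_genes).
    """
    return _run_partition(pb, cell_a, cell_b, alpha, with_time=True)


def dark_partition_test(pb: PseudobulkMatrix, cell_a, cell_b, alpha=0.05):
    """Partitioning at the 0-h (etiolated) time point only: full model
    ``count ~ cell_type`` vs intercept-only, over replicate (batch) samples."""
    dark = pb.subset((pb.samples["time_h"] == 0).to_numpy())
    if dark.samples.empty:
        raise ValueError("no 0-h samples present")
    return _run_partition(dark, cell_a, cell_b, alpha, with_time=False)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def _log_normalize(adata, target_sum=None):
    X = sp.csr_matrix(adata.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        totals[totals <= 0] = 1.0
    if target_sum is None:
        target_sum = float(np.median(totals))
    norm = X.multiply(target_sum / totals[:, None]).tocsr()
    return norm


def find_markers(adata, cluster_key="cell_type", p_cut=0.05, min_pct=0.1, min_specificity=0.0):
    """One-vs-rest Wilcoxon rank-sum markers on log-normalized expression.

    A record is returned only if padj < p_cut, pct_in > min_pct and
    specificity (in-cluster mean / out-of-cluster mean of normalized
    expression) > min_specificity.  Clusters with < 3 cells are skipped.
    """
    clusters = adata.obs[cluster_key].astype(str)
    uniq = sorted(clusters.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters to find markers")
    norm = _log_normalize(adata)
    logn = norm.copy()
    logn.data = np.log1p(logn.data)
    dense = np.asarray(logn.todense())
    norm_dense = np.asarray(norm.todense())
    genes = list(adata.var_names)
    out = []
    for ct in uniq:
        mask = (clusters == ct).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster '{ct}' has fewer than 3 cells; skipped")
            continue
        in_m, out_m = dense[mask], dense[~mask]
        with np.errstate(invalid="ignore"):
            stat = scipy.stats.mannwhitneyu(in_m, out_m, axis=0, alternative="two-sided")
        pvals = np.where(np.isnan(stat.pvalue), 1.0, stat.pvalue)
        padj = bh_adjust(pvals)
        mean_in = norm_dense[mask].mean(axis=0)
        mean_out = norm_dense[~mask].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            specificity = np.where(mean_out > 0, mean_in / mean_out, np.where(mean_in > 0, np.inf, 0.0))
        pct_in = (in_m > 0).mean(axis=0)
        pct_out = (out_m > 0).mean(axis=0)
        keep = (padj < p_cut) & (pct_in > min_pct) & (specificity > min_specificity) & (mean_in > mean_out)
        for gi in np.flatnonzero(keep):
            out.append(
                MarkerRecord(
                    gene=genes[gi],
                    cluster=ct,
                    p=float(pvals[gi]),
                    padj=float(padj[gi]),
                    specificity=float(specificity[gi]),
                    pct_in=float(pct_in[gi]),
                    pct_out=float(pct_out[gi]),
                )
            )
    return out


def records_to_frame(records) -> pd.DataFrame:
    """Convert a list of dataclass records to a DataFrame."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])
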