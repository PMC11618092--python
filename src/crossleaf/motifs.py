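"""PWM scanning, DOF-site counting and background-matched motif enrichment.

Scoring is FIMO-like: the PWM's log2-odds against the background are
discretized onto an integer grid, the null score distribution is computed
exactly (within discretization) by dynamic programming over positions, and
the score threshold is the smallest score whose upper-tail probability under
the background does not exceed the per-position p-value threshold (the
DOF-site quantification uses p = 0.005).  Windows containing N are skipped;
both strands are scanned by default and overlapping hits all count.

Enrichment follows the permutation-rank protocol: per permutation a GC- and
length-matched background set is sampled, per-motif hypergeometric
enrichment of peaks-with-a-hit is computed, motifs are ranked within the
permutation, and ranks are averaged over the permutations (100 by default)
into a final ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import PWMModel
from .partition import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "MotifHit",
    "EnrichmentRecord",
    "PairedCountRecord",
    "pwm_logodds",
    "score_distribution",
    "score_threshold",
    "scan",
    "count_sites_near_tss",
    "paired_excess_test",
    "motif_enrichment",
    "top_k_overlap",
    "dof_core_pwm",
    "reverse_complement_pwm",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ScanParams:
    p_threshold: float = 0.005
    both_strands: bool = True
    score_bins: int = 1000

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")


@dataclass
class MotifHit:
    sequence_id: str
    offset: int  # 0-based window start on the forward strand
    strand: str  # '+' or '-'
    score: float  # log2-odds
    p: float  # match p-value under the background


@dataclass
class EnrichmentRecord:
    motif_id: str
    fg_hits: int
    bg_hits: float  # mean over permutations
    fold: float
    p: float  # median over permutations
    padj: float  # median BH-adjusted p over permutations
    rank_per_permutation: list = field(default_factory=list)
    padj_per_permutation: list = field(default_factory=list)
    mean_rank: float = np.nan


@dataclass
class PairedCountRecord:
    orthogroup: str
    sites_a: int
    sites_b: int


def dof_core_pwm(strength=0.97) -> PWMModel:
    """Synthetic DOF-core model: a near-deterministic PWM on the AAAG
    consensus (the core shared by DOF-family binding motifs)."""
    return PWMModel.from_consensus("DOFcore", "AAAG", strength=strength)


def pwm_logodds(pwm: PWMModel, background=None) -> np.ndarray:
    """Per-position log2-odds matrix log2(prob / background)."""
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must all be positive")
    if not np.allclose(bg.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    with np.errstate(divide="ignore"):
        return np.log2(pwm.probs / bg[:, None])


@dataclass
class ScoreDistribution:
    """Integerized null score distribution of a PWM under its background."""

    int_matrix: np.ndarray  # 4 x w rounded log-odds / step
    step: float
    support: np.ndarray  # integer scores with nonzero probability
    probs: np.ndarray
    background: np.ndarray

    def tail(self, int_score) -> float:
        """P(score >= int_score) under the background."""
        return float(self.probs[self.support >= int_score].sum())


def score_distribution(pwm: PWMModel, background=None, bins=1000) -> ScoreDistribution:
    """Exact (within discretization) null distribution of window scores.

    Log-odds are rounded to a grid of ``bins`` steps spanning the total
    score range; the distribution of the integer sum over positions is built
    by dynamic programming with per-base background probabilities.
    """
    L = pwm_logodds(pwm, background)
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    span = L.max(axis=0).sum() - L.min(axis=0).sum()
    step = span / bins if span > 0 else 1.0
    I = np.round(L / step).astype(np.int64)
    # DP over positions: arr[k] = P(partial integer score == base + k)
    arr = np.array([1.0])
    base = 0  # integer score of arr[0]
    for j in range(pwm.width):
        col = I[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(arr) + (cmax - cmin))
        for b in range(4):
            new[col[b] - cmin : col[b] - cmin + len(arr)] += bg[b] * arr
        arr = new
        base += cmin
    support = np.arange(base, base + len(arr))
    keep = arr > 0
    return ScoreDistribution(I, step, support[keep], arr[keep], bg)


def score_threshold(pwm: PWMModel, background=None, p_threshold=0.005, bins=1000):
    """Smallest integer score with tail probability <= p_threshold.

    Returns (int_threshold, dist).  If even the maximal score is more
    probable than ``p_threshold`` the maximum achievable score is used (and
    logged): only exact top-scoring windows will pass.
    """
    dist = score_distribution(pwm, background, bins)
    tails = np.cumsum(dist.probs[::-1])[::-1]  # tail at each support point
    ok = np.flatnonzero(tails <= p_threshold)
    if ok.size == 0:
        log.warning(
            "motif %s: p_threshold %g below the most extreme achievable tail %g; "
            "using the maximal score",
            pwm.motif_id, p_threshold, tails[-1],
        )
        t = int(dist.support[-1])
    else:
        t = int(dist.support[ok[0]])
    return t, dist


def reverse_complement_pwm(pwm: PWMModel) -> PWMModel:
    """Column-reversed, base-complemented PWM (scores the - strand)."""
    probs = pwm.probs[::-1, ::-1]
    bg = pwm.background[::-1]
    return PWMModel(pwm.motif_id, pwm.name, probs.copy(), bg.copy(), pwm.pseudocount)


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return out


def _window_scores(codes: np.ndarray, int_matrix: np.ndarray):
    """Integer score of every window; windows containing N get None (masked)."""
    w = int_matrix.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        c = codes[j : j + n]
        bad = c < 0
        valid &= ~bad
        scores += int_matrix[np.clip(c, 0, 3), j]
    return scores, valid


def scan(sequences: dict, pwm: PWMModel, params: ScanParams | None = None,
         background=None) -> list[MotifHit]:
    """Emit every window whose score meets the exact p-value threshold.

    Hits are sorted by (sequence_id, offset); the reported score is the
    float log2-odds and the p-value is the discretized-null tail at the
    window's score.  Minus-strand offsets refer to the forward-strand
    position of the window start.
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    params = params or ScanParams()
    t_int, dist = score_threshold(pwm, background, params.p_threshold, params.score_bins)
    L = pwm_logodds(pwm, background)
    strands = [("+", dist.int_matrix, L)]
    if params.both_strands:
        rc = reverse_complement_pwm(pwm)
        # use the same background as forward for the null; the rc matrix is
        # rounded on the same step so thresholds are directly comparable
        Lrc = pwm_logodds(rc, dist.background)
        Irc = np.round(Lrc / dist.step).astype(np.int64)
        strands.append(("-", Irc, Lrc))
    hits = []
    for sid in sorted(sequences):
        codes = _encode(sequences[sid].upper())
        for strand, I, Lmat in strands:
            scores, valid = _window_scores(codes, I)
            for off in np.flatnonzero(valid & (scores >= t_int)):
                fscore = float(Lmat[codes[off : off + pwm.width], np.arange(pwm.width)].sum())
                hits.append(
                    MotifHit(sid, int(off), strand, fscore, dist.tail(int(scores[off])))
                )
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# DOF-site counting near TSSs
# ---------------------------------------------------------------------------

def assign_peaks_to_tss(peaks, tss: pd.DataFrame, window=1500):
    """Assign each TSS-proximal peak to its closest TSS.

    A peak is proximal when its interval overlaps [TSS-window, TSS+window);
    a peak proximal to several TSSs goes to the one closest to the peak
    midpoint (ties to the lexicographically smaller gene id).  Returns
    {peak_id: gene}.
    """
    assignment = {}
    tss_by_chrom = {c: g for c, g in tss.groupby("chrom")}
    for p in peaks:
        cand = tss_by_chrom.get(p.chrom)
        if cand is None:
            continue
        lo, hi = cand["pos"] - window, cand["pos"] + window
        ovl = cand[(p.start < hi) & (p.end > lo)]
        if ovl.empty:
            continue
        dist = (ovl["pos"] - p.midpoint).abs()
        best = ovl.assign(_d=dist).sort_values(["_d", "gene"]).iloc[0]
        assignment[p.peak_id] = best["gene"]
    return assignment


def count_sites_near_tss(peaks, tss: pd.DataFrame, sequences: dict, pwm: PWMModel,
                         params: ScanParams | None = None, window=1500) -> dict:
    """Per-gene count of motif hits in TSS-proximal peaks (default +/-1500 bp).

    Every gene in the TSS table is reported (0 when it has no proximal
    peak).  A proximal peak lacking a sequence is an error.
    """
    params = params or ScanParams()
    assignment = assign_peaks_to_tss(peaks, tss, window)
    counts = {g: 0 for g in tss["gene"]}
    assigned_seqs = {}
    for p in peaks:
        gene = assignment.get(p.peak_id)
        if gene is None:
            continue
        seq = p.sequence if p.sequence is not None else sequences.get(p.peak_id)
        if seq is None:
            raise ValueError(f"peak {p.peak_id} has no sequence")
        assigned_seqs[p.peak_id] = (gene, seq)
    if assigned_seqs:
        hits = scan({pid: s for pid, (g, s) in assigned_seqs.items()}, pwm, params)
        for h in hits:
            counts[assigned_seqs[h.sequence_id][0]] += 1
    return counts


def paired_excess_test(pairs, direction="b") -> dict:
    """One-sided sign test for a systematic excess of sites in one species.

    Ties are dropped; p = P(X >= n_higher | n_informative, 0.5) where
    'higher' means more sites in the hypothesized species (``direction`` is
    'a' or 'b').  Raises when every pair is tied.
    """
    n_hi = n_lo = n_tie = 0
    for rec in pairs:
        hi, lo = (rec.sites_b, rec.sites_a) if direction == "b" else (rec.sites_a, rec.sites_b)
        if hi > lo:
            n_hi += 1
        elif hi < lo:
            n_lo += 1
        else:
            n_tie += 1
    n = n_hi + n_lo
    if n == 0:
        raise ValueError("no informative pairs (all ties)")
    p = float(scipy.stats.binom.sf(n_hi - 1, n, 0.5))
    return {"n_higher": n_hi, "n_lower": n_lo, "n_ties": n_tie, "p": p}


# ---------------------------------------------------------------------------
# permutation-rank enrichment
# ---------------------------------------------------------------------------

def _gc_content(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    return (s.count("G") + s.count("C")) / acgt if acgt else 0.0


def _strata(values, edges):
    return np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)


def motif_enrichment(fg_ids, peaks, sequences, motif_library, B=100, bg_multiple=2,
                     seed=0, scan_p_threshold=1e-4, alpha=0.05) -> list[EnrichmentRecord]:
    """Rank motifs by enrichment in foreground peaks over matched backgrounds.

    Per permutation a background set GC-decile- and length-quartile-matched
    to the foreground is sampled without replacement from the non-foreground
    peaks; per motif the hypergeometric enrichment p of peaks-with-a-hit in
    foreground vs background is computed, and motifs are ranked by p within
    the permutation.  The mean of a motif's rank over the ``B`` permutations
    is the final ordering (rank 1 = most consistently enriched).
    """
    fg_ids = list(fg_ids)
    all_ids = [p.peak_id for p in peaks]
    id_set = set(all_ids)
    missing = [f for f in fg_ids if f not in id_set]
    if missing:
        raise ValueError(f"foreground peaks not in peak set: {missing[:3]}...")
    seqs = {}
    for p in peaks:
        s = p.sequence if p.sequence is not None else sequences.get(p.peak_id)
        if s is None:
            raise ValueError(f"peak {p.peak_id} has no sequence")
        seqs[p.peak_id] = s

    # binary hit matrix, computed once
    params = ScanParams(p_threshold=scan_p_threshold)
    hit = np.zeros((len(all_ids), len(motif_library)), dtype=bool)
    pos_of = {pid: i for i, pid in enumerate(all_ids)}
    for mj, pwm in enumerate(motif_library):
        for h in scan(seqs, pwm, params):
            hit[pos_of[h.sequence_id], mj] = True

    gc = np.array([_gc_content(seqs[pid]) for pid in all_ids])
    length = np.array([len(seqs[pid]) for pid in all_ids])
    gc_edges = np.quantile(gc, np.linspace(0, 1, 11))
    gc_edges[0], gc_edges[-1] = -np.inf, np.inf
    len_edges = np.quantile(length, np.linspace(0, 1, 5))
    len_edges[0], len_edges[-1] = -np.inf, np.inf
    stratum = _strata(gc, gc_edges) * 10 + _strata(length, len_edges)

    is_fg = np.array([pid in set(fg_ids) for pid in all_ids])
    bg_pool = np.flatnonzero(~is_fg)
    fg_idx = np.flatnonzero(is_fg)
    if len(bg_pool) < bg_multiple * len(fg_idx):
        raise ValueError("not enough non-foreground peaks for the requested background size")

    fg_strata, fg_counts = np.unique(stratum[fg_idx], return_counts=True)
    pool_by_stratum = {s: bg_pool[stratum[bg_pool] == s] for s in np.unique(stratum[bg_pool])}
    rng = np.random.default_rng(seed)
    n_motifs = len(motif_library)
    ranks = np.empty((B, n_motifs))
    pmat = np.empty((B, n_motifs))
    padjmat = np.empty((B, n_motifs))
    bg_hit_counts = np.zeros(n_motifs)
    warned = False
    for b in range(B):
        chosen = []
        for s, c in zip(fg_strata, fg_counts):
            want = bg_multiple * c
            pool = pool_by_stratum.get(s, np.empty(0, int))
            if len(pool) < want:
                if not warned:
                    log.warning("insufficient matched background in a stratum; relaxing to nearest strata")
                    warned = True
                # relax: nearest strata by GC bin distance
                order = sorted(pool_by_stratum, key=lambda t: abs(t - s))
                pool = np.concatenate([pool_by_stratum[t] for t in order])[: max(want, len(pool))]
            take = rng.choice(pool, size=min(want, len(pool)), replace=False)
            chosen.append(take)
        bg_idx = np.concatenate(chosen) if chosen else np.empty(0, int)
        n_fg, n_bg = len(fg_idx), len(bg_idx)
        fg_with = hit[fg_idx].sum(axis=0)
        bg_with = hit[bg_idx].sum(axis=0)
        bg_hit_counts += bg_with
        # hypergeometric: draws = foreground peaks, successes = peaks with hit
        M = n_fg + n_bg
        K = fg_with + bg_with
        pvals = scipy.stats.hypergeom.sf(fg_with - 1, M, K, n_fg)
        pmat[b] = pvals
        padjmat[b] = bh_adjust(pvals)
        ranks[b] = scipy.stats.rankdata(pvals, method="average")
    mean_rank = ranks.mean(axis=0)
    records = []
    n_fg = len(fg_idx)
    for mj, pwm in enumerate(motif_library):
        fg_with = int(hit[fg_idx, mj].sum())
        bg_mean = float(bg_hit_counts[mj] / B)
        bg_frac = bg_mean / (bg_multiple * n_fg) if n_fg else 0.0
        fold = (fg_with / n_fg) / bg_frac if (n_fg and bg_frac > 0) else np.inf if fg_with else 0.0
        records.append(
            EnrichmentRecord(
                motif_id=pwm.motif_id,
                fg_hits=fg_with,
                bg_hits=bg_mean,
                fold=float(fold),
                p=float(np.median(pmat[:, mj])),
                padj=float(np.median(padjmat[:, mj])),
                rank_per_permutation=ranks[:, mj].tolist(),
                padj_per_permutation=padjmat[:, mj].tolist(),
                mean_rank=float(mean_rank[mj]),
            )
        )
    records.sort(key=lambda r: r.mean_rank)
    return records


def top_k_overlap(enrich_a, enrich_b, k=25, alpha=0.05):
    """Overlap of the two species' top-k enriched motifs.

    Each side's candidates are its significantly enriched motifs (median
    BH-adjusted p < alpha) ordered by mean rank; the top k (all of them, if
    fewer are significant) are overlap-tested against a universe of the full
    motif library.
    """
    from .orthology import OrthogroupSet, overlap_test

    lib = {r.motif_id for r in enrich_a} | {r.motif_id for r in enrich_b}
    universe = len(lib)

    def top(records):
        sig = [r for r in sorted(records, key=lambda r: r.mean_rank) if r.padj < alpha]
        if len(sig) < k:
            log.warning("only %d significant motifs (< k=%d); using all", len(sig), k)
        return frozenset(r.motif_id for r in sig[:k])

    set_a = OrthogroupSet(top(enrich_a), universe)
    set_b = OrthogroupSet(top(enrich_b), universe)
    return overlap_test(set_a, set_b)
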