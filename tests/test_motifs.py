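import itertools
import math

import numpy as np
import pytest

from crossleaf.io import PWMModel
from crossleaf.motifs import (
    EnrichmentRecord,
    PairedCountRecord,
    ScanParams,
    count_sites_near_tss,
    dof_core_pwm,
    motif_enrichment,
    paired_excess_test,
    pwm_logodds,
    reverse_complement_pwm,
    revcomp,
    scan,
    score_distribution,
    score_threshold,
    top_k_overlap,
)


def _random_pwm(rng, width):
    probs = rng.dirichlet(np.ones(4), size=width).T
    return PWMModel(f"rnd{width}", "rnd", probs)


class TestLogOdds:
    def test_uniform_pwm_uniform_background_is_zero(self):
        pwm = PWMModel("u", "u", np.full((4, 3), 0.25))
        assert np.allclose(pwm_logodds(pwm), 0.0)

    def test_hand_algebra_pseudocounted_column(self):
        pwm = PWMModel.from_counts("x", "x", np.array([[1], [0], [0], [0]]), pseudocount=0.01)
        L = pwm_logodds(pwm)
        assert L[0, 0] == pytest.approx(math.log2((1.01 / 1.04) / 0.25), abs=1e-12)

    def test_zero_background_raises(self):
        pwm = PWMModel("u", "u", np.full((4, 2), 0.25))
        with pytest.raises(ValueError, match="positive"):
            pwm_logodds(pwm, [0.5, 0.5, 0.0, 0.0])

    def test_reverse_complement_symmetry(self, rng):
        pwm = _random_pwm(rng, 5)
        L = pwm_logodds(pwm)
        Lrc = pwm_logodds(reverse_complement_pwm(pwm), pwm.background[::-1])
        assert np.allclose(Lrc, L[::-1, ::-1])


class TestScoreDistribution:
    def test_dp_equals_exhaustive_enumeration(self, rng):
        """DP tail probabilities equal brute-force enumeration over all 4^w
        words scored with the same integerized matrix."""
        for _ in range(5):
            pwm = _random_pwm(rng, 6)
            dist = score_distribution(pwm, bins=500)
            counts = {}
            for word in itertools.product(range(4), repeat=6):
                s = int(sum(dist.int_matrix[b, j] for j, b in enumerate(word)))
                pr = np.prod([pwm.background[b] for b in word])
                counts[s] = counts.get(s, 0.0) + pr
            support = np.array(sorted(counts))
            probs = np.array([counts[s] for s in support])
            assert np.array_equal(support, dist.support)
            assert np.allclose(probs, dist.probs, atol=1e-12)
            # spot-check the tail at a mid support point
            mid = support[len(support) // 2]
            assert dist.tail(mid) == pytest.approx(probs[support >= mid].sum(), abs=1e-12)

    def test_consensus_4mer_tail_is_1_over_256(self):
        t, dist = score_threshold(dof_core_pwm(), p_threshold=0.005)
        assert t == dist.support[-1]
        assert dist.tail(t) == pytest.approx(1 / 256)

    def test_threshold_1_accepts_everything(self):
        pwm = dof_core_pwm()
        t, dist = score_threshold(pwm, p_threshold=1.0)
        assert t == dist.support[0]

    def test_unreachable_threshold_falls_back_to_max(self):
        t, dist = score_threshold(dof_core_pwm(), p_threshold=1e-6)
        assert t == dist.support[-1]


class TestScan:
    def test_plus_strand_consensus_hit(self):
        hits = scan({"s1": "TTAAAGTT"}, dof_core_pwm(),
                    ScanParams(p_threshold=0.005, both_strands=False))
        assert [(h.sequence_id, h.offset, h.strand) for h in hits] == [("s1", 2, "+")]

    def test_minus_strand_hit_on_cttt(self):
        # CTTT is the reverse complement of AAAG
        hits = scan({"s1": "GGCTTTGG"}, dof_core_pwm(), ScanParams(p_threshold=0.005))
        assert [(h.offset, h.strand) for h in hits] == [(2, "-")]

    def test_short_sequence_yields_no_hits(self):
        assert scan({"s": "AA"}, dof_core_pwm(), ScanParams(p_threshold=0.005)) == []

    def test_windows_with_n_are_skipped(self):
        hits = scan({"s": "AANGAAAG"}, dof_core_pwm(),
                    ScanParams(p_threshold=0.005, both_strands=False))
        assert [(h.offset,) for h in hits] == [(4,)]

    def test_matches_bruteforce_window_scorer(self, rng):
        """Oracle: naive per-window loops with the same integerized scores
        must reproduce the hit set exactly."""
        pwm = _random_pwm(rng, 6)
        params = ScanParams(p_threshold=0.01)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=200)) for i in range(5)
        }
        hits = scan(seqs, pwm, params)
        got = {(h.sequence_id, h.offset, h.strand) for h in hits}
        t_int, dist = score_threshold(pwm, None, 0.01)
        I_fwd = dist.int_matrix
        rc = reverse_complement_pwm(pwm)
        I_rc = np.round(pwm_logodds(rc, dist.background) / dist.step).astype(int)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = set()
        for sid, seq in seqs.items():
            for off in range(len(seq) - 5):
                word = [idx[c] for c in seq[off : off + 6]]
                if sum(I_fwd[b, j] for j, b in enumerate(word)) >= t_int:
                    expected.add((sid, off, "+"))
                if sum(I_rc[b, j] for j, b in enumerate(word)) >= t_int:
                    expected.add((sid, off, "-"))
        assert got == expected

    def test_revcomp_sequence_mirror(self, rng):
        """Scanning a sequence equals scanning its reverse complement with
        strands exchanged and offsets mirrored."""
        pwm = _random_pwm(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        params = ScanParams(p_threshold=0.01)
        fwd = scan({"s": seq}, pwm, params)
        rev = scan({"s": revcomp(seq)}, pwm, params)
        n = len(seq)
        mirrored = {(n - h.offset - pwm.width, "+-"[h.strand == "+"]) for h in rev}
        assert {(h.offset, h.strand) for h in fwd} == mirrored


class TestTssCounting:
    def test_peak_outside_window_excluded(self, small_landscape):
        import pandas as pd

        from crossleaf.io import PeakRecord

        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [5000], "strand": ["+"], "gene": ["g1"]})
        pwm = dof_core_pwm()
        far = PeakRecord("chr1", 6600, 6700, "far", {}, "A" * 100)
        near = PeakRecord("chr1", 6400, 6490, "near", {}, "T" * 90)
        counts = count_sites_near_tss([far, near], tss, {}, pwm, window=1500)
        from crossleaf.motifs import assign_peaks_to_tss

        asn = assign_peaks_to_tss([far, near], tss, window=1500)
        assert "far" not in asn and asn["near"] == "g1"
        assert counts == {"g1": 0}

    def test_equidistant_peak_lexicographic_gene(self):
        import pandas as pd

        from crossleaf.io import PeakRecord
        from crossleaf.motifs import assign_peaks_to_tss

        tss = pd.DataFrame(
            {"chrom": "chr1", "pos": [1000, 3000], "strand": "+", "gene": ["gB", "gA"]}
        )
        peak = PeakRecord("chr1", 1950, 2050, "pk", {}, "A" * 100)
        asn = assign_peaks_to_tss([peak], tss, window=1500)
        assert asn["pk"] == "gA"

    def test_counts_equal_planted_truth_at_strict_threshold(self):
        """With a threshold admitting only the exact consensus — and a GC-rich
        background in which the A/T-rich consensus cannot arise by chance —
        per-gene hit counts equal the planted counts exactly."""
        from crossleaf.simulate import SimConfig, simulate_expression, simulate_regulatory_landscape

        cfg = SimConfig(seed=31, n_genes_per_species=120, gc_content=0.9,
                        markers_per_celltype=0)
        a, b, orth, truth = simulate_expression(cfg)
        land = simulate_regulatory_landscape(cfg, truth, a, b)["species_b"]
        pwm = PWMModel.from_consensus("planted", cfg.planted_motif)
        strict = 1.5 / 4 ** len(cfg.planted_motif)
        counts = count_sites_near_tss(
            land["peaks"], land["tss"], land["sequences"], pwm,
            ScanParams(p_threshold=strict), window=1500,
        )
        planted_per_gene = {}
        asn = land["assigned_gene"]
        from crossleaf.motifs import assign_peaks_to_tss

        proximal = assign_peaks_to_tss(land["peaks"], land["tss"], 1500)
        for pid, sites in truth.planted_sites["species_b"].items():
            if pid in proximal:
                g = proximal[pid]
                planted_per_gene[g] = planted_per_gene.get(g, 0) + len(sites)
        for g, c in planted_per_gene.items():
            assert counts[g] == c
        assert sum(counts.values()) == sum(planted_per_gene.values())


class TestSignTest:
    def test_closed_form_examples(self):
        res = paired_excess_test(
            [PairedCountRecord(f"o{i}", 0, 1) for i in range(9)]
            + [PairedCountRecord("o9", 1, 0)],
            direction="b",
        )
        assert res["n_higher"] == 9 and res["n_lower"] == 1
        assert res["p"] == pytest.approx(11 / 1024)
        res = paired_excess_test(
            [PairedCountRecord(f"o{i}", 0, 1) for i in range(5)]
            + [PairedCountRecord(f"p{i}", 1, 0) for i in range(5)],
        )
        assert res["p"] == pytest.approx(0.623, abs=1e-3)

    def test_all_ties_raise(self):
        with pytest.raises(ValueError, match="informative"):
            paired_excess_test([PairedCountRecord("o", 2, 2)] * 3)

    def test_matches_scipyfree_binomial_sum_all_n_le_20(self):
        for n in range(1, 21):
            for k in range(n + 1):
                pairs = [PairedCountRecord(f"h{i}", 0, 1) for i in range(k)] + [
                    PairedCountRecord(f"l{i}", 1, 0) for i in range(n - k)
                ]
                res = paired_excess_test(pairs, direction="b")
                exact = sum(math.comb(n, j) for j in range(k, n + 1)) / 2**n
                assert res["p"] == pytest.approx(exact, rel=1e-12)


class TestEnrichment:
    def test_planted_motif_ranks_first_and_stably(self, small_sim, small_landscape):
        from crossleaf.pipeline import _motif_library

        cfg, *_, truth = small_sim
        land = small_landscape["species_b"]
        lib = _motif_library(cfg)
        fg_genes = {g for (s, g), v in truth.partition_sign.items()
                    if s == "species_b" and v == -1}
        fg = [p.peak_id for p in land["peaks"]
              if land["assigned_gene"][p.peak_id] in fg_genes and p.peak_id.endswith("p")]
        e1 = motif_enrichment(fg, land["peaks"], land["sequences"], lib, B=50, seed=1)
        e2 = motif_enrichment(fg, land["peaks"], land["sequences"], lib, B=50, seed=2)
        assert e1[0].motif_id == "PLANTED_DOFLIKE"
        assert e1[0].mean_rank == 1.0
        import scipy.stats

        r1 = {r.motif_id: r.mean_rank for r in e1}
        r2 = {r.motif_id: r.mean_rank for r in e2}
        ids = sorted(r1)
        rho = scipy.stats.spearmanr([r1[i] for i in ids], [r2[i] for i in ids]).statistic
        assert rho >= 0.9

    def test_null_foreground_is_calibrated(self, small_sim, small_landscape):
        """A random foreground yields no motif significant in >=95% of
        permutations."""
        from crossleaf.pipeline import _motif_library

        cfg, *_ , truth = small_sim
        land = small_landscape["species_a"]
        lib = _motif_library(cfg)
        rng = np.random.default_rng(3)
        ids = [p.peak_id for p in land["peaks"]]
        fg = list(rng.choice(ids, size=40, replace=False))
        recs = motif_enrichment(fg, land["peaks"], land["sequences"], lib, B=50, seed=4)
        for r in recs:
            frac_sig = np.mean(np.array(r.padj_per_permutation) < 0.05)
            assert frac_sig < 0.95


class TestTopKOverlap:
    def _mk(self, motif_ids, sig_ids, rank_start=1):
        out = []
        for i, mid in enumerate(motif_ids):
            out.append(EnrichmentRecord(
                motif_id=mid, fg_hits=10, bg_hits=1.0, fold=2.0,
                p=0.001 if mid in sig_ids else 0.9,
                padj=0.01 if mid in sig_ids else 0.9,
                mean_rank=float(i + rank_start),
            ))
        return out

    def test_identical_inputs_overlap_fully(self):
        ids = [f"m{i}" for i in range(20)]
        sig = set(ids[:8])
        ea = self._mk(ids, sig)
        res = top_k_overlap(ea, ea, k=8)
        assert res.n_overlap == 8
        assert res.p < 1e-4

    def test_disjoint_top_sets_not_significant(self):
        ids = [f"m{i}" for i in range(24)]
        ea = self._mk(ids, set(ids[:6]))
        eb = self._mk(ids[6:] + ids[:6], set(ids[6:12]))
        res = top_k_overlap(ea, eb, k=6)
        assert res.n_overlap == 0
        assert res.p >= 0.5
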