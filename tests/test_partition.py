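import numpy as np
import pandas as pd
import pytest

from crossleaf.partition import (
    PseudobulkMatrix,
    bh_adjust,
    dark_partition_test,
    find_markers,
    partition_test,
    pseudobulk,
    _irls,
)
from crossleaf.simulate import SimConfig, simulate_expression


def _toy_pb(counts_by_ct, times=(0.0, 12.0), batches=("b0", "b1")):
    """Build a PseudobulkMatrix from {cell_type: {gene: base_count}}."""
    cols, meta = {}, []
    for ct, genes in counts_by_ct.items():
        for t in times:
            for b in batches:
                name = f"{ct}|{t:g}|{b}"
                cols[name] = [genes[g] for g in sorted(genes)]
                meta.append({"sample": name, "cell_type": ct, "time_h": t,
                             "batch": b, "n_cells": 10})
    counts = pd.DataFrame(cols, index=sorted(next(iter(counts_by_ct.values()))))
    samples = pd.DataFrame(meta).set_index("sample")
    samples["size_factor"] = 1.0
    return PseudobulkMatrix(counts, samples)


class TestBH:
    def test_matches_step_up_on_hand_example(self):
        # hand-computed BH for (0.01, 0.02, 0.03, 0.04, 0.9):
        # p*(m/rank) = .05, .05, .05, .05, .9; step-up -> (.05,.05,.05,.05,.9)
        out = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.9])
        assert np.allclose(out, [0.05, 0.05, 0.05, 0.05, 0.9])

    def test_padj_monotone_and_at_least_p(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPseudobulk:
    def test_group_sums_exhaustive(self, small_sim):
        _, adata, *_ = small_sim
        pb = pseudobulk(adata, min_cells=1)
        X = np.asarray(adata.X.todense())
        for sample in pb.samples.index:
            ct, t, b = pb.samples.loc[sample, ["cell_type", "time_h", "batch"]]
            mask = (
                (adata.obs["cell_type"] == ct)
                & (adata.obs["time_h"] == t)
                & (adata.obs["batch"] == b)
            ).to_numpy()
            assert np.array_equal(pb.counts[sample].to_numpy(), X[mask].sum(axis=0))
            assert pb.samples.loc[sample, "n_cells"] == mask.sum()

    def test_summation_of_two_cells(self):
        import anndata as ad
        import scipy.sparse as sp

        obs = pd.DataFrame(
            {"species": "s", "cell_type": "m", "time_h": 0.0, "batch": "b0"},
            index=pd.Index(["c1", "c2"], name="cell"),
        )
        adata = ad.AnnData(X=sp.csr_matrix(np.array([[3], [4]])), obs=obs,
                           var=pd.DataFrame(index=pd.Index(["g"], name="gene")))
        pb = pseudobulk(adata, min_cells=1)
        assert pb.counts.iloc[0, 0] == 7

    def test_missing_grouping_key_raises(self, small_sim):
        _, adata, *_ = small_sim
        with pytest.raises(KeyError, match="nonsense"):
            pseudobulk(adata, group_by=("nonsense",))

    def test_min_cells_filter_can_empty(self, small_sim):
        _, adata, *_ = small_sim
        with pytest.raises(ValueError, match="min_cells"):
            pseudobulk(adata, min_cells=10_000)


class TestPartitionTest:
    def test_identical_counts_no_effect(self):
        pb = _toy_pb({"mesophyll": {"g1": 50}, "bundle_sheath": {"g1": 50}})
        recs, _ = partition_test(pb, "mesophyll", "bundle_sheath")
        assert abs(recs[0].log2fc) < 0.05
        assert recs[0].p > 0.5

    def test_symmetry_under_cell_swap(self):
        pb = _toy_pb({"mesophyll": {"g1": 80, "g2": 10},
                      "bundle_sheath": {"g1": 20, "g2": 40}})
        r_ab, _ = partition_test(pb, "mesophyll", "bundle_sheath")
        r_ba, _ = partition_test(pb, "bundle_sheath", "mesophyll")
        for a, b in zip(r_ab, r_ba):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-6)
            assert a.p == pytest.approx(b.p, rel=1e-6)
            assert a.favoured_cell == b.favoured_cell

    def test_requires_two_samples_per_celltype(self):
        pb = _toy_pb({"mesophyll": {"g1": 5}, "bundle_sheath": {"g1": 5}},
                     times=(0.0,), batches=("b0",))
        with pytest.raises(ValueError, match="< 2"):
            partition_test(pb, "mesophyll", "bundle_sheath")

    def test_all_zero_genes_excluded(self):
        pb = _toy_pb({"mesophyll": {"g1": 5, "g2": 0},
                      "bundle_sheath": {"g1": 5, "g2": 0}})
        recs, excluded = partition_test(pb, "mesophyll", "bundle_sheath")
        assert excluded == ["g2"]
        assert [r.gene for r in recs] == ["g1"]

    def test_irls_matches_statsmodels_glm(self, rng):
        """Independent oracle: statsmodels NB GLM with the same fixed
        dispersion must give the same coefficients and log-likelihood."""
        import statsmodels.api as sm

        n = 12
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.uniform(0, 12, n)])
        offset = rng.normal(0, 0.1, n)
        y = rng.poisson(np.exp(0.5 + 0.8 * X[:, 1] + 0.05 * X[:, 2] + offset))
        alpha = 0.05
        beta, mu, ll, conv = _irls(y.astype(float), X, offset, alpha)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=offset).fit()
        assert conv
        assert np.allclose(beta, ref.params, atol=1e-5)
        assert ll == pytest.approx(ref.llf, abs=1e-5)

    def test_lrt_close_to_wald_at_large_n(self, rng):
        """At n=200 samples the LRT statistic should agree with the square
        of the Wald z (p within a factor of 1.5)."""
        import scipy.stats
        import statsmodels.api as sm

        n = 200
        X_full = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.uniform(0, 12, n)])
        y = rng.poisson(np.exp(1.0 + 0.3 * X_full[:, 1] + 0.02 * X_full[:, 2]))
        offset = np.zeros(n)
        alpha = 1e-6
        _, _, ll_full, _ = _irls(y.astype(float), X_full, offset, alpha)
        _, _, ll_red, _ = _irls(y.astype(float), X_full[:, [0, 2]], offset, alpha)
        lrt = 2 * (ll_full - ll_red)
        p_lrt = scipy.stats.chi2.sf(lrt, 1)
        ref = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
        p_wald = 2 * scipy.stats.norm.sf(abs(ref.params[1] / ref.bse[1]))
        assert p_lrt < 0.05  # the planted effect is detected by both routes
        ratio = p_lrt / p_wald
        assert 1 / 1.5 < ratio < 1.5

    def test_planted_effect_recovered_with_correct_sign(self):
        cfg = SimConfig(seed=21, n_genes_per_species=200, n_celltypes=2,
                        cells_per_type_per_time=100, markers_per_celltype=0)
        adata, _, _, truth = simulate_expression(cfg)
        pb = pseudobulk(adata)
        recs, _ = partition_test(pb, "mesophyll", "bundle_sheath")
        planted = {g: s for (spc, g), s in truth.partition_sign.items() if spc == "species_a"}
        hits = [r for r in recs if r.gene in planted and r.padj < 0.05]
        assert len(hits) / len(planted) >= 0.9
        sign_ok = sum(np.sign(r.log2fc) == planted[r.gene] for r in hits)
        assert sign_ok / len(hits) >= 0.99


class TestDarkPartition:
    def test_identical_profiles_not_significant(self):
        pb = _toy_pb({"mesophyll": {"g1": 30}, "bundle_sheath": {"g1": 30}})
        recs, _ = dark_partition_test(pb, "mesophyll", "bundle_sheath")
        assert all(r.p > 0.1 for r in recs)

    def test_cell_a_only_expression_favours_cell_a(self):
        pb = _toy_pb({"mesophyll": {"g1": 55}, "bundle_sheath": {"g1": 0}},
                     times=(0.0,), batches=("b0", "b1"))
        recs, _ = dark_partition_test(pb, "mesophyll", "bundle_sheath")
        assert recs[0].favoured_cell == "mesophyll"
        assert recs[0].log2fc > 0

    def test_planted_effect_detected_at_0h(self):
        cfg = SimConfig(seed=22, n_genes_per_species=100, n_celltypes=2,
                        cells_per_type_per_time=100, markers_per_celltype=0)
        adata, _, _, truth = simulate_expression(cfg)
        pb = pseudobulk(adata)
        recs, _ = dark_partition_test(pb, "mesophyll", "bundle_sheath")
        planted = {g for (spc, g) in truth.partition_sign if spc == "species_a"}
        sig = {r.gene for r in recs if r.padj < 0.05}
        assert len(sig & planted) / len(planted) >= 0.8


class TestMarkers:
    def test_planted_markers_recovered_with_high_precision(self, small_sim):
        cfg, adata, *_ , truth = small_sim
        recs = find_markers(adata, "cell_type", p_cut=0.01, min_pct=0.1,
                            min_specificity=1.25)
        truth_m = truth.markers["species_a"]
        # precision against genes planted with any cell-type-elevated effect
        def elevated(gene, ct):
            if truth_m.get(gene) == ct:
                return True
            s = truth.partition_sign.get(("species_a", gene), 0)
            return (ct == "mesophyll" and s > 0) or (ct == "bundle_sheath" and s < 0)

        assert recs
        prec = np.mean([elevated(r.gene, r.cluster) for r in recs])
        assert prec >= 0.9
        # planted markers recalled
        found = {(r.gene, r.cluster) for r in recs}
        recall = np.mean([(g, ct) in found for g, ct in truth_m.items()])
        assert recall >= 0.9

    def test_uniform_gene_not_returned(self):
        import anndata as ad
        import scipy.sparse as sp

        rng = np.random.default_rng(1)
        X = rng.poisson(5.0, size=(60, 3))
        obs = pd.DataFrame(
            {"species": "s", "cell_type": ["a"] * 30 + ["b"] * 30,
             "time_h": 0.0, "batch": "b0"},
            index=pd.Index([f"c{i}" for i in range(60)], name="cell"),
        )
        adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs,
                           var=pd.DataFrame(index=pd.Index(["g1", "g2", "g3"], name="gene")))
        recs = find_markers(adata, "cell_type", p_cut=0.05, min_pct=0.1)
        assert recs == []

    def test_exclusive_gene_gets_pct_one_and_inf_specificity(self):
        import anndata as ad
        import scipy.sparse as sp

        X = np.zeros((40, 2))
        X[:20, 0] = 7  # gene g1 only in cluster a
        X[:, 1] = 5
        obs = pd.DataFrame(
            {"species": "s", "cell_type": ["a"] * 20 + ["b"] * 20,
             "time_h": 0.0, "batch": "b0"},
            index=pd.Index([f"c{i}" for i in range(40)], name="cell"),
        )
        adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs,
                           var=pd.DataFrame(index=pd.Index(["g1", "g2"], name="gene")))
        recs = find_markers(adata, "cell_type", p_cut=0.05, min_pct=0.1)
        rec = next(r for r in recs if r.gene == "g1" and r.cluster == "a")
        assert rec.pct_in == 1.0 and rec.pct_out == 0.0
        assert np.isinf(rec.specificity)
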