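"""End-to-end orchestration of the cross-species pipeline on simulated data.

``run_all`` executes simulate -> partition (both species) -> cross-species
classification/conservation/similarity -> motif enrichment and DOF-site
counting -> chromatin assignment/normalization/tests -> light response, and
writes a machine-readable run report including truth-recovery metrics.
Thresholds default to the protocol's printed values (partition alpha 0.05,
marker p 0.01 / min.pct 0.1 / specificity 1.25, motif-site p 0.005, TSS
window 1,500 bp, gene window 2,000 bp, top-25 overlap, 100 permutations,
minimum trend-cluster size 10).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import SimConfig, simulate_expression, simulate_regulatory_landscape, write_simulation
from .partition import pseudobulk, partition_test, find_markers, records_to_frame
from .orthology import classify_partitioning, marker_conservation, celltype_similarity, overlap_test, to_orthogroups
from .motifs import (
    PairedCountRecord,
    ScanParams,
    count_sites_near_tss,
    motif_enrichment,
    paired_excess_test,
)
from .io import PWMModel
from .chromatin import assign_gene_peak, minmax_normalize, accessibility_test, link_peaks
from .light import light_de, significant_genes, trend_cluster

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults mirror the protocol's printed values."""

    sim: SimConfig = field(default_factory=SimConfig)
    alpha: float = 0.05
    marker_p: float = 0.01
    marker_min_pct: float = 0.1
    marker_specificity: float = 1.25
    motif_site_p: float = 0.005
    tss_window: int = 1500
    gene_window: int = 2000
    top_k: int = 25
    n_permutations: int = 100
    min_cluster_size: int = 10
    min_cells: int = 3
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _motif_library(cfg: SimConfig, n_motifs=10, seed=12345):
    """A small scanning library: the planted DOF-like consensus plus random
    consensus motifs of the same width."""
    rng = np.random.default_rng(seed)
    lib = [PWMModel.from_consensus("PLANTED_DOFLIKE", cfg.planted_motif)]
    bases = np.array(list("ACGT"))
    for i in range(n_motifs - 1):
        cons = "".join(rng.choice(bases, size=len(cfg.planted_motif)))
        lib.append(PWMModel.from_consensus(f"RANDOM{i:02d}", cons))
    return lib


def run_all(config: RunConfig) -> dict:
    """Run every stage on one simulated two-species dataset.

    Returns the run report (also written to <outdir>/report.json when an
    output directory is configured, alongside stage TSV outputs).
    """
    cfg = config
    report = {
        "version": __version__,
        "seed": cfg.sim.seed,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "stages": {},
    }

    # ----- simulate
    adata_a, adata_b, orthology, truth = simulate_expression(cfg.sim)
    landscape = simulate_regulatory_landscape(cfg.sim, truth, adata_a, adata_b)
    report["stages"]["simulate"] = {
        "n_genes": int(adata_a.n_vars),
        "n_cells_per_species": int(adata_a.n_obs),
        "n_orthology_rows": int(len(orthology)),
    }

    # ----- partitioning per species
    partition = {}
    for name, adata in (("species_a", adata_a), ("species_b", adata_b)):
        pb = pseudobulk(adata, min_cells=cfg.min_cells)
        recs, excluded = partition_test(pb, "mesophyll", "bundle_sheath", cfg.alpha)
        partition[name] = {"pb": pb, "records": recs, "excluded": excluded}
        report["stages"][f"partition_{name}"] = {
            "n_tested": len(recs),
            "n_significant": sum(r.padj < cfg.alpha for r in recs),
            "n_excluded_all_zero": len(excluded),
        }

    # ----- cross-species classification
    class_recs, class_report = classify_partitioning(
        partition["species_a"]["records"], partition["species_b"]["records"],
        orthology, alpha=cfg.alpha,
    )
    n_cons = sum(r.klass == "consistent" for r in class_recs)
    n_diff = sum(r.klass == "differential" for r in class_recs)
    truth_class = truth.orthogroup_class
    correct = sum(
        truth_class.get(r.orthogroup) == r.klass
        for r in class_recs if truth_class.get(r.orthogroup) in ("consistent", "differential")
    )
    evaluable = sum(
        truth_class.get(r.orthogroup) in ("consistent", "differential") for r in class_recs
    )
    report["stages"]["crossspecies"] = {
        "n_consistent": n_cons,
        "n_differential": n_diff,
        **class_report,
        "class_accuracy_vs_truth": (correct / evaluable) if evaluable else None,
    }

    # planted-partition recovery
    sig_a = {r.gene for r in partition["species_a"]["records"] if r.padj < cfg.alpha}
    planted_a = {g for (spc, g), s in truth.partition_sign.items() if spc == "species_a"}
    sens = len(sig_a & planted_a) / len(planted_a) if planted_a else None
    report["stages"]["crossspecies"]["partition_sensitivity_species_a"] = sens

    # ----- markers + conservation + similarity
    markers = {}
    for name, adata in (("species_a", adata_a), ("species_b", adata_b)):
        recs = find_markers(adata, "cell_type", cfg.marker_p, cfg.marker_min_pct,
                            cfg.marker_specificity)
        by_ct = {}
        for r in recs:
            by_ct.setdefault(r.cluster, set()).add(r.gene)
        for ct in cfg.sim.celltypes:
            by_ct.setdefault(ct, set())
        markers[name] = by_ct
    conservation = marker_conservation(markers["species_a"], markers["species_b"], orthology)
    sim_mat, best_match = celltype_similarity(markers["species_a"], markers["species_b"], orthology)
    report["stages"]["markers"] = {
        "conservation": conservation.reset_index().to_dict(orient="records"),
        "best_match": best_match,
    }

    # ----- motifs: enrichment in species-B bundle-sheath-swap foreground
    lib = _motif_library(cfg.sim)
    land_b = landscape["species_b"]
    fg_genes = {
        g for (spc, g), s in truth.partition_sign.items()
        if spc == "species_b" and s == -1
    }
    fg_ids = [p.peak_id for p in land_b["peaks"]
              if land_b["assigned_gene"][p.peak_id] in fg_genes and p.peak_id.endswith("p")]
    enrich = motif_enrichment(fg_ids, land_b["peaks"], land_b["sequences"], lib,
                              B=cfg.n_permutations, seed=cfg.sim.seed)
    planted_rank = next(r.mean_rank for r in enrich if r.motif_id == "PLANTED_DOFLIKE")
    report["stages"]["motifs"] = {
        "planted_motif_mean_rank": planted_rank,
        "top_motif": enrich[0].motif_id,
    }

    # DOF-like site counting near TSSs in both species + paired excess test
    params = ScanParams(p_threshold=cfg.motif_site_p)
    pwm = lib[0]
    counts_by_species = {}
    for spc in ("species_a", "species_b"):
        land = landscape[spc]
        counts_by_species[spc] = count_sites_near_tss(
            land["peaks"], land["tss"], land["sequences"], pwm, params, cfg.tss_window
        )
    diff_pairs, cons_pairs = [], []
    for row in orthology.itertuples(index=False):
        klass = truth.orthogroup_class.get(row.orthogroup)
        rec = PairedCountRecord(
            row.orthogroup,
            counts_by_species["species_a"].get(row.gene_a, 0),
            counts_by_species["species_b"].get(row.gene_b, 0),
        )
        if klass == "differential":
            diff_pairs.append(rec)
        elif klass == "consistent":
            cons_pairs.append(rec)
    excess = {}
    for label, prs in (("differential", diff_pairs), ("consistent", cons_pairs)):
        try:
            excess[label] = paired_excess_test(prs, direction="b")
        except ValueError:
            excess[label] = None
    report["stages"]["dof_sites"] = {"excess_test": excess}

    # ----- chromatin
    chrom_report = {}
    for spc in ("species_a", "species_b"):
        land = landscape[spc]
        assignments, arep = assign_gene_peak(land["peaks"], land["gene_bodies"],
                                             window=cfg.gene_window)
        pb = partition[spc]["pb"]
        # per-(cell_type,time) accessibility pseudobulk for linked peaks
        cells = land["peak_cell_counts"].columns
        adata = adata_a if spc == "species_a" else adata_b
        groups = adata.obs.loc[cells, ["cell_type", "time_h"]]
        keymap = groups.apply(lambda r: f"{r['cell_type']}|{r['time_h']:g}", axis=1)
        acc_pb = land["peak_cell_counts"].T.groupby(keymap.to_numpy()).sum().T
        expr_groups = pb.counts.T.groupby(
            (pb.samples["cell_type"] + "|" + pb.samples["time_h"].map("{:g}".format)).to_numpy()
        ).sum().T
        shared = [c for c in acc_pb.columns if c in expr_groups.columns]
        pairs = [(a.peak_id, a.gene) for a in assignments]
        links = link_peaks(acc_pb[shared], expr_groups[shared], pairs,
                           alpha=cfg.alpha, seed=cfg.sim.seed)
        chrom_report[spc] = {
            "frac_trimmed": arep["frac_trimmed"],
            "n_assigned": len(assignments),
            "n_links_kept": sum(l.kept for l in links),
        }
    report["stages"]["chromatin"] = chrom_report

    # ----- light response (mesophyll of species A)
    pb_a = partition["species_a"]["pb"]
    de = light_de(pb_a, "mesophyll", cfg.alpha)
    sig = significant_genes(de, cfg.alpha)
    truth_light = set(truth.light_responsive["species_a"])
    light_sens = len(sig & truth_light) / len(truth_light) if truth_light else None
    # trend clustering of significant genes over the time course
    sub = pb_a.subset((pb_a.samples["cell_type"] == "mesophyll").to_numpy())
    logmat = np.log2(sub.counts.to_numpy(float) / sub.samples["size_factor"].to_numpy()[None, :] + 1)
    prof = pd.DataFrame(logmat, index=sub.counts.index, columns=sub.samples["time_h"].to_numpy())
    prof = prof.T.groupby(level=0).mean().T
    sig_prof = prof.loc[sorted(sig & set(prof.index))]
    clusters = []
    if sig_prof.shape[0] >= cfg.min_cluster_size:
        clusters = trend_cluster(sig_prof, min_size=cfg.min_cluster_size, target_k=2)
    report["stages"]["light"] = {
        "n_light_responsive": len(sig),
        "sensitivity_vs_truth": light_sens,
        "n_trend_clusters": len(clusters),
    }

    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_simulation(outdir / "sim", adata_a, adata_b, orthology, truth, landscape)
        for spc in ("species_a", "species_b"):
            records_to_frame(partition[spc]["records"]).to_csv(
                outdir / f"partition.{spc}.tsv", sep="\t", index=False
            )
        records_to_frame(class_recs).to_csv(outdir / "classification.tsv", sep="\t", index=False)
        conservation.to_csv(outdir / "conservation.tsv", sep="\t")
        sim_mat.to_csv(outdir / "similarity.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray, tuple, set, frozenset)):
        return list(o)
    return str(o)


def report_checksum(report: dict) -> str:
    import hashlib

    payload = json.dumps(report, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(payload).hexdigest()
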