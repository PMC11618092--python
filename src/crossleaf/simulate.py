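"""Two-species synthetic single-nucleus data with known ground truth.

The generator emulates the structure of a paired C3/C4 leaf atlas experiment:
two species sharing orthogroups (one-to-one and one-to-many), several cell
types (the first two are mesophyll and bundle sheath) sampled over a
de-etiolation time course, negative-binomial counts with cell-type and time
effects, planted consistently/differentially partitioned orthologue pairs,
planted cell-type markers with known cross-species conservation, and an
accessible-chromatin landscape whose peak sequences carry planted motif
instances at gene-class-dependent rates.

Counts use the mean/dispersion NB parameterization (variance mu + alpha*mu^2)
with a dispersion shared across genes.  Per-cell library sizes vary
log-normally so downstream stages must normalize.  Identical configs (same
seed) give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    PeakRecord,
    write_bed_peaks,
    write_counts,
    write_fasta,
    write_gene_bodies,
    write_orthology,
    write_truth,
    write_tss,
)

DEFAULT_CELLTYPES = (
    "mesophyll",
    "bundle_sheath",
    "guard",
    "epidermis",
    "phloem",
    "xylem",
)

#: DOF-like planted cis-element: the AAAG core with fixed flanks, long enough
#: that chance occurrences in a few-hundred-bp peak are rare.
PLANTED_MOTIF_CONSENSUS = "CAAAGCTC"

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the two-species simulation (the study conditions)."""

    seed: int = 0
    n_genes_per_species: int = 300
    n_celltypes: int = 6
    timepoints_h: tuple = (0.0, 6.0, 12.0)
    cells_per_type_per_time: int = 50
    n_batches: int = 2
    nb_dispersion: float = 0.1
    baseline_mean: float = 1.0
    partition_log2fc: float = 2.0
    frac_consistent: float = 0.2
    frac_differential: float = 0.15
    orthology_one_to_many_frac: float = 0.1
    # cell-type markers
    markers_per_celltype: int = 10
    marker_log2fc: float = 3.0
    marker_conserved_frac: float = 0.5
    # light response
    frac_light_responsive: float = 0.2
    time_log2fc_per_h: float = 0.15
    # library-size variation
    sf_sigma: float = 0.2
    # regulatory landscape
    peak_len_bp: int = 300
    motif_plant_rate_fg: float = 2.0
    motif_plant_rate_bg: float = 0.2
    gc_content: float = 0.45
    planted_motif: str = PLANTED_MOTIF_CONSENSUS

    def __post_init__(self):
        if self.n_celltypes < 2:
            raise ValueError("need at least 2 cell types (a mesophyll/bundle-sheath pair)")
        if len(self.timepoints_h) == 0:
            raise ValueError("timepoints_h must be non-empty")
        if any(t < 0 for t in self.timepoints_h):
            raise ValueError("timepoints must be non-negative")
        if self.frac_consistent + self.frac_differential > 1:
            raise ValueError("frac_consistent + frac_differential must be <= 1")
        if min(self.n_genes_per_species, self.cells_per_type_per_time, self.n_batches) < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion and baseline_mean must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if min(self.motif_plant_rate_fg, self.motif_plant_rate_bg) < 0:
            raise ValueError("plant rates must be >= 0")
        if self.peak_len_bp < len(self.planted_motif):
            raise ValueError("peak_len_bp smaller than planted motif width")

    @property
    def celltypes(self) -> list:
        named = list(DEFAULT_CELLTYPES)
        if self.n_celltypes <= len(named):
            return named[: self.n_celltypes]
        return named + [f"celltype{i}" for i in range(len(named), self.n_celltypes)]


@dataclass
class TruthTable:
    """Ground truth of a simulation run.

    ``orthogroup_class`` maps orthogroup id -> consistent/differential/null;
    ``partition_sign`` maps (species, gene) -> planted mesophyll-over-BS
    log2 fold-change sign (+1 toward mesophyll); ``markers`` maps species ->
    gene -> cell type; ``marker_conserved`` flags species-A markers whose
    orthologue is a same-cell-type marker in B; ``light_responsive`` maps
    species -> gene -> +1/-1 slope sign; ``planted_sites`` maps species ->
    peak_id -> list of planted (offset, strand) motif instances.
    """

    orthogroup_class: dict = field(default_factory=dict)
    partition_sign: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    marker_conserved: dict = field(default_factory=dict)
    light_responsive: dict = field(default_factory=dict)
    planted_sites: dict = field(default_factory=dict)

    def planted_counts(self, species) -> dict:
        return {pid: len(v) for pid, v in self.planted_sites.get(species, {}).items()}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["partition_sign"] = {f"{sp}|{g}": v for (sp, g), v in self.partition_sign.items()}
        return d

    @classmethod
    def from_dict(cls, d) -> "TruthTable":
        d = dict(d)
        d["partition_sign"] = {
            tuple(k.split("|", 1)): v for k, v in d.get("partition_sign", {}).items()
        }
        d["planted_sites"] = {
            spc: {pid: [tuple(x) for x in v] for pid, v in per.items()}
            for spc, per in d.get("planted_sites", {}).items()
        }
        return cls(**d)


def _gene_ids(prefix, n):
    return [f"{prefix}{i:05d}" for i in range(n)]


def _orthogroup_layout(cfg, rng):
    """Assign genes to orthogroups. The first K orthogroups carry a second
    member in each species (one-to-many rows in the map); the rest are 1:1."""
    n = cfg.n_genes_per_species
    k = int(round(cfg.orthology_one_to_many_frac * n / (1 + cfg.orthology_one_to_many_frac)))
    m = n - k  # number of orthogroups
    ogs = [f"OG{i:05d}" for i in range(m)]
    gene_og = np.concatenate([np.arange(m), np.arange(k)])  # gene index -> og index
    return ogs, gene_og, m, k


def simulate_expression(config: SimConfig):
    """Simulate per-species count matrices, the orthology map and the truth.

    Returns ``(adata_a, adata_b, orthology, truth)`` where the AnnData
    objects are cells x genes with (species, cell_type, time_h, batch) in
    ``.obs`` and the orthology map is a DataFrame (gene_a, gene_b,
    orthogroup).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes_per_species
    genes_a = _gene_ids("gA", n)
    genes_b = _gene_ids("gB", n)
    ogs, gene_og, m, k = _orthogroup_layout(cfg, rng)

    orthology = pd.DataFrame(
        {
            "gene_a": genes_a,
            "gene_b": [genes_b[i] for i in range(n)],
            "orthogroup": [ogs[gene_og[i]] for i in range(n)],
        }
    )

    truth = TruthTable()
    # ----- orthogroup classes: planted on 1:1 orthogroups after the first k
    n_cons = int(round(cfg.frac_consistent * m))
    n_diff = int(round(cfg.frac_differential * m))
    if k + n_cons + n_diff > m:
        raise ValueError("not enough one-to-one orthogroups for requested class fractions")
    class_of_og = {}
    cons_ogs = list(range(k, k + n_cons))
    diff_ogs = list(range(k + n_cons, k + n_cons + n_diff))
    for i in range(m):
        class_of_og[ogs[i]] = "null"
    for i in cons_ogs:
        class_of_og[ogs[i]] = "consistent"
    for i in diff_ogs:
        class_of_og[ogs[i]] = "differential"
    truth.orthogroup_class = class_of_og

    # direction of consistent partitioning: random per orthogroup (+1 = mesophyll)
    cons_dir = {i: int(rng.choice([-1, 1])) for i in cons_ogs}

    # per-gene planted partition sign per species (+1 toward mesophyll)
    sign_a = np.zeros(n)
    sign_b = np.zeros(n)
    for gi in range(n):
        ogi = gene_og[gi]
        cls = class_of_og[ogs[ogi]]
        if cls == "consistent":
            sign_a[gi] = sign_b[gi] = cons_dir[ogi]
        elif cls == "differential":
            sign_a[gi], sign_b[gi] = 1, -1  # mesophyll in A, bundle sheath in B
    truth.partition_sign = {
        **{("species_a", genes_a[i]): int(sign_a[i]) for i in range(n) if sign_a[i]},
        **{("species_b", genes_b[i]): int(sign_b[i]) for i in range(n) if sign_b[i]},
    }

    # ----- markers: genes outside planted partition classes
    celltypes = cfg.celltypes
    free = [gi for gi in range(n) if class_of_og[ogs[gene_og[gi]]] == "null"]
    rng.shuffle(free)
    need = cfg.markers_per_celltype * len(celltypes)
    if cfg.markers_per_celltype > 0 and need > len(free):
        raise ValueError("not enough unplanted genes for requested markers")
    marker_ct_a = {}
    marker_ct_b = {}
    conserved = {}
    pos = 0
    for ct in celltypes:
        for _ in range(cfg.markers_per_celltype):
            gi = free[pos]
            pos += 1
            marker_ct_a[gi] = ct
            if rng.random() < cfg.marker_conserved_frac:
                marker_ct_b[gi] = ct
                conserved[genes_a[gi]] = True
            else:
                conserved[genes_a[gi]] = False
    truth.markers = {
        "species_a": {genes_a[gi]: ct for gi, ct in marker_ct_a.items()},
        "species_b": {genes_b[gi]: ct for gi, ct in marker_ct_b.items()},
    }
    truth.marker_conserved = conserved

    # ----- light response: shared slope sign for orthologous genes
    n_light = int(round(cfg.frac_light_responsive * n))
    light_idx = rng.choice(n, size=n_light, replace=False) if n_light else np.array([], int)
    slope_sign = np.zeros(n)
    if n_light:
        slope_sign[light_idx] = rng.choice([-1, 1], size=n_light)
    truth.light_responsive = {
        "species_a": {genes_a[i]: int(slope_sign[i]) for i in light_idx},
        "species_b": {genes_b[i]: int(slope_sign[i]) for i in light_idx},
    }

    def make_species(genes, sign, spc_name, spc_rng):
        ct_effect = np.zeros((n, len(celltypes)))  # log2 units
        # partition effect: +/- fc/2 on mesophyll (col 0) and bundle sheath (col 1)
        ct_effect[:, 0] += sign * cfg.partition_log2fc / 2.0
        ct_effect[:, 1] -= sign * cfg.partition_log2fc / 2.0
        markers = marker_ct_a if spc_name == "species_a" else marker_ct_b
        for gi, ct in markers.items():
            ct_effect[gi, celltypes.index(ct)] += cfg.marker_log2fc
        slopes = slope_sign * cfg.time_log2fc_per_h  # log2 per hour

        cells, metas = [], []
        for ct_i, ct in enumerate(celltypes):
            for t in cfg.timepoints_h:
                for c in range(cfg.cells_per_type_per_time):
                    cells.append(f"{spc_name}_{ct}_{t:g}h_c{c:03d}")
                    metas.append((ct, float(t), f"batch{c % cfg.n_batches}"))
        n_cells = len(cells)
        sf = np.exp(spc_rng.normal(0.0, cfg.sf_sigma, size=n_cells))
        ct_idx = np.array([celltypes.index(mt[0]) for mt in metas])
        t_vec = np.array([mt[1] for mt in metas])
        log2mu = (
            np.log2(cfg.baseline_mean)
            + ct_effect[:, ct_idx]
            + slopes[:, None] * t_vec[None, :]
        )
        mu = np.exp2(log2mu) * sf[None, :]
        r = 1.0 / cfg.nb_dispersion
        counts = spc_rng.negative_binomial(r, r / (r + mu))
        obs = pd.DataFrame(
            {
                "species": spc_name,
                "cell_type": [mt[0] for mt in metas],
                "time_h": t_vec,
                "batch": [mt[2] for mt in metas],
            },
            index=pd.Index(cells, name="cell"),
        )
        adata = ad.AnnData(
            X=sp.csr_matrix(counts.T),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        return adata

    rng_a = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rng_b = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    adata_a = make_species(genes_a, sign_a, "species_a", rng_a)
    adata_b = make_species(genes_b, sign_b, "species_b", rng_b)
    return adata_a, adata_b, orthology, truth


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------

GENE_SPACING = 4000
GENE_BODY_LEN = 1200


def _random_seq(rng, length, gc):
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def simulate_regulatory_landscape(config: SimConfig, truth: TruthTable, adata_a, adata_b):
    """Simulate peaks, sequences, TSS/gene-body tables and per-cell fragment
    counts for both species.

    Foreground peaks (promoter-proximal peaks of genes differentially
    partitioned toward the species-B bundle sheath) receive planted exact
    consensus insertions of the configured motif at ``motif_plant_rate_fg``
    per peak; every other peak at ``motif_plant_rate_bg``.  Per-cell peak
    fragment counts are Poisson with a rate increasing in the assigned
    gene's expected expression, so accessibility correlates positively with
    expression by construction.

    Returns a dict per species with keys ``peaks`` (list of PeakRecord,
    sequences attached), ``sequences``, ``tss``, ``gene_bodies``,
    ``peak_cell_counts`` (DataFrame peaks x cells) and ``assigned_gene``.
    """
    cfg = config
    motif = cfg.planted_motif.upper()
    out = {}
    diff_ogs = {og for og, c in truth.orthogroup_class.items() if c == "differential"}
    for spc, adata, seed_tag in (
        ("species_a", adata_a, 3),
        ("species_b", adata_b, 4),
    ):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed_tag]))
        genes = list(adata.var_names)
        n = len(genes)
        strands = ["+" if i % 2 == 0 else "-" for i in range(n)]
        tss_pos = [2000 + i * GENE_SPACING for i in range(n)]
        gene_bodies = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [p if s == "+" else p - GENE_BODY_LEN for p, s in zip(tss_pos, strands)],
                "end": [p + GENE_BODY_LEN if s == "+" else p for p, s in zip(tss_pos, strands)],
                "strand": strands,
                "gene": genes,
            }
        )
        tss = pd.DataFrame({"chrom": "chr1", "pos": tss_pos, "strand": strands, "gene": genes})

        # which genes are foreground for motif planting in this species
        gene_sign = {g: truth.partition_sign.get((spc, g), 0) for g in genes}
        # foreground: differential genes partitioned toward the bundle sheath of species B
        fg_genes = set()
        if spc == "species_b":
            for g in genes:
                if gene_sign[g] == -1:  # toward bundle sheath
                    fg_genes.add(g)

        peaks, seqs, assigned, planted = [], {}, {}, {}
        mean_expr = _expected_group_means(adata)  # genes x (ct,time) expected means
        cells = list(adata.obs_names)
        ct_of_cell = adata.obs["cell_type"].to_numpy()
        t_of_cell = adata.obs["time_h"].to_numpy()
        peak_rows = []
        peak_ids = []
        for i, g in enumerate(genes):
            # proximal peak: centred near the TSS, within +/-1500 bp
            jitter = int(rng.integers(-500, 501))
            start = tss_pos[i] - cfg.peak_len_bp // 2 + jitter
            prox_id = f"{spc}_pk{i:05d}p"
            entries = [(prox_id, start, True)]
            if i % 5 == 0:
                # distal peak: outside the +/-1500 TSS window
                dstart = tss_pos[i] + 1600 + int(rng.integers(0, 400))
                entries.append((f"{spc}_pk{i:05d}d", dstart, False))
            for pid, pstart, proximal in entries:
                seq = list(_random_seq(rng, cfg.peak_len_bp, cfg.gc_content))
                rate = cfg.motif_plant_rate_fg if (proximal and g in fg_genes) else cfg.motif_plant_rate_bg
                n_plant = int(rng.poisson(rate))
                sites = []
                if n_plant:
                    # non-overlapping slots
                    slots = list(range(0, cfg.peak_len_bp - len(motif) + 1, len(motif)))
                    rng.shuffle(slots)
                    for off in slots[:n_plant]:
                        strand = "+" if rng.random() < 0.5 else "-"
                        ins = motif if strand == "+" else _revcomp(motif)
                        seq[off : off + len(motif)] = list(ins)
                        sites.append((int(off), strand))
                seq = "".join(seq)
                seqs[pid] = seq
                planted[pid] = sorted(sites)
                assigned[pid] = g
                peak_rows.append((pid, pstart, pstart + cfg.peak_len_bp, seq, g))
                peak_ids.append(pid)

        # per-cell fragment counts: Poisson with rate tied to the gene's
        # expected expression in that cell's (cell_type, time) group
        gene_index = {g: i for i, g in enumerate(genes)}
        cell_key = pd.MultiIndex.from_arrays([ct_of_cell, t_of_cell])
        cell_col = mean_expr.columns.get_indexer(cell_key)
        lam = np.empty((len(peak_rows), len(cells)))
        for j, (pid, s, e, seq, g) in enumerate(peak_rows):
            mu_cells = mean_expr.to_numpy()[gene_index[g], cell_col]
            lam[j] = 0.1 + 0.4 * np.log2(1.0 + mu_cells)
        frag = rng.poisson(lam)
        peak_cell_counts = pd.DataFrame(frag, index=peak_ids, columns=cells)

        celltypes = cfg.celltypes
        for j, (pid, s, e, seq, g) in enumerate(peak_rows):
            counts = {
                ct: int(frag[j, ct_of_cell == ct].sum()) for ct in celltypes
            }
            peaks.append(PeakRecord("chr1", int(s), int(e), pid, counts, seq))

        truth.planted_sites[spc] = planted
        out[spc] = {
            "peaks": peaks,
            "sequences": seqs,
            "tss": tss,
            "gene_bodies": gene_bodies,
            "peak_cell_counts": peak_cell_counts,
            "assigned_gene": assigned,
        }
    return out


def _expected_group_means(adata):
    """Observed mean count per gene per (cell_type, time_h) group.

    Returns a DataFrame with gene index (integer position) as rows and a
    (cell_type, time_h) MultiIndex as columns.
    """
    X = sp.csr_matrix(adata.X)
    keys = list(zip(adata.obs["cell_type"], adata.obs["time_h"]))
    uniq = sorted(set(keys))
    means = np.empty((adata.n_vars, len(uniq)))
    keys_arr = pd.Series(keys)
    for k, key in enumerate(uniq):
        mask = (keys_arr == key).to_numpy()
        means[:, k] = np.asarray(X[mask].mean(axis=0)).ravel()
    cols = pd.MultiIndex.from_tuples(uniq, names=["cell_type", "time_h"])
    return pd.DataFrame(means, index=range(adata.n_vars), columns=cols)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_simulation(outdir, adata_a, adata_b, orthology, truth, landscape=None):
    """Serialize a full simulation to plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(adata_a, outdir, "species_a")
    write_counts(adata_b, outdir, "species_b")
    write_orthology(orthology, outdir / "orthology.tsv")
    write_truth(truth, outdir / "truth.json")
    if landscape:
        for spc, land in landscape.items():
            write_bed_peaks(land["peaks"], outdir / f"{spc}.peaks.bed")
            write_fasta(land["sequences"], outdir / f"{spc}.peaks.fa")
            write_tss(land["tss"], outdir / f"{spc}.tss.tsv")
            write_gene_bodies(land["gene_bodies"], outdir / f"{spc}.genes.tsv.bed")
            land["peak_cell_counts"].to_csv(outdir / f"{spc}.peak_cell_counts.tsv", sep="\t")
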