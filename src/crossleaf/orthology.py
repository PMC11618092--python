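"""Cross-species comparison through orthogroups.

Gene sets from the two species are made comparable by converting to
orthogroup identifiers (optionally collapsing one-to-many relationships to a
deterministic one-to-one choice).  Overlap significance uses the one-sided
hypergeometric (Fisher) test with the total number of orthogroups in the map
as the background universe.  Orthologue pairs significantly partitioned
between mesophyll and bundle sheath in BOTH species are classified as
consistently partitioned (same favoured cell type) or differentially
partitioned (the gene swaps cell type across species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "OrthogroupSet",
    "OverlapTestResult",
    "PartitionClassRecord",
    "to_orthogroups",
    "overlap_test",
    "classify_partitioning",
    "marker_conservation",
    "celltype_similarity",
]


@dataclass
class OrthogroupSet:
    members: frozenset
    universe_size: int
    n_dropped: int = 0  # input genes absent from the orthology map

    def __post_init__(self):
        self.members = frozenset(self.members)
        if len(self.members) > self.universe_size:
            raise ValueError("orthogroup set larger than its universe")


@dataclass
class OverlapTestResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    odds_ratio: float
    p: float


@dataclass
class PartitionClassRecord:
    orthogroup: str
    gene_a: str
    gene_b: str
    log2fc_a: float
    log2fc_b: float
    klass: str  # consistent | differential


def to_orthogroups(genes, orthology: pd.DataFrame, species="a", mode="orthogroup") -> OrthogroupSet:
    """Convert a gene set to orthogroup identifiers.

    ``mode='orthogroup'`` maps each gene to its orthogroup id(s), keeping
    higher-order (one-to-many) relationships.  ``mode='one_to_one'`` keeps a
    single cross-species partner per gene — deterministically the
    lexicographically smallest partner id — and returns the orthogroups of
    those retained pairs.  Genes absent from the map are dropped and counted.
    """
    col = f"gene_{species}"
    other = "gene_b" if species == "a" else "gene_a"
    genes = set(genes)
    sub = orthology[orthology[col].isin(genes)]
    universe = orthology["orthogroup"].nunique()
    dropped = len(genes - set(sub[col]))
    if mode == "orthogroup":
        members = set(sub["orthogroup"])
    elif mode == "one_to_one":
        best = sub.sort_values(other).drop_duplicates(col, keep="first")
        members = set(best["orthogroup"])
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return OrthogroupSet(members, universe, dropped)


def overlap_test(set_a: OrthogroupSet, set_b: OrthogroupSet) -> OverlapTestResult:
    """One-sided (enrichment) Fisher/hypergeometric overlap test.

    p = P(X >= overlap) drawing |B| from a universe containing |A|
    successes; the odds ratio comes from the 2x2 table.
    """
    if set_a.universe_size != set_b.universe_size:
        raise ValueError("orthogroup sets have different universes")
    u = set_a.universe_size
    na, nb = len(set_a.members), len(set_b.members)
    ov = len(set_a.members & set_b.members)
    table = [[ov, na - ov], [nb - ov, u - na - nb + ov]]
    odds, p = scipy.stats.fisher_exact(table, alternative="greater")
    return OverlapTestResult(na, nb, ov, u, float(odds), float(p))


def classify_partitioning(records_a, records_b, orthology: pd.DataFrame, alpha=0.05,
                          mesophyll="mesophyll", bundle_sheath="bundle_sheath"):
    """Classify orthologue pairs significant in both species.

    ``records_a``/``records_b`` are PartitionRecord lists for the homologous
    mesophyll/bundle-sheath pair, oriented so positive log2fc favours
    mesophyll.  Same fold-change sign in both species -> consistent;
    opposite signs -> differential.  Orthogroups whose multiple member pairs
    disagree go to a separate 'complex' report.

    Returns (records, report) where report holds complex orthogroups and
    unmatched counts.
    """
    def index(records):
        out = {}
        for r in records:
            if {r.cell_a, r.cell_b} != {mesophyll, bundle_sheath}:
                raise ValueError(
                    f"records compare {r.cell_a} vs {r.cell_b}, expected "
                    f"{mesophyll} vs {bundle_sheath}"
                )
            fc = r.log2fc if r.cell_a == mesophyll else -r.log2fc
            out[r.gene] = (fc, r.padj)
        return out

    a_by_gene = index(records_a)
    b_by_gene = index(records_b)

    pair_rows = []
    for row in orthology.itertuples(index=False):
        if row.gene_a in a_by_gene and row.gene_b in b_by_gene:
            fa, pa = a_by_gene[row.gene_a]
            fb, pb_ = b_by_gene[row.gene_b]
            if pa < alpha and pb_ < alpha and fa != 0 and fb != 0:
                klass = "consistent" if np.sign(fa) == np.sign(fb) else "differential"
                pair_rows.append(
                    PartitionClassRecord(row.orthogroup, row.gene_a, row.gene_b,
                                         float(fa), float(fb), klass)
                )

    by_og = {}
    for rec in pair_rows:
        by_og.setdefault(rec.orthogroup, []).append(rec)
    records, complex_ogs = [], []
    for og, recs in sorted(by_og.items()):
        classes = {r.klass for r in recs}
        if len(classes) == 1:
            records.extend(recs)
        else:
            complex_ogs.append(og)
    report = {
        "n_pairs_significant_both": len(pair_rows),
        "n_orthogroups": len(by_og),
        "complex_orthogroups": complex_ogs,
        "n_complex": len(complex_ogs),
    }
    return records, report


def marker_conservation(markers_a: dict, markers_b: dict, orthology: pd.DataFrame):
    """Per-cell-type marker conservation of species-A markers in species B.

    ``markers_a``/``markers_b`` map cell-type label -> set of marker genes.
    A species-A marker is conserved iff any member of its orthogroup is a
    species-B marker of the same cell type.  Percent is reported floored to
    an integer (43% for 184/426, 13% for 31/229); the raw fraction is kept
    alongside.
    """
    og_of_a = orthology.groupby("gene_a")["orthogroup"].apply(set)
    ogs_b_by_ct = {}
    og_members_b = orthology.groupby("orthogroup")["gene_b"].apply(set)
    rows = []
    for ct, genes_a in markers_a.items():
        if ct not in markers_b:
            raise KeyError(f"cell type '{ct}' missing from species-B marker sets")
        genes_b = set(markers_b[ct])
        n_total = len(genes_a)
        n_cons = 0
        for g in genes_a:
            for og in og_of_a.get(g, ()):  # type: ignore[arg-type]
                if og_members_b.get(og, frozenset()) & genes_b:
                    n_cons += 1
                    break
        fraction = n_cons / n_total if n_total else 0.0
        rows.append(
            {
                "cell_type": ct,
                "n_conserved": n_cons,
                "n_total": n_total,
                "fraction": fraction,
                "percent": int(np.floor(100.0 * fraction)),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def celltype_similarity(markers_a: dict, markers_b: dict, orthology: pd.DataFrame):
    """Cross-species cell-type similarity from marker-set orthogroup overlap.

    For every (A cell type, B cell type) pair the marker sets are converted
    to orthogroups and overlap-tested; similarity is -log10(p).  Returns
    (score_matrix, best_match) where best_match maps each species-B cell
    type to its highest-scoring species-A cell type (a Sankey-style map).
    """
    sets_a = {ct: to_orthogroups(g, orthology, "a") for ct, g in markers_a.items()}
    sets_b = {ct: to_orthogroups(g, orthology, "b") for ct, g in markers_b.items()}
    mat = pd.DataFrame(index=sorted(sets_a), columns=sorted(sets_b), dtype=float)
    for ca, sa in sets_a.items():
        for cb, sbset in sets_b.items():
            if not sa.members or not sbset.members:
                mat.loc[ca, cb] = 0.0
                continue
            res = overlap_test(sa, sbset)
            mat.loc[ca, cb] = -np.log10(max(res.p, 1e-300))
    best_match = {cb: mat[cb].idxmax() for cb in mat.columns}
    return mat, best_match
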