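"""iModulon annotation: regulon enrichment, combinatorial labels, TF checks.

An iModulon is the data-driven analogue of a regulon, so the first
annotation route tests each iModulon's member set against every curated
regulon with a two-sided Fisher exact test, controls the family-wise FDR
by Benjamini-Hochberg at a strict cutoff (default 1e-5), and reports
recall (overlap / regulon size) and precision (overlap / iModulon size).
iModulons enriched for several regulons get a combinatorial label:
regulators joined by '+' when the members concentrate in the regulons'
intersection (combinatorial regulation of the same genes), by '/' when
they split across the regulons. iModulons with no enriched regulon can be
annotated through motif evidence produced by external tools; this module
prepares the motif-search inputs (strand-aware 200-bp upstream regions
that overlap no annotated gene, filtered by a precomputed promoter-score
table) and validates a candidate TF by correlating its expression with
the member genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compendium import ExpressionCompendium
from .extraction import IModulon


# -- regulon database ----------------------------------------------------------

@dataclass
class RegulonDB:
    """Mapping regulator name -> gene set over a fixed gene universe."""

    universe: set[str]
    regulons: dict[str, set[str]]

    def __post_init__(self) -> None:
        for reg, genes in self.regulons.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(f"regulon {reg!r} has genes outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_tsv(cls, path, universe: set[str] | None = None) -> "RegulonDB":
        """Two-column TSV (regulator, gene). Universe defaults to the genes
        present in the table; pass the compendium gene set to widen it."""
        table = pd.read_csv(path, sep="\t", dtype=str)
        reg_col, gene_col = table.columns[:2]
        regulons: dict[str, set[str]] = {}
        for reg, sub in table.groupby(reg_col):
            regulons[str(reg)] = set(sub[gene_col])
        if universe is None:
            universe = set().union(*regulons.values()) if regulons else set()
        return cls(universe=set(universe), regulons=regulons)

    def to_tsv(self, path) -> None:
        rows = [(r, g) for r in sorted(self.regulons) for g in sorted(self.regulons[r])]
        pd.DataFrame(rows, columns=["regulator", "gene"]).to_csv(path, sep="\t", index=False)


# -- Fisher enrichment ---------------------------------------------------------

@dataclass
class EnrichmentResult:
    im_id: str
    target_name: str
    overlap: int
    im_size: int
    target_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")
    empty_im: bool = False

    @property
    def recall(self) -> float:
        return self.overlap / self.target_size if self.target_size else 0.0

    @property
    def precision(self) -> float:
        return self.overlap / self.im_size if self.im_size else 0.0


def fisher_enrichment(
    im_members: set[str],
    target: set[str],
    universe: set[str],
    im_id: str = "",
    target_name: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test on the 2x2 in-IM / in-target partition
    of the universe. An empty iModulon gets p = 1 by convention, flagged."""
    if not universe:
        raise ValueError("empty universe")
    if not im_members <= universe or not target <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    n = len(universe)
    a = len(im_members & target)
    b = len(im_members) - a
    c = len(target) - a
    d = n - a - b - c
    if not im_members:
        return EnrichmentResult(im_id, target_name, 0, 0, len(target), n,
                                p_value=1.0, empty_im=True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(im_id, target_name, a, len(im_members), len(target), n,
                            p_value=float(p))


def enrich_all(
    ims: list[IModulon],
    db: RegulonDB,
    fdr_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """All iModulon x regulon Fisher tests with BH q-values over the full
    family. Returns a tidy table with a ``significant`` flag at
    ``q < fdr_cutoff``."""
    if not db.regulons:
        import warnings

        warnings.warn("empty regulon database; no enrichment computed")
        return pd.DataFrame(
            columns=["im_id", "regulator", "overlap", "im_size", "regulon_size",
                     "universe_size", "p_value", "q_value", "recall", "precision",
                     "significant"]
        )
    results = []
    for im in ims:
        members = im.members & db.universe
        for reg, genes in db.regulons.items():
            results.append(fisher_enrichment(members, genes, db.universe, im.id, reg))
    pvals = np.array([r.p_value for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        rows.append(
            {
                "im_id": r.im_id,
                "regulator": r.target_name,
                "overlap": r.overlap,
                "im_size": r.im_size,
                "regulon_size": r.target_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "recall": r.recall,
                "precision": r.precision,
                "significant": bool(r.q_value < fdr_cutoff and not r.empty_im),
            }
        )
    return pd.DataFrame(rows).sort_values(["im_id", "q_value"]).reset_index(drop=True)


# -- regulatory labels ---------------------------------------------------------

@dataclass
class RegulatoryAnnotation:
    im_id: str
    label: str
    status: str  # regulon_enrichment | motif_comparison | uncharacterized
    evidence: list[dict] = field(default_factory=list)


def combinatorial_label(
    im: IModulon,
    significant_regulons: list[str],
    db: RegulonDB,
    intersection_dominance: float = 0.6,
) -> RegulatoryAnnotation:
    """Join multiple enriched regulators with '+' (combinatorial: members
    concentrate in the regulons' intersection) or '/' (union: members
    split across the regulons). The decision rule formalizes what is
    usually a manual call from a Venn diagram: among members covered by
    any enriched regulon, if more than ``intersection_dominance`` lie in
    the intersection of all of them, use '+'.
    """
    if not significant_regulons:
        raise ValueError("need at least one significant regulon")
    regs = list(significant_regulons)
    if len(regs) == 1:
        return RegulatoryAnnotation(im.id, regs[0], "regulon_enrichment")
    sets = [db.regulons[r] for r in regs]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    covered = im.members & union
    frac = len(im.members & inter) / len(covered) if covered else 0.0
    sep = "+" if frac > intersection_dominance else "/"
    evidence = [{"regulators": regs, "intersection_fraction": frac}]
    return RegulatoryAnnotation(im.id, sep.join(regs), "regulon_enrichment", evidence)


# -- TF-correlation validation -------------------------------------------------

@dataclass
class TfValidation:
    tf_gene: str
    im_id: str
    validated: bool
    fraction_significant: float
    per_gene: pd.DataFrame  # gene, r, p
    activity_pcc: float | None = None
    activity_p: float | None = None
    skipped_genes: list[str] = field(default_factory=list)


def tf_correlation_validation(
    tf_gene: str,
    im: IModulon,
    compendium: ExpressionCompendium,
    activity: pd.Series | None = None,
    p_cutoff: float = 0.05,
) -> TfValidation:
    """Validate a candidate TF by correlating its expression with every
    member gene; the TF annotates the iModulon when most (> 50%) members
    correlate significantly. Also reports the TF-expression vs iModulon-
    activity PCC when an activity row is supplied."""
    if tf_gene not in compendium.values.index:
        raise KeyError(f"TF gene {tf_gene!r} not in compendium")
    if not im.members:
        raise ValueError(f"iModulon {im.id} has no members")
    tf_row = compendium.values.loc[tf_gene].to_numpy(dtype=float)
    rows, skipped = [], []
    for gene in sorted(im.members - {tf_gene}):
        row = compendium.values.loc[gene].to_numpy(dtype=float)
        if np.ptp(row) == 0 or np.ptp(tf_row) == 0:
            skipped.append(gene)
            continue
        r, p = stats.pearsonr(tf_row, row)
        rows.append({"gene": gene, "r": float(r), "p": float(p)})
    per_gene = pd.DataFrame(rows, columns=["gene", "r", "p"])
    frac = float((per_gene["p"] < p_cutoff).mean()) if len(per_gene) else 0.0
    act_r = act_p = None
    if activity is not None:
        a = activity.to_numpy(dtype=float)
        if np.ptp(a) > 0 and np.ptp(tf_row) > 0:
            act_r, act_p = (float(x) for x in stats.pearsonr(tf_row, a))
    return TfValidation(
        tf_gene=tf_gene,
        im_id=im.id,
        validated=frac > 0.5,
        fraction_significant=frac,
        per_gene=per_gene,
        activity_pcc=act_r,
        activity_p=act_p,
        skipped_genes=skipped,
    )


def _stars(p: float) -> str:
    if p < 1e-3:
        return "***"
    if p < 0.05:
        return "*"
    return "NS"


def overlap_vs_regulon_pcc(
    im: IModulon,
    regulon: set[str],
    tf_gene: str,
    compendium: ExpressionCompendium,
    n_random: int = 50,
    rng: np.random.Generator | None = None,
) -> dict:
    """Compare TF-gene PCC distributions of (i) genes in the IM-regulon
    overlap, (ii) all regulon genes, (iii) randomly sampled genes, with
    pairwise two-sided Mann-Whitney tests. Detects whether the overlap
    carries stronger regulatory signal than the regulon at large."""
    overlap = im.members & regulon
    if not overlap:
        raise ValueError("empty IM-regulon overlap")
    if rng is None:
        rng = np.random.default_rng(0)
    tf_row = compendium.values.loc[tf_gene].to_numpy(dtype=float)

    def pccs(genes) -> np.ndarray:
        out = []
        for g in sorted(genes):
            if g == tf_gene or g not in compendium.values.index:
                continue
            row = compendium.values.loc[g].to_numpy(dtype=float)
            if np.ptp(row) == 0:
                continue
            out.append(stats.pearsonr(tf_row, row)[0])
        return np.asarray(out, dtype=float)

    pool = [g for g in compendium.gene_ids if g != tf_gene]
    random_genes = rng.choice(pool, size=min(n_random, len(pool)), replace=False)
    dists = {
        "overlap": pccs(overlap),
        "regulon": pccs(regulon),
        "random": pccs(random_genes),
    }
    comparisons = {}
    for a, b in [("overlap", "regulon"), ("overlap", "random"), ("regulon", "random")]:
        if np.array_equal(dists[a], dists[b]):
            comparisons[f"{a}_vs_{b}"] = {"p": 1.0, "stars": "NS"}
            continue
        _, p = stats.mannwhitneyu(dists[a], dists[b], alternative="two-sided")
        comparisons[f"{a}_vs_{b}"] = {"p": float(p), "stars": _stars(float(p))}
    return {"tf_gene": tf_gene, "im_id": im.id, "pccs": dists, "comparisons": comparisons}


# -- orchestration -------------------------------------------------------------

def annotate_imodulons(
    ims: list[IModulon],
    db: RegulonDB,
    fdr_cutoff: float = 1e-5,
    intersection_dominance: float = 0.6,
) -> tuple[pd.DataFrame, list[RegulatoryAnnotation]]:
    """Run the regulon-enrichment route end to end and attach labels."""
    table = enrich_all(ims, db, fdr_cutoff=fdr_cutoff)
    annotations = []
    for im in ims:
        sub = table[(table["im_id"] == im.id) & table["significant"]]
        regs = list(sub.sort_values("q_value")["regulator"])
        if regs:
            ann = combinatorial_label(im, regs, db, intersection_dominance)
        else:
            ann = RegulatoryAnnotation(im.id, "", "uncharacterized")
        im.regulator_label = ann.label
        im.status = ann.status
        annotations.append(ann)
    return table, annotations


def functional_enrichment(
    ims: list[IModulon],
    pathways: dict[str, set[str]],
    universe: set[str],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of member sets against pathway gene sets
    (supplied as input, e.g. a two-column TSV read like a regulon table)."""
    db = RegulonDB(universe=set(universe), regulons=pathways)
    table = enrich_all(ims, db, fdr_cutoff=fdr_cutoff)
    for im in ims:
        sub = table[(table["im_id"] == im.id) & table["significant"]]
        if len(sub):
            im.function_label = sub.sort_values("q_value")["regulator"].iloc[0]
    return table.rename(columns={"regulator": "pathway", "regulon_size": "pathway_size"})


def annotation_table(ims: list[IModulon]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "im_id": [im.id for im in ims],
            "size": [im.size for im in ims],
            "regulator": [im.regulator_label for im in ims],
            "status": [im.status for im in ims],
            "function": [im.function_label for im in ims],
        }
    )


# -- upstream regions for motif search ----------------------------------------

def extract_upstream_regions(
    fasta_path,
    gff_path,
    length: int = 200,
    feature_type: str = "gene",
) -> pd.DataFrame:
    """Strand-aware upstream regions for motif discovery.

    For each coding gene, takes the ``length``-bp window immediately
    upstream in strand orientation (reverse-complemented on the minus
    strand). Windows that overlap any annotated gene are excluded, as are
    windows truncated by a contig edge. Coordinates in the returned table
    are 0-based half-open on the forward strand.
    """
    import gffutils
    from Bio import SeqIO
    from intervaltree import IntervalTree

    contigs = {rec.id: rec.seq for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for f in db.features_of_type(feature_type):
        if f.strand not in ("+", "-") or f.seqid not in contigs:
            import logging

            logging.getLogger(__name__).warning("skipping malformed record %s", f.id)
            continue
        genes.append(f)
    trees: dict[str, IntervalTree] = {}
    for f in genes:
        trees.setdefault(f.seqid, IntervalTree()).addi(f.start - 1, f.end, f.id)

    rows = []
    for f in genes:
        start0, end0 = f.start - 1, f.end  # GFF is 1-based closed
        if f.strand == "+":
            lo, hi = start0 - length, start0
        else:
            lo, hi = end0, end0 + length
        if lo < 0 or hi > len(contigs[f.seqid]):
            continue  # truncated at contig edge
        hits = {iv.data for iv in trees[f.seqid].overlap(lo, hi)} - {f.id}
        if hits:
            continue  # upstream window overlaps another gene
        seq = contigs[f.seqid][lo:hi]
        if f.strand == "-":
            seq = seq.reverse_complement()
        rows.append(
            {
                "gene_id": f.id,
                "contig": f.seqid,
                "start": lo,
                "end": hi,
                "strand": f.strand,
                "sequence": str(seq),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand", "sequence"])


def filter_by_promoter_score(
    regions: pd.DataFrame, scores: pd.DataFrame, cutoff: float = 0.8
) -> pd.DataFrame:
    """Keep regions whose gene has a precomputed promoter probability
    above ``cutoff`` (scores table: gene_id, score — produced by an
    external promoter predictor)."""
    score_map = dict(zip(scores.iloc[:, 0].astype(str), scores.iloc[:, 1].astype(float)))
    keep = regions["gene_id"].map(lambda g: score_map.get(str(g), 0.0) > cutoff)
    return regions[keep].reset_index(drop=True)


def write_upstream_fasta(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in regions.itertuples():
            fh.write(f">{row.gene_id} {row.contig}:{row.start}-{row.end}({row.strand})\n")
            fh.write(f"{row.sequence}\n")
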