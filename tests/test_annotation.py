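"""Fisher enrichment, labels, TF validation, and upstream-region extraction."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_compendium
from modulome.annotation import (
    RegulonDB,
    combinatorial_label,
    enrich_all,
    extract_upstream_regions,
    filter_by_promoter_score,
    fisher_enrichment,
    overlap_vs_regulon_pcc,
    tf_correlation_validation,
)
from modulome.extraction import IModulon
from oracles import fisher_two_sided_reference, upstream_regions_reference


def _im(im_id, members, universe):
    w = pd.Series(0.0, index=sorted(universe))
    w[sorted(members)] = 1.0
    return IModulon(id=im_id, weights=w, threshold=0.5, members=set(members))


def _ims_from_truth(truth):
    ims = []
    for j, (mod, members) in enumerate(sorted(truth.modules.items())):
        ims.append(_im(f"IM-{j + 1}", members, truth.gene_ids))
    return ims


class TestFisherEnrichment:
    def test_degenerate_full_table(self):
        u = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(u, u, u)
        assert res.p_value == 1.0

    def test_matches_enumeration_oracle(self):
        u = {f"g{i}" for i in range(100)}
        im = {f"g{i}" for i in range(10)}
        target = {f"g{i}" for i in range(8)} | {"g50", "g51"}
        res = fisher_enrichment(im, target, u)
        a = len(im & target)
        expected = fisher_two_sided_reference(a, len(im) - a, len(target) - a,
                                              100 - len(im) - len(target) + a)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_disjoint_sets_enumeration(self):
        u = {f"g{i}" for i in range(20)}
        im = {f"g{i}" for i in range(10)}
        target = u - im
        res = fisher_enrichment(im, target, u)
        expected = fisher_two_sided_reference(0, 10, 10, 0)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_symmetry_in_the_two_sets(self):
        rng = np.random.default_rng(0)
        u = {f"g{i}" for i in range(60)}
        a = set(rng.choice(sorted(u), 15, replace=False))
        b = set(rng.choice(sorted(u), 20, replace=False))
        assert fisher_enrichment(a, b, u).p_value == pytest.approx(
            fisher_enrichment(b, a, u).p_value, rel=1e-12
        )

    def test_empty_im_flagged(self):
        u = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(set(), {"g1"}, u)
        assert res.p_value == 1.0 and res.empty_im

    def test_recall_precision_perfect_match(self):
        u = {f"g{i}" for i in range(100)}
        s = {f"g{i}" for i in range(10)}
        res = fisher_enrichment(s, s, u)
        assert res.recall == 1.0 and res.precision == 1.0


class TestEnrichAll:
    def test_planted_regulons_are_top_hits(self, small_truth):
        from modulome import derive_regulons

        ims = _ims_from_truth(small_truth)
        regs = derive_regulons(small_truth, 0.0)
        db = RegulonDB(universe=set(small_truth.gene_ids), regulons=regs)
        table = enrich_all(ims, db)
        for j, (mod, members) in enumerate(sorted(small_truth.modules.items())):
            sub = table[table["im_id"] == f"IM-{j + 1}"].sort_values("q_value")
            assert sub.iloc[0]["regulator"] == f"TF_{mod}"
            assert sub.iloc[0]["q_value"] < 1e-5
            assert sub.iloc[0]["recall"] == 1.0 and sub.iloc[0]["precision"] == 1.0

    def test_bh_q_monotone_and_at_least_p(self, small_truth):
        from modulome import derive_regulons

        ims = _ims_from_truth(small_truth)
        db = RegulonDB(universe=set(small_truth.gene_ids),
                       regulons=derive_regulons(small_truth, 0.4))
        table = enrich_all(ims, db).sort_values("p_value")
        assert (table["q_value"].to_numpy() >= table["p_value"].to_numpy() - 1e-15).all()
        assert (np.diff(table["q_value"].to_numpy()) >= -1e-12).all()

    def test_permuted_labels_yield_no_hits(self, small_truth):
        rng = np.random.default_rng(1)
        genes = list(small_truth.gene_ids)
        hits = 0
        for _ in range(20):
            perm = dict(zip(genes, rng.permutation(genes)))
            ims = [
                _im(f"IM-{j}", {perm[g] for g in members}, genes)
                for j, members in enumerate(small_truth.modules.values())
            ]
            db = RegulonDB(universe=set(genes), regulons=small_truth.regulons)
            table = enrich_all(ims, db)
            hits += int(table["significant"].sum() > 0)
        assert hits <= 1


class TestCombinatorialLabel:
    UNIVERSE = {f"g{i}" for i in range(40)}

    def _db(self, r1, r2):
        return RegulonDB(universe=self.UNIVERSE, regulons={"R1": r1, "R2": r2})

    def test_full_intersection_plus(self):
        r1 = {f"g{i}" for i in range(10)}
        r2 = {f"g{i}" for i in range(5, 15)}
        im = _im("IM-1", {"g5", "g6", "g7"}, self.UNIVERSE)  # inside R1 & R2
        ann = combinatorial_label(im, ["R1", "R2"], self._db(r1, r2))
        assert ann.label == "R1+R2"

    def test_disjoint_split_slash(self):
        r1 = {f"g{i}" for i in range(10)}
        r2 = {f"g{i}" for i in range(10, 20)}
        im = _im("IM-1", {"g1", "g2", "g12", "g13"}, self.UNIVERSE)
        ann = combinatorial_label(im, ["R1", "R2"], self._db(r1, r2))
        assert ann.label == "R1/R2"

    def test_single_regulon_bare_name(self):
        r1 = {f"g{i}" for i in range(10)}
        im = _im("IM-1", {"g1"}, self.UNIVERSE)
        ann = combinatorial_label(im, ["R1"], self._db(r1, {"g20"}))
        assert ann.label == "R1" and ann.status == "regulon_enrichment"


class TestTfValidation:
    def test_identical_rows_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        row = rng.normal(0, 1, 12)
        vals = np.vstack([row, row, rng.normal(0, 1, (3, 12))])
        groups = ["a", "a", "b", "b", "c", "c", "d", "d", "e", "e", "f", "f"]
        comp = make_compendium(vals, groups, "a", state="log")
        im = IModulon(id="IM-1", weights=pd.Series(0.0, index=comp.gene_ids),
                      threshold=0.0, members={"g001", "g002"})
        res = tf_correlation_validation("g001", im, comp)
        row2 = res.per_gene.set_index("gene").loc["g002"]
        assert row2["r"] == pytest.approx(1.0)
        assert row2["p"] < 1e-10

    def test_planted_tf_validates(self, small_truth, small_logged):
        mod = sorted(small_truth.modules)[0]
        im = _im("IM-1", small_truth.modules[mod], small_truth.gene_ids)
        res = tf_correlation_validation(small_truth.tf_genes[mod], im, small_logged)
        assert res.validated

    def test_noise_tf_rarely_validates(self, small_truth, small_logged):
        # a gene outside every module shares no signal with a module; the
        # member genes are mutually correlated, so validation behaves as
        # one effective test per candidate at the nominal 5% level
        rng = np.random.default_rng(3)
        in_modules = set().union(*small_truth.modules.values())
        outsiders = [g for g in small_truth.gene_ids if g not in in_modules]
        mod = sorted(small_truth.modules)[0]
        im = _im("IM-1", small_truth.modules[mod], small_truth.gene_ids)
        trials = 100
        validated = sum(
            tf_correlation_validation(tf, im, small_logged).validated
            for tf in rng.choice(outsiders, trials, replace=False)
        )
        margin = 1.96 * np.sqrt(0.05 * 0.95 / trials)
        assert validated / trials <= 0.05 + margin


class TestOverlapVsRegulon:
    def test_identical_sets_are_ns(self, small_truth, small_logged):
        mod = sorted(small_truth.modules)[0]
        members = small_truth.modules[mod]
        im = _im("IM-1", members, small_truth.gene_ids)
        rec = overlap_vs_regulon_pcc(im, set(members), small_truth.tf_genes[mod],
                                     small_logged, n_random=20)
        assert rec["comparisons"]["overlap_vs_regulon"]["stars"] == "NS"

    def test_overlap_dominates_when_it_carries_signal(self, small_truth, small_logged):
        # regulon = module plus random outside genes; overlap genes share
        # the TF's component, padding genes do not
        rng = np.random.default_rng(4)
        mod = sorted(small_truth.modules)[0]
        members = small_truth.modules[mod]
        in_modules = set().union(*small_truth.modules.values())
        pad = [g for g in small_truth.gene_ids if g not in in_modules]
        regulon = set(members) | set(rng.choice(pad, 15, replace=False))
        im = _im("IM-1", members, small_truth.gene_ids)
        rec = overlap_vs_regulon_pcc(im, regulon, small_truth.tf_genes[mod],
                                     small_logged, n_random=20)
        assert np.median(rec["pccs"]["overlap"]) > np.median(rec["pccs"]["regulon"])
        assert abs(np.median(rec["pccs"]["random"])) < 0.35


class TestUpstreamRegions:
    GFF_HEADER = "##gff-version 3\n"

    def _write(self, tmp_path, genes, contig_len=5000):
        import random

        random.seed(0)
        seq = "".join(random.choice("ACGT") for _ in range(contig_len))
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\n" + seq + "\n")
        lines = [self.GFF_HEADER]
        for gid, start0, end0, strand in genes:
            lines.append(
                f"chr1\ttest\tgene\t{start0 + 1}\t{end0}\t.\t{strand}\t.\tID={gid}\n"
            )
        gff = tmp_path / "genome.gff3"
        gff.write_text("".join(lines))
        return fasta, gff, seq

    def test_plus_strand_window(self, tmp_path):
        fasta, gff, seq = self._write(tmp_path, [("geneA", 1000, 2000, "+")])
        regions = extract_upstream_regions(fasta, gff)
        row = regions.iloc[0]
        assert (row.start, row.end) == (800, 1000)
        assert row.sequence == seq[800:1000]

    def test_minus_strand_reverse_complement(self, tmp_path):
        from Bio.Seq import Seq

        fasta, gff, seq = self._write(tmp_path, [("geneB", 1000, 2000, "-")])
        regions = extract_upstream_regions(fasta, gff)
        row = regions.iloc[0]
        assert (row.start, row.end) == (2000, 2200)
        assert row.sequence == str(Seq(seq[2000:2200]).reverse_complement())

    def test_overlapping_window_excluded(self, tmp_path):
        genes = [("geneA", 100, 950, "+"), ("geneB", 1000, 2000, "+")]
        fasta, gff, _ = self._write(tmp_path, genes)
        regions = extract_upstream_regions(fasta, gff)
        assert "geneB" not in set(regions["gene_id"])  # window [800,1000) hits geneA

    def test_contig_edge_truncation_dropped(self, tmp_path):
        fasta, gff, _ = self._write(tmp_path, [("geneA", 100, 400, "+")])
        regions = extract_upstream_regions(fasta, gff)
        assert regions.empty

    def test_matches_naive_reference_on_random_annotation(self, tmp_path):
        rng = np.random.default_rng(5)
        genes = []
        pos = 250
        for i in range(12):
            length = int(rng.integers(150, 600))
            gap = int(rng.integers(0, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((f"gene{i:02d}", pos, pos + length, strand))
            pos += length + gap
        fasta, gff, _ = self._write(tmp_path, genes, contig_len=pos + 100)
        regions = extract_upstream_regions(fasta, gff)
        got = {r.gene_id: (r.start, r.end) for r in regions.itertuples()}
        expected = upstream_regions_reference(
            [(g, "chr1", s, e, st) for g, s, e, st in genes],
            {"chr1": pos + 100},
        )
        assert got == expected

    def test_emitted_regions_never_overlap_genes(self, tmp_path):
        genes = [("geneA", 300, 700, "+"), ("geneB", 820, 1300, "-"),
                 ("geneC", 1400, 1900, "+")]
        fasta, gff, _ = self._write(tmp_path, genes)
        regions = extract_upstream_regions(fasta, gff)
        for r in regions.itertuples():
            for _, s, e, _ in genes:
                assert not (r.start < e and s < r.end)


def test_promoter_score_filter():
    regions = pd.DataFrame(
        {"gene_id": ["a", "b", "c"], "contig": "chr1", "start": 0, "end": 200,
         "strand": "+", "sequence": "ACGT"}
    )
    scores = pd.DataFrame({"gene_id": ["a", "b"], "score": [0.9, 0.5]})
    kept = filter_by_promoter_score(regions, scores, cutoff=0.8)
    assert list(kept["gene_id"]) == ["a"]
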