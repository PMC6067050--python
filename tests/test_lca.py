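"""Weighted-LCA gene vote, contig consensus, and propagation."""

import numpy as np
import pytest

from genecat.hit_io import AlignmentHit
from genecat.lca import (
    GeneAssignment,
    RankThresholds,
    assign_contig,
    assign_gene,
    assign_taxonomy,
    hit_weight,
    propagate,
)
from genecat.taxonomy import RankedLineage


def hit(taxid, ident, alen=100, qlen=100, gene="g1"):
    return AlignmentHit(gene, f"ref_{taxid}", taxid, ident, alen, qlen,
                        1e-20, 100.0)


def lineage(*names_and_ids):
    from genecat.taxonomy import CANONICAL_RANKS
    return RankedLineage(tuple(
        (CANONICAL_RANKS[i], t, n) for i, (t, n) in enumerate(names_and_ids)
    ))


class TestHitWeight:
    def test_product_of_aligned_fraction_and_identity(self):
        assert hit_weight(hit("1", 90.0, alen=50, qlen=100)) == pytest.approx(
            0.45
        )

    def test_full_length_perfect_hit_is_one(self):
        assert hit_weight(hit("1", 100.0, alen=100, qlen=100)) == 1.0

    def test_zero_identity_is_zero(self):
        assert hit_weight(hit("1", 0.0)) == 0.0

    def test_gapped_alignment_fraction_capped_at_one(self):
        assert hit_weight(hit("1", 50.0, alen=150, qlen=100)) == 0.5


class TestAssignGene:
    def test_single_high_identity_hit_reaches_species(self, toy_tree):
        ga = assign_gene("g1", [hit("562", 96.0)], toy_tree)
        assert ga.depth == 7
        assert ga.lineage.names()[-1] == "Escherichia coli"
        assert ga.support["species"] == 1.0

    def test_even_phylum_split_stops_at_superkingdom(self, toy_tree):
        # 50/50 is not strictly greater than half
        hits = [hit("1224", 80.0), hit("1239", 80.0)]
        ga = assign_gene("g1", hits, toy_tree)
        assert ga.lineage.names() == ("Bacteria",)

    def test_identity_floor_stops_descent(self, toy_tree):
        # two agreeing hits at 85% identity pass the family floor (80) but
        # not the genus floor (90); a weak conflicting hit only dilutes
        hits = [
            hit("562", 85.0),            # weight 0.85
            hit("562", 85.0),            # weight 0.85
            hit("2157", 20.0),           # weight 0.20, below all floors
        ]
        ga = assign_gene("g1", hits, toy_tree)
        assert ga.depth == 5
        assert ga.lineage.names()[-1] == "Enterobacteriaceae"
        assert ga.support["family"] == pytest.approx(1.7 / 1.9)
        assert ga.total_weight == pytest.approx(1.9)

    def test_subthreshold_hits_stay_in_denominator(self, toy_tree):
        # one 96% species hit vs an equal-weight 30% junk hit: the junk hit
        # cannot vote anywhere but halves every support fraction
        hits = [hit("562", 96.0, alen=50), hit("2157", 96.0, alen=50),
                hit("562", 30.0)]
        ga = assign_gene("g1", hits, toy_tree)
        assert ga.depth == 0  # 0.48 vs total 1.26: no majority

    def test_empty_hit_list_is_contract_violation(self, toy_tree):
        with pytest.raises(ValueError):
            assign_gene("g1", [], toy_tree)

    def test_unknown_taxid_hits_are_dropped(self, toy_tree):
        ga = assign_gene("g1", [hit("999999", 96.0), hit("562", 96.0)],
                         toy_tree)
        assert ga.depth == 7
        assert ga.total_weight == pytest.approx(0.96)

    def test_order_independence(self, toy_tree):
        hits = [hit("562", 91.0), hit("561", 85.0), hit("1224", 55.0),
                hit("2157", 45.0)]
        base = assign_gene("g1", hits, toy_tree)
        for _ in range(5):
            rng = np.random.default_rng(_)
            shuffled = [hits[i] for i in rng.permutation(len(hits))]
            assert assign_gene("g1", shuffled, toy_tree).lineage == \
                base.lineage

    def test_raising_floor_never_deepens(self, toy_tree):
        hits = [hit("562", 91.0), hit("561", 96.0)]
        base = assign_gene("g1", hits, toy_tree)
        raised = dict(
            zip(
                ("superkingdom", "phylum", "class", "order", "family",
                 "genus", "species"),
                (40.0, 50.0, 60.0, 70.0, 80.0, 92.0, 95.0),
            )
        )
        deeper = assign_gene(
            "g1", hits, toy_tree, RankThresholds(min_identity=raised)
        )
        assert deeper.depth <= base.depth


class TestAssignContig:
    def ga(self, names_ids, weight, gene="g"):
        return GeneAssignment(gene, lineage(*names_ids), weight)

    def test_unanimous_genes(self):
        genes = [
            self.ga([("2", "Bacteria"), ("1224", "Proteobacteria")], 1.0,
                    f"g{i}")
            for i in range(3)
        ]
        ca = assign_contig("c1", genes)
        assert ca.lineage.names() == ("Bacteria", "Proteobacteria")
        assert ca.support == 1.0

    def test_two_thirds_majority_assigns_superkingdom(self):
        genes = [
            self.ga([("2", "Bacteria")], 1.0, "g1"),
            self.ga([("2", "Bacteria")], 1.0, "g2"),
            self.ga([("2759", "Eukaryota")], 1.0, "g3"),
        ]
        ca = assign_contig("c1", genes)
        assert ca.lineage.names() == ("Bacteria",)
        assert ca.support == pytest.approx(2 / 3)

    def test_exact_tie_leaves_contig_unassigned(self):
        genes = [
            self.ga([("2", "Bacteria")], 1.0, "g1"),
            self.ga([("2157", "Archaea")], 1.0, "g2"),
        ]
        assert assign_contig("c1", genes).depth == 0

    def test_unassigned_genes_are_ignored(self):
        genes = [
            self.ga([("2", "Bacteria")], 0.5, "g1"),
            GeneAssignment("g2", RankedLineage(), 5.0),
        ]
        ca = assign_contig("c1", genes)
        assert ca.lineage.names() == ("Bacteria",)
        assert ca.support == 1.0

    def test_shallow_genes_count_in_denominator_only(self):
        # one deep gene holds exactly half the weight: non-strict "at
        # least 50%" passes at phylum because the shallow gene votes for
        # nothing there
        genes = [
            self.ga([("2", "Bacteria"), ("1224", "Proteobacteria")], 1.0,
                    "g1"),
            self.ga([("2", "Bacteria")], 1.0, "g2"),
        ]
        ca = assign_contig("c1", genes)
        assert ca.lineage.names() == ("Bacteria", "Proteobacteria")
        assert ca.support == pytest.approx(0.5)

    def test_empty_gene_list_unassigned(self):
        assert assign_contig("c1", []).depth == 0

    def test_uniform_gene_weight_mode(self):
        genes = [
            self.ga([("2", "Bacteria")], 10.0, "g1"),
            self.ga([("2157", "Archaea")], 1.0, "g2"),
            self.ga([("2157", "Archaea")], 1.0, "g3"),
        ]
        weighted = assign_contig("c1", genes)
        uniform = assign_contig(
            "c1", genes, RankThresholds(uniform_gene_weights=True)
        )
        assert weighted.lineage.names() == ("Bacteria",)
        assert uniform.lineage.names() == ("Archaea",)


class TestPropagate:
    def test_contig_lineage_overwrites_deeper_gene(self):
        contig = assign_contig(
            "c1",
            [GeneAssignment("g1", lineage(("2", "Bacteria")), 1.0)],
        )
        deep = GeneAssignment(
            "g2",
            lineage(("2", "Bacteria"), ("1224", "Proteobacteria")),
            2.0,
        )
        (out,) = propagate(contig, [deep])
        assert out.lineage.names() == ("Bacteria",)
        assert out.total_weight == 2.0

    def test_unassigned_contig_clears_all_genes(self):
        from genecat.lca import ContigAssignment
        contig = ContigAssignment("c1", RankedLineage())
        genes = [GeneAssignment("g1", lineage(("2", "Bacteria")), 1.0)]
        assert propagate(contig, genes)[0].depth == 0

    def test_previously_unassigned_gene_adopts_contig_lineage(self):
        from genecat.lca import ContigAssignment
        contig = ContigAssignment(
            "c1", lineage(("2", "Bacteria")), support=1.0
        )
        genes = [GeneAssignment("g1", RankedLineage(), 0.0)]
        assert propagate(contig, genes)[0].lineage.names() == ("Bacteria",)


def test_full_stage_one_lineage_per_contig(toy_tree):
    hits_by_gene = {
        "g1": [hit("562", 96.0, gene="g1")],
        "g2": [hit("2157", 96.0, gene="g2")],
        "g3": [hit("562", 96.0, gene="g3")],
    }
    gene_to_contig = {"g1": "c1", "g2": "c1", "g3": "c1", "g4": "c1"}
    genes, contigs = assign_taxonomy(hits_by_gene, gene_to_contig, toy_tree)
    lineages = {genes[g].lineage for g in gene_to_contig}
    assert len(lineages) == 1  # propagation guarantee, incl. hitless g4
    assert contigs["c1"].lineage.names()[-1] == "Escherichia coli"
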