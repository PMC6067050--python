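"""Eligibility flagging, TPM normalization, and table summarization."""

import numpy as np
import pandas as pd
import pytest

from genecat.hmm_filter import AnnotationRecord
from genecat.lca import GeneAssignment
from genecat.quantify import (
    GeneRecord,
    compute_tpm,
    exclude_contigs,
    flag_eligible_genes,
    summarize_by_annotation,
    summarize_by_taxon,
)
from genecat.taxonomy import CANONICAL_RANKS, RankedLineage


def gene_map(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "contig_id", "gene_len", "contig_len"]
    )


class TestEligibility:
    def test_boundary_inclusive(self):
        records = flag_eligible_genes(
            gene_map([("g1", "c1", 300, 1000), ("g2", "c2", 300, 999)])
        )
        assert [r.eligible for r in records] == [True, False]

    def test_zero_cutoff_makes_all_eligible(self):
        records = flag_eligible_genes(
            gene_map([("g1", "c1", 300, 5)]), cutoff=0
        )
        assert records[0].eligible

    def test_unknown_contig_is_consistency_error(self):
        gm = gene_map([("g1", "c1", 300, np.nan)])
        with pytest.raises(ValueError, match="g1"):
            flag_eligible_genes(gm)

    def test_gene_len_must_be_positive(self):
        with pytest.raises(ValueError):
            GeneRecord("g1", "c1", 0, True)


class TestTpm:
    def test_worked_example(self):
        # lengths 1000/500 nt, counts 10/10, read length 100:
        # per-length rates 1 and 2, T = 3, TPM 333333.33 / 666666.67
        counts = pd.DataFrame({"S1": [10, 10]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, {"g1": 1000, "g2": 500}, {"S1": 100.0})
        assert tpm.loc["g1", "S1"] == pytest.approx(333333.33, abs=0.01)
        assert tpm.loc["g2", "S1"] == pytest.approx(666666.67, abs=0.01)

    def test_single_gene_gets_full_million(self):
        counts = pd.DataFrame({"S1": [7]}, index=["g1"])
        tpm = compute_tpm(counts, {"g1": 123}, {"S1": 95.5})
        assert tpm.loc["g1", "S1"] == pytest.approx(1e6)

    def test_all_zero_sample_stays_zero(self):
        counts = pd.DataFrame({"S1": [0, 0]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, {"g1": 100, "g2": 200}, {"S1": 100.0})
        assert (tpm["S1"] == 0).all()

    def test_per_sample_sums_to_one_million(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("ABCD"),
        )
        lengths = {f"g{i}": int(rng.integers(150, 3000)) for i in range(50)}
        rl = {s: float(rng.uniform(80, 150)) for s in "ABCD"}
        tpm = compute_tpm(counts, lengths, rl)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_invariant_to_uniform_count_scaling(self):
        counts = pd.DataFrame({"S1": [3, 9, 1]}, index=["a", "b", "c"])
        lengths = {"a": 100, "b": 300, "c": 900}
        t1 = compute_tpm(counts, lengths, {"S1": 100.0})
        t2 = compute_tpm(counts * 7, lengths, {"S1": 100.0})
        assert np.allclose(t1, t2)

    def test_matches_exact_arithmetic_oracle(self):
        from genecat import naive
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(20, 2)),
            index=[f"g{i}" for i in range(20)], columns=["S1", "S2"],
        )
        lengths = {f"g{i}": int(rng.integers(100, 2000)) for i in range(20)}
        for s, rl in (("S1", "101.5"), ("S2", "99")):
            exact = naive.tpm_exact(counts[s].to_dict(), lengths, rl)
            got = compute_tpm(counts, lengths, {"S1": 101.5, "S2": 99.0})[s]
            for g in counts.index:
                assert got[g] == pytest.approx(float(exact[g]), rel=1e-12)

    def test_missing_read_length_rejected(self):
        counts = pd.DataFrame({"S1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            compute_tpm(counts, {"g1": 100}, {})


COUNTS = pd.DataFrame(
    {"S1": [3, 4, 5], "S2": [1, 0, 2]}, index=["g1", "g2", "g3"]
)


class TestSummarizeByAnnotation:
    def test_sums_genes_sharing_annotation(self):
        anns = [AnnotationRecord("g1", "pfam", "PF1", 1.0, 1e-9),
                AnnotationRecord("g2", "pfam", "PF1", 1.0, 1e-9)]
        out = summarize_by_annotation(COUNTS, anns, "pfam")
        assert out.loc["PF1", "S1"] == 7

    def test_duplicate_domain_counts_twice(self):
        anns = [AnnotationRecord("g3", "pfam", "PF1", 1.0, 1e-9),
                AnnotationRecord("g3", "pfam", "PF1", 2.0, 1e-7)]
        out = summarize_by_annotation(COUNTS, anns, "pfam")
        assert out.loc["PF1", "S1"] == 10

    def test_other_sources_ignored_and_empty_ok(self):
        anns = [AnnotationRecord("g1", "eggnog", "NOG1", 1.0, 1e-9)]
        assert summarize_by_annotation(COUNTS, anns, "pfam").empty

    def test_unannotated_row_collects_rest(self):
        anns = [AnnotationRecord("g1", "pfam", "PF1", 1.0, 1e-9)]
        out = summarize_by_annotation(
            COUNTS, anns, "pfam", include_unannotated=True
        )
        assert out.loc["unannotated", "S1"] == 9


def assignment(gene, names):
    taxa = tuple(
        (CANONICAL_RANKS[i], f"t:{n}", n) for i, n in enumerate(names)
    )
    return GeneAssignment(gene, RankedLineage(taxa), 1.0)


class TestSummarizeByTaxon:
    TAX = {
        "g1": assignment("g1", ["Bacteria", "Proteobacteria"]),
        "g2": assignment("g2", ["Bacteria"]),
        "g3": assignment("g3", ["Archaea", "Euryarchaeota"]),
    }

    def test_superkingdom_rows(self):
        out = summarize_by_taxon(COUNTS, self.TAX, depth=1)
        assert out.loc["Bacteria", "S1"] == 7
        assert out.loc["Archaea", "S1"] == 5

    def test_shallow_gene_rolls_into_unclassified(self):
        out = summarize_by_taxon(COUNTS, self.TAX, depth=2)
        assert out.loc["unclassified", "S1"] == 4  # g2 stops at superkingdom
        assert out.loc["Bacteria;Proteobacteria", "S1"] == 3

    def test_hierarchical_conservation(self):
        for depth in range(1, 7):
            shallow = summarize_by_taxon(COUNTS, self.TAX, depth=depth)
            deep = summarize_by_taxon(COUNTS, self.TAX, depth=depth + 1)
            assert shallow.sum(axis=0).equals(deep.sum(axis=0))

    def test_genes_without_taxonomy_record_excluded(self):
        out = summarize_by_taxon(COUNTS, {"g1": self.TAX["g1"]}, depth=1)
        assert out.sum(axis=0)["S1"] == 3


class TestExcludeContigs:
    RECORDS = [
        GeneRecord("g1", "c1", 300, True),
        GeneRecord("g2", "spike", 300, True),
        GeneRecord("g3", "c2", 300, True),
    ]

    def test_spike_genes_removed(self):
        out = exclude_contigs(COUNTS, self.RECORDS, {"spike"})
        assert list(out.index) == ["g1", "g3"]

    def test_empty_exclusion_is_identity(self):
        assert exclude_contigs(COUNTS, self.RECORDS, set()).equals(COUNTS)

    def test_excluding_everything_empties_table(self):
        out = exclude_contigs(COUNTS, self.RECORDS, {"c1", "c2", "spike"})
        assert out.empty
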