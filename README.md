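# genecat

Annotation and quantification toolkit for co-assembled metagenome gene
catalogues.

When a set of shotgun metagenome samples is co-assembled into a reference
gene catalogue, the bespoke computational steps between the standard search
tools and the final count tables are: assigning taxonomy to genes and
contigs from protein-alignment hits, reducing raw HMM search output to
accepted functional annotations, mapping orthologous groups to Enzyme
Commission (EC) numbers, and normalizing per-gene read counts.  `genecat`
implements exactly those steps as a tested library plus a thin CLI.  It
consumes the *outputs* of DIAMOND/BLAST, hmmsearch/hmmscan, a gene caller
and a read counter — it never runs them — so it works on any catalogue at
any scale.

## Methods at a glance

**Weighted-LCA taxonomy.** Every alignment hit of a gene gets weight
*w = min(ℓ<sub>aln</sub>/ℓ<sub>query</sub>, 1) · id/100*, the aligned
fraction of the query times its fractional percent identity.  Descending
the rank ladder superkingdom → species, a hit supports its subject's taxon
at rank *r* only if its identity clears that rank's floor (40/50/60/70/80/
90/95 %).  The gene is assigned at *r* if one taxon's supporting weight
strictly exceeds half the total weight of all its hits.  Each contig is
then assigned the deepest rank at which a single taxon holds ≥ 50 % of its
genes' summed weights (and strictly outweighs every competitor), and that
consensus overwrites all gene-level calls: every gene on a contig shares
one lineage.

**HMM-hit filtering.** For single-annotation databases (EggNOG, TIGRFAM):
remove hits with full-sequence E-value > 1e-4, keep the best-scoring model
per gene.  For domain databases (dbCAN): keep every domain with model
coverage > 0.3 whose independent E-value is < 1e-5 (alignments > 80 aa) or
< 1e-3 (≤ 80 aa); strict mode further requires E < 1e-18 and coverage
> 0.35.

**EC mapping.** A group's EC set is the set of EC numbers carried by a
strict majority of its EC-assigned member proteins (after removing member
proteins with implausibly many EC entries); genes inherit their group's EC
set.

**Quantification.** Counts are summed per annotation (a gene carrying a
domain twice counts twice) and per taxon path at each rank.  TPM is

```
TPM_g = r_g · rl · 10^6 / (fl_g · T),    T = Σ_g r_g · rl / fl_g
```

with *r<sub>g</sub>* the read count, *rl* the sample's mean read length and
*fl<sub>g</sub>* the gene length; per sample TPM sums to 10^6.  Only genes
on contigs ≥ 1 kb are annotated; normalization uses all counted genes.

## Worked example

```python
>>> import pandas as pd
>>> from genecat.quantify import compute_tpm
>>> counts = pd.DataFrame({"S1": [10, 10]}, index=["g1", "g2"])
>>> compute_tpm(counts, {"g1": 1000, "g2": 500}, {"S1": 100.0})
               S1
g1  333333.333333
g2  666666.666667
```

Two genes with equal counts but lengths 1000 and 500 nt at read length
100: the per-length rates are 1 and 2, so the shorter gene gets two thirds
of the million.

```python
>>> from genecat import assign_gene, load_taxonomy
>>> from genecat.hit_io import read_alignment_hits
>>> tree = load_taxonomy(nodes_path="nodes.dmp", names_path="names.dmp")
>>> hits = list(read_alignment_hits("diamond_hits.tsv"))
>>> ga = assign_gene("gene_1", hits, tree)
>>> ga.lineage.names(), ga.support
```

The CLI mirrors the library: `genecat assign-taxonomy`, `genecat
filter-annotations`, `genecat assign-ec`, `genecat quantify`, and `genecat
make-fixture` (synthetic toy data with oracle ground truth).  Run any of
them with `--help`.

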