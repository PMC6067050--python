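# Methods

This note documents the models and procedures `genecat` implements, the
parameters that matter, the numerical and design choices made where the
conventions of the field leave room, and what the synthetic fixtures do and
do not establish.

## Weighted-LCA taxonomic assignment

The input is a tabular protein-alignment file (DIAMOND/BLAST "outfmt 6"
style) whose subjects carry taxon ids, plus a taxonomy (NCBI-style
`nodes.dmp`/`names.dmp` or a flat seven-rank lineage TSV).  Lineages are
projected onto the seven canonical ranks — superkingdom, phylum, class,
order, family, genus, species — skipping intermediate ranks such as
strains or subfamilies.  When a canonical rank is genuinely absent from a
taxon's ancestry the projection truncates at the gap (longest contiguous
prefix from superkingdom): this keeps the "no gaps" lineage invariant and
never invents a placement; it only affects trees with rank holes, which the
synthetic fixtures do not produce.

**Gene stage.** Each hit's weight is the product of its aligned query
fraction (capped at 1, since gapped alignments can exceed the query
length) and its fractional identity.  The two factors are the conventional
evidence measures; the product is the simplest combination consistent with
both, and the formula is isolated in `hit_weight` so alternatives can be
substituted.  At each rank, a hit supports its subject's taxon only if its
percent identity reaches that rank's floor:

| rank | superkingdom | phylum | class | order | family | genus | species |
|------|----|----|----|----|----|----|----|
| floor (% id) | 40 | 50 | 60 | 70 | 80 | 90 | 95 |

The denominator of the vote is the summed weight of *all* hits for the
gene — sub-floor and off-lineage hits dilute support rather than
disappearing.  Assignment at a rank requires one taxon's support to
*strictly* exceed half the denominator; descent stops at the first failing
rank.  The identity gate is applied per hit by default; a variant that
gates on the weighted-mean identity of the winning taxon is available
(`identity_gate="mean_identity"`), since both readings of "identity high
enough" are defensible.

**Contig stage.** Unassigned genes are ignored; each assigned gene votes
with its summed hit weight (weight 1 per gene with
`uniform_gene_weights=True`).  The contig descends to the deepest rank
where one taxon holds at least half of the summed gene weights *and*
strictly outweighs every competitor — the non-strict threshold together
with the unique-maximum requirement reconciles "at least 50 %" with
"majority": an exact two-way tie leaves the contig unassigned.  Genes
assigned above the current rank stay in the denominator but support no
taxon.  The contig lineage then overwrites every gene on the contig,
including genes that had no hits, so grouping genes by contig always
yields exactly one lineage per contig.

Hits whose subject taxid is missing from the tree are dropped (version
skew between an alignment database and a taxonomy dump is routine);
merged-taxid remapping is out of scope and callers must supply a
consistent tree.

## HMM-hit filtering

Raw HMMER3 per-domain tables (`--domtblout`) are parsed positionally by the
22-column convention, with the free-text description kept intact; a
`program` flag handles the query/target orientation difference between
`hmmscan` and `hmmsearch`.

*Top-score selection* (EggNOG, TIGRFAM): hits with full-sequence E-value
strictly greater than 1e-4 are removed — a hit at exactly the cutoff
survives — and the best full-sequence score per gene wins; ties break to
the lexicographically smallest model id for determinism.  Whether the
full-sequence or best-domain score drives selection is switchable
(`use_domain_score`); full-sequence is the default.  Pfam gathering
thresholds and TIGRFAM trusted cutoffs are applied by the upstream search
tools; this module does not re-implement them.

*dbCAN-style domain filtering*: model coverage `(hmm_to − hmm_from + 1) /
model_len` must be strictly greater than 0.3; alignments longer than 80 aa
need an independent E-value strictly below 1e-5, shorter ones below 1e-3;
strict mode (the bacteria-oriented recommendation) additionally requires
E < 1e-18 and coverage > 0.35.  The per-domain *independent* E-value is
compared, matching the upstream parser convention.  Every qualifying
domain is kept, so genes may carry several annotations.

## EC assignment by group majority

Reference proteins with more than `max_protein_ecs` (default 10) EC
entries are removed before voting: genuine multifunctional enzymes carry a
handful of ECs, while identifier collisions carry hundreds, so any value
in the wide gap between those regimes behaves identically.  Within a
group, only EC-assigned members vote; an EC is assigned iff it is carried
by strictly more than half of them (`strict_majority=False` relaxes to at
least half).  Partial EC strings ("1.1.-.-") are distinct labels, not
hierarchy nodes.  A protein belonging to several groups votes in each
independently.

## Quantification and TPM

Counts are whatever the upstream counter emits (mates counted
individually); `rl` is the per-sample mean read length over those same
units, supplied in sample metadata so users can match their counter's
convention.  TPM is computed over *all* counted genes — the 1 kb contig
cutoff governs which genes are annotated, not the normalization — and
conservation (Σ TPM = 10^6 per nonzero sample) is algebraically forced, so
the floating-point implementation is checked against an exact
`fractions.Fraction` oracle (observed agreement ~1e-15 relative).
Per-annotation tables sum gene rows per record, so a gene with the same
domain accepted twice contributes twice — deliberate, so each annotation's
abundance is self-contained.  Per-taxon tables are produced per rank
depth, with genes assigned above the queried depth pooled into an
`unclassified` row; column totals are therefore conserved across depths.
Per-annotation TPM is obtained by summing gene TPM values (not by
recomputing from summed counts).  Spike-in or other excluded contigs are
removed before normalization so they cannot influence T.

## Synthetic fixtures and the oracle

`genecat.fixtures` emulates: a complete binary seven-rank taxonomy, genes
grouped on contigs, hit identities drawn from truncated normals (sd 2)
around a per-target-depth mean (defaults 45/55/65/75/85/92.5/97.5 — each
sitting between consecutive identity floors), a configurable fraction of
genes with uniformly off-lineage hits (default 0.1), short contigs below
the eligibility cutoff (default rate 0.1), one spike-in contig, and
negative-binomial counts with per-sample read lengths.  Default scale is
30 contigs × 4 genes × 6 samples — small enough that the whole suite runs
in seconds, large enough to hit every code path.  It does **not** emulate
real sequence content, alignment score correlations, database redundancy
or realistic overdispersion, so passing tests demonstrate algorithmic
correctness and determinism, not recovery rates on real data.

Ground truth is computed by `genecat.naive`: deliberately naive loops
sharing no code with the production modules (the weight formula is
re-stated there because it *is* the definition under test).  Discrete
outcomes (lineages, EC sets, filter decisions) are compared exactly;
TPM is compared at 1e-9 relative tolerance since the oracle uses exact
rational arithmetic and production uses floats.

## Numerical and degenerate-input choices

- All boundary comparisons are implemented exactly as specified above
  (strict vs non-strict); unit tests pin each boundary.
- Winner selection in votes breaks exact weight ties deterministically (by
  taxid), but a tie can only matter below the majority threshold, where
  descent stops anyway; contig-level ties are unassigned by construction.
- Empty inputs: a gene with no hits or only unknown-taxid hits gets a
  depth-0 assignment; an empty gene list gives an unassigned contig; an
  all-zero sample gives all-zero TPM with T = 0; empty annotation sets give
  empty tables.
- Genes below the contig-length cutoff never enter the taxonomy or
  annotation stages but are normalized like any other counted gene.

## Known limitations

- No merged/deleted-taxid remapping and no accession→taxid mapping.
- The EggNOG/Pfam acquisition pipelines (gathering thresholds, clan
  resolution) are trusted upstream; only their tabular outputs are read.
- Per-annotation TPM summation order (sum of gene TPMs) is fixed, not
  configurable.
- The fixture oracle validates the algorithms, not parameter choices for
  any particular environment or database snapshot.
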