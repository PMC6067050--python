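"""Weighted lowest-common-ancestor taxonomy assignment.

Genes are assigned by a weighted per-rank majority vote over their protein
alignment hits, then contigs by a consensus vote over their genes'
preliminary assignments, and the contig assignment is finally propagated
back so that every gene on a contig shares one lineage.

The vote
--------
Each hit carries weight ``min(align_len / query_len, 1) * pct_identity/100``
— the aligned fraction of the query times the fractional identity.  Walking
the rank ladder from superkingdom to species, a hit supports its lineage's
taxon at rank *r* only if its percent identity clears that rank's identity
floor (defaults 40/50/60/70/80/90/95).  The gene is assigned at *r* if one
taxon's supporting weight strictly exceeds half the total weight of *all*
hits; descent stops at the first rank where no taxon manages that.

At the contig level each assigned gene votes with its summed hit weight; the
contig takes the most detailed rank at which a single taxon holds at least
half of the summed gene weights and strictly more than every competitor.
Genes without an assignment are ignored as voters, and genes assigned above
the current rank count in the denominator but support no taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hit_io import AlignmentHit
from .taxonomy import (
    CANONICAL_RANKS,
    RankedLineage,
    TaxonomyTree,
    lineage_of,
)

#: Per-rank identity floors: a hit may support an assignment at a rank only
#: if its percent identity reaches that rank's floor.
DEFAULT_MIN_IDENTITY: dict[str, float] = {
    "superkingdom": 40.0,
    "phylum": 50.0,
    "class": 60.0,
    "order": 70.0,
    "family": 80.0,
    "genus": 90.0,
    "species": 95.0,
}


@dataclass(frozen=True)
class RankThresholds:
    """Thresholds steering the gene and contig votes.

    ``gene_majority`` is strict (a taxon must hold *more* than this fraction
    of the total hit weight); ``contig_consensus`` is non-strict but the
    winning taxon must additionally hold strictly more weight than every
    competitor, so an exact two-way tie leaves the contig unassigned.
    """

    min_identity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_IDENTITY)
    )
    gene_majority: float = 0.5
    contig_consensus: float = 0.5
    identity_gate: str = "per_hit"  # or "mean_identity"
    uniform_gene_weights: bool = False

    def __post_init__(self) -> None:
        floors = [self.min_identity[r] for r in CANONICAL_RANKS]
        if any(b < a for a, b in zip(floors, floors[1:])):
            raise ValueError(
                "identity floors must be non-decreasing with rank depth: "
                f"{floors}"
            )
        if self.identity_gate not in ("per_hit", "mean_identity"):
            raise ValueError(
                f"identity_gate must be per_hit or mean_identity, "
                f"got {self.identity_gate!r}"
            )


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    lineage: RankedLineage
    total_weight: float
    support: Mapping[str, float] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return self.lineage.depth


@dataclass(frozen=True)
class ContigAssignment:
    contig_id: str
    lineage: RankedLineage
    support: float = 0.0

    @property
    def depth(self) -> int:
        return self.lineage.depth


def hit_weight(hit: AlignmentHit) -> float:
    """Weight of one hit: aligned query fraction times fractional identity.

    The aligned fraction is capped at 1 (gapped alignments can exceed the
    query length), so the weight lies in [0, 1].
    """
    if hit.query_len < 1:
        raise ValueError(f"query_len must be >= 1, got {hit.query_len}")
    return min(hit.align_len / hit.query_len, 1.0) * hit.pct_identity / 100.0


def assign_gene(
    gene_id: str,
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    thresholds: RankThresholds | None = None,
) -> GeneAssignment:
    """Assign a gene by weighted per-rank majority over its hits.

    Hits whose subject taxid is absent from the tree are dropped (they
    contribute nothing, not even to the denominator).  Raises ``ValueError``
    on an empty hit list.
    """
    if not hits:
        raise ValueError(f"assign_gene({gene_id!r}): empty hit list")
    thr = thresholds or RankThresholds()

    weighted: list[tuple[float, float, RankedLineage]] = []
    for h in hits:
        try:
            lin = lineage_of(tree, h.subject_taxid)
        except KeyError:
            continue
        weighted.append((hit_weight(h), h.pct_identity, lin))
    total = sum(w for w, _i, _l in weighted)
    if total <= 0.0:
        return GeneAssignment(gene_id, RankedLineage(), total, {})

    taxa: list[tuple[str, str, str]] = []
    support: dict[str, float] = {}
    for depth, rank in enumerate(CANONICAL_RANKS, start=1):
        floor = thr.min_identity[rank]
        votes: dict[tuple[str, str, str], float] = {}
        idsum: dict[tuple[str, str, str], float] = {}
        for w, ident, lin in weighted:
            taxon = lin.taxon_at(depth)
            if taxon is None:
                continue
            if thr.identity_gate == "per_hit" and ident < floor:
                continue
            votes[taxon] = votes.get(taxon, 0.0) + w
            idsum[taxon] = idsum.get(taxon, 0.0) + w * ident
        if not votes:
            break
        # deterministic winner: max weight, ties broken by taxid
        winner = max(votes, key=lambda t: (votes[t], t[1]))
        if votes[winner] <= thr.gene_majority * total:
            break
        if thr.identity_gate == "mean_identity":
            if idsum[winner] / votes[winner] < floor:
                break
        taxa.append(winner)
        support[rank] = votes[winner] / total
    return GeneAssignment(gene_id, RankedLineage(tuple(taxa)), total, support)


def assign_contig(
    contig_id: str,
    gene_assignments: Sequence[GeneAssignment],
    thresholds: RankThresholds | None = None,
) -> ContigAssignment:
    """Consensus taxonomy of a contig over its genes' assignments.

    Unassigned genes (depth 0) are ignored.  Each remaining gene votes with
    its total hit weight (or weight 1 with ``uniform_gene_weights``).  The
    contig descends to the deepest rank where one taxon holds at least
    ``contig_consensus`` of the summed weights and strictly outweighs every
    other taxon; if no superkingdom qualifies the contig stays unassigned.
    """
    thr = thresholds or RankThresholds()
    voters = [g for g in gene_assignments if g.depth > 0]
    if not voters:
        return ContigAssignment(contig_id, RankedLineage())

    def gw(g: GeneAssignment) -> float:
        return 1.0 if thr.uniform_gene_weights else g.total_weight

    denom = sum(gw(g) for g in voters)
    if denom <= 0.0:
        return ContigAssignment(contig_id, RankedLineage())

    taxa: list[tuple[str, str, str]] = []
    best_support = 0.0
    for depth in range(1, len(CANONICAL_RANKS) + 1):
        votes: dict[tuple[str, str, str], float] = {}
        for g in voters:
            taxon = g.lineage.taxon_at(depth)
            if taxon is None:
                continue  # assigned above this rank: denominator only
            votes[taxon] = votes.get(taxon, 0.0) + gw(g)
        if not votes:
            break
        winner = max(votes, key=lambda t: (votes[t], t[1]))
        wv = votes[winner]
        if wv < thr.contig_consensus * denom:
            break
        if any(v >= wv for t, v in votes.items() if t != winner):
            break  # tie (or beaten): no unique majority taxon
        taxa.append(winner)
        best_support = wv / denom
    return ContigAssignment(
        contig_id, RankedLineage(tuple(taxa)), best_support
    )


def propagate(
    contig: ContigAssignment, gene_assignments: Sequence[GeneAssignment]
) -> list[GeneAssignment]:
    """Overwrite every gene's lineage with the contig's shared assignment.

    Applies to all genes on the contig, including previously unassigned
    ones, so grouping genes by contig afterwards yields one lineage per
    contig.
    """
    out = []
    for g in gene_assignments:
        support = (
            {contig.lineage.taxa[-1][0]: contig.support}
            if contig.depth > 0
            else {}
        )
        out.append(
            GeneAssignment(g.gene_id, contig.lineage, g.total_weight, support)
        )
    return out


def assign_taxonomy(
    hits_by_gene: Mapping[str, Sequence[AlignmentHit]],
    gene_to_contig: Mapping[str, str],
    tree: TaxonomyTree,
    thresholds: RankThresholds | None = None,
) -> tuple[dict[str, GeneAssignment], dict[str, ContigAssignment]]:
    """Full taxonomy stage: gene vote, contig consensus, propagation.

    ``gene_to_contig`` must cover every gene to be assigned; genes with no
    hits get a depth-0 preliminary assignment but still receive the contig
    lineage by propagation.  Returns (per-gene, per-contig) assignment maps
    with the gene map already propagated.
    """
    thr = thresholds or RankThresholds()
    prelim: dict[str, GeneAssignment] = {}
    for gene_id in gene_to_contig:
        hits = hits_by_gene.get(gene_id, ())
        if hits:
            prelim[gene_id] = assign_gene(gene_id, hits, tree, thr)
        else:
            prelim[gene_id] = GeneAssignment(gene_id, RankedLineage(), 0.0)

    by_contig: dict[str, list[GeneAssignment]] = {}
    for gene_id, contig_id in gene_to_contig.items():
        by_contig.setdefault(contig_id, []).append(prelim[gene_id])

    genes: dict[str, GeneAssignment] = {}
    contigs: dict[str, ContigAssignment] = {}
    for contig_id in sorted(by_contig):
        members = by_contig[contig_id]
        ca = assign_contig(contig_id, members, thr)
        contigs[contig_id] = ca
        for g in propagate(ca, members):
            genes[g.gene_id] = g
    return genes, contigs


def write_assignments(path, assignments: Iterable, kind: str = "gene") -> None:
    """Write gene or contig assignments as a seven-rank TSV."""
    from ._io import open_text

    with open_text(path, "wt") as fh:
        id_col = "gene_id" if kind == "gene" else "contig_id"
        extra = (
            ["support", "total_weight"] if kind == "gene" else ["support"]
        )
        fh.write("#" + "\t".join([id_col, *CANONICAL_RANKS, *extra]) + "\n")
        for a in assignments:
            names = list(a.lineage.names())
            names += [""] * (len(CANONICAL_RANKS) - len(names))
            if kind == "gene":
                deepest = (
                    a.lineage.taxa[-1][0] if a.lineage.depth else ""
                )
                sup = a.support.get(deepest, "") if deepest else ""
                extra_vals = [
                    format(sup, ".6g") if sup != "" else "",
                    format(a.total_weight, ".6g"),
                ]
                ident = a.gene_id
            else:
                extra_vals = [format(a.support, ".6g") if a.depth else ""]
                ident = a.contig_id
            fh.write("\t".join([ident, *names, *extra_vals]) + "\n")
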