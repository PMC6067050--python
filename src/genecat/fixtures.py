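"""Synthetic toy datasets with known ground truth.

Generates an internally consistent bundle — taxonomy tree, gene catalogue,
protein-alignment hits, HMM domain tables, orthologous-group membership and
protein-EC tables, and count tables — at toy scale, in exactly the file
dialects the rest of the toolkit consumes.  Ground truth (the taxonomy the
weighted-LCA vote *should* produce, group EC majorities, exact TPM values)
is computed by the naive oracle in :mod:`genecat.naive`, never by the
production code, so round-tripping a fixture through the pipeline is a real
equivalence test.

What it emulates: hit identity decaying with taxonomic novelty (each gene
targets a recovery depth and its hits are drawn around that depth's mean
identity), off-lineage contamination hits, short contigs below the
annotation-eligibility cutoff, and a spike-in contig to exclude from
quantification.  What it does not emulate: real sequence content, alignment
biases, database redundancy, or realistic count overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import naive
from .hit_io import (
    AlignmentHit,
    DomainHit,
    write_alignment_hits,
    write_domtblout,
)
from .taxonomy import CANONICAL_RANKS


def _default_identity_decay() -> dict[int, float]:
    # mean hit identity for a gene meant to be recoverable to depth d;
    # sits between the floors of depth d and d+1
    return {1: 45.0, 2: 55.0, 3: 65.0, 4: 75.0, 5: 85.0, 6: 92.5, 7: 97.5}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_contigs: int = 30
    genes_per_contig: int = 4
    n_samples: int = 6
    contamination_rate: float = 0.1
    identity_decay: dict[int, float] = field(
        default_factory=_default_identity_decay
    )
    spike_contigs: int = 1
    short_contig_rate: float = 0.1
    min_hits: int = 2
    max_hits: int = 5
    identity_sd: float = 2.0
    branching: int = 2  # children per taxon at every rank

    def __post_init__(self) -> None:
        for name in ("contamination_rate", "short_contig_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for d, v in self.identity_decay.items():
            if not (1 <= d <= 7 and 0.0 <= v <= 100.0):
                raise ValueError(
                    f"identity_decay[{d}] = {v} outside rank 1-7 / [0, 100]"
                )


@dataclass
class Fixture:
    """In-memory fixture bundle plus oracle ground truth."""

    spec: FixtureSpec
    taxonomy_rows: list[tuple]  # (taxid, parent, rank, name)
    lineages: dict[str, tuple[str, ...]]  # species taxid -> 7 name path
    taxid_paths: dict[str, tuple[str, ...]]  # species taxid -> 7 taxid path
    gene_map: pd.DataFrame  # gene_id contig_id gene_len contig_len
    hits: list[AlignmentHit]
    eggnog_domains: list[DomainHit]
    dbcan_domains: list[DomainHit]
    members: dict[str, frozenset[str]]
    protein_ec: dict[str, frozenset[str]]
    counts: pd.DataFrame
    read_lengths: pd.Series
    spike_contig_ids: set[str]
    # ground truth (oracle-computed)
    truth_gene: dict[str, tuple[tuple[str, ...], float]]  # pre-propagation
    truth_contig: dict[str, tuple[tuple[str, ...], float]]
    truth_propagated: dict[str, tuple[str, ...]]
    truth_group_ec: dict[str, frozenset[str]]
    truth_tpm: pd.DataFrame


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _build_taxonomy(spec: FixtureSpec):
    """A complete tree with `branching` children per node at each rank."""
    rows = [("1", "1", "no rank", "root")]
    next_id = 2
    frontier = [("1", ())]  # (taxid, name path)
    lineages: dict[str, tuple[str, ...]] = {}
    taxid_paths: dict[str, tuple[str, ...]] = {}
    id_frontier = [("1", ())]
    for depth, rank in enumerate(CANONICAL_RANKS, start=1):
        new_frontier = []
        new_id_frontier = []
        for (parent, path), (_pid, idpath) in zip(frontier, id_frontier):
            for i in range(spec.branching):
                taxid = str(next_id)
                next_id += 1
                name = f"{rank[:2]}{taxid}"
                rows.append((taxid, parent, rank, name))
                np_path = path + (name,)
                nt_path = idpath + (taxid,)
                new_frontier.append((taxid, np_path))
                new_id_frontier.append((taxid, nt_path))
                if depth == len(CANONICAL_RANKS):
                    lineages[taxid] = np_path
                    taxid_paths[taxid] = nt_path
        frontier = new_frontier
        id_frontier = new_id_frontier
    return rows, lineages, taxid_paths


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a fixture bundle; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    taxonomy_rows, lineages, taxid_paths = _build_taxonomy(spec)
    species = sorted(lineages)

    # --- gene catalogue -------------------------------------------------
    gene_rows = []
    gene_ids = []
    contig_of: dict[str, str] = {}
    spike_ids = set()
    for c in range(spec.n_contigs + spec.spike_contigs):
        is_spike = c >= spec.n_contigs
        contig_id = f"spike_c{c}" if is_spike else f"c{c}"
        if is_spike:
            spike_ids.add(contig_id)
        glens = (rng.integers(100, 1000, size=spec.genes_per_contig)
                 * 3).tolist()
        short = (not is_spike) and rng.random() < spec.short_contig_rate
        if short:
            contig_len = int(rng.integers(300, 1000))
        else:
            contig_len = int(sum(glens) + rng.integers(0, 500))
            contig_len = max(contig_len, 1000)
        for g, glen in enumerate(glens):
            gene_id = f"{contig_id}_g{g}"
            gene_ids.append(gene_id)
            contig_of[gene_id] = contig_id
            gene_rows.append((gene_id, contig_id, int(glen), contig_len))
    gene_map = pd.DataFrame(
        gene_rows, columns=["gene_id", "contig_id", "gene_len", "contig_len"]
    )

    # --- alignment hits -------------------------------------------------
    # each contig has a true species; each gene targets a recovery depth
    hits: list[AlignmentHit] = []
    hits_raw: dict[str, list[tuple]] = {}
    contig_species = {}
    depths = sorted(spec.identity_decay)
    for contig_id in gene_map["contig_id"].unique():
        contig_species[contig_id] = species[rng.integers(len(species))]
    for gene_id in gene_ids:
        contig_id = contig_of[gene_id]
        true_sp = contig_species[contig_id]
        target_depth = depths[rng.integers(len(depths))]
        mean_ident = spec.identity_decay[target_depth]
        n_hits = int(rng.integers(spec.min_hits, spec.max_hits + 1))
        contaminated = rng.random() < spec.contamination_rate
        qlen = int(rng.integers(100, 500))
        raw = []
        for k in range(n_hits):
            if contaminated:
                subj = species[rng.integers(len(species))]
            else:
                subj = true_sp
            ident = _truncnorm(rng, mean_ident, spec.identity_sd, 0.0, 100.0)
            ident = round(ident, 1)
            alen = int(rng.integers(max(1, qlen // 2), qlen + 1))
            hit = AlignmentHit(
                query_id=gene_id,
                subject_id=f"ref_{subj}_{k}",
                subject_taxid=subj,
                pct_identity=ident,
                align_len=alen,
                query_len=qlen,
                evalue=float(f"{10.0 ** -int(rng.integers(10, 60)):.1e}"),
                bitscore=round(float(rng.uniform(50, 500)), 1),
            )
            hits.append(hit)
            raw.append((ident, alen, qlen, taxid_paths[subj]))
        hits_raw[gene_id] = raw

    # --- oracle taxonomy ground truth ----------------------------------
    truth_gene: dict[str, tuple[tuple[str, ...], float]] = {}
    for gene_id in gene_ids:
        lin, total, _sup = naive.gene_vote(hits_raw[gene_id])
        truth_gene[gene_id] = (lin, total)
    truth_contig: dict[str, tuple[tuple[str, ...], float]] = {}
    truth_propagated: dict[str, tuple[str, ...]] = {}
    for contig_id in gene_map["contig_id"].unique():
        members_g = [g for g in gene_ids if contig_of[g] == contig_id]
        lin, sup = naive.contig_vote(
            [truth_gene[g] for g in members_g]
        )
        truth_contig[contig_id] = (lin, sup)
        for g in members_g:
            truth_propagated[g] = lin

    # --- HMM domains ----------------------------------------------------
    nogs = [f"NOG{i:05d}" for i in range(1, 9)]
    nog_len = {m: int(rng.integers(120, 400)) for m in nogs}
    cazys = [f"GH{i}" for i in (1, 2, 3, 5, 13)]
    cazy_len = {m: int(rng.integers(100, 300)) for m in cazys}
    eggnog_domains: list[DomainHit] = []
    dbcan_domains: list[DomainHit] = []
    for gene_id in gene_ids:
        for m in rng.choice(nogs, size=rng.integers(1, 4), replace=False):
            mlen = nog_len[m]
            hf = int(rng.integers(1, mlen // 2))
            ht = int(rng.integers(hf, mlen + 1))
            eggnog_domains.append(DomainHit(
                query_id=gene_id, model_id=str(m), model_len=mlen,
                full_seq_evalue=float(f"{10.0 ** -int(rng.integers(2, 40)):.1e}"),
                full_seq_score=round(float(rng.uniform(20, 400)), 1),
                dom_ievalue=float(f"{10.0 ** -int(rng.integers(2, 40)):.1e}"),
                hmm_from=hf, hmm_to=ht,
                ali_from=1, ali_to=ht - hf + 1,
            ))
        if rng.random() < 0.5:
            m = str(rng.choice(cazys))
            mlen = cazy_len[m]
            hf = int(rng.integers(1, mlen // 2))
            ht = int(rng.integers(hf, mlen + 1))
            af = int(rng.integers(1, 50))
            at = af + int(rng.integers(20, 200))
            dbcan_domains.append(DomainHit(
                query_id=gene_id, model_id=m, model_len=mlen,
                full_seq_evalue=float(f"{10.0 ** -int(rng.integers(1, 30)):.1e}"),
                full_seq_score=round(float(rng.uniform(20, 300)), 1),
                dom_ievalue=float(f"{10.0 ** -int(rng.integers(1, 30)):.1e}"),
                hmm_from=hf, hmm_to=ht, ali_from=af, ali_to=at,
                description=f"glycoside hydrolase family {m[2:]}",
            ))

    # --- orthologous groups and protein ECs ------------------------------
    proteins = [f"P{i:03d}" for i in range(1, 41)]
    protein_ec: dict[str, frozenset[str]] = {}
    ec_pool = ["1.1.1.1", "2.7.7.7", "3.2.1.4", "3.2.1.21", "1.1.-.-"]
    for p in proteins:
        r = rng.random()
        if r < 0.3:
            continue  # unmapped protein
        k = 1 if r < 0.85 else 2
        protein_ec[p] = frozenset(
            str(e) for e in rng.choice(ec_pool, size=k, replace=False)
        )
    # one deliberate outlier with implausibly many ECs
    protein_ec["P_outlier"] = frozenset(
        f"9.9.{i}.{j}" for i in range(1, 6) for j in range(1, 6)
    )
    members: dict[str, frozenset[str]] = {}
    for m in nogs:
        size = int(rng.integers(3, 8))
        chosen = list(rng.choice(proteins, size=size, replace=False))
        if rng.random() < 0.2:
            chosen.append("P_outlier")
        members[m] = frozenset(str(p) for p in chosen)
    clean = {p: e for p, e in protein_ec.items()
             if len(e) <= 10}  # oracle-side outlier removal
    truth_group_ec = {
        g: frozenset(naive.ec_majority(
            [clean.get(p, frozenset()) for p in sorted(members[g])]
        ))
        for g in members
    }

    # --- counts and exact TPM -------------------------------------------
    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.05, size=(len(gene_ids),
                                             spec.n_samples)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    read_lengths = pd.Series(
        [round(float(rng.uniform(90, 150)), 1) for _ in sample_ids],
        index=pd.Index(sample_ids, name="sample_id"),
        name="mean_read_length",
    )
    glen = dict(zip(gene_map["gene_id"], gene_map["gene_len"]))
    tpm_cols = {}
    for s in sample_ids:
        exact = naive.tpm_exact(
            counts[s].to_dict(), glen, Fraction(str(read_lengths[s]))
        )
        tpm_cols[s] = [float(exact[g]) for g in gene_ids]
    truth_tpm = pd.DataFrame(
        tpm_cols, index=pd.Index(gene_ids, name="gene_id")
    )

    return Fixture(
        spec=spec,
        taxonomy_rows=taxonomy_rows,
        lineages=lineages,
        taxid_paths=taxid_paths,
        gene_map=gene_map,
        hits=hits,
        eggnog_domains=eggnog_domains,
        dbcan_domains=dbcan_domains,
        members=members,
        protein_ec=protein_ec,
        counts=counts,
        read_lengths=read_lengths,
        spike_contig_ids=spike_ids,
        truth_gene=truth_gene,
        truth_contig=truth_contig,
        truth_propagated=truth_propagated,
        truth_group_ec=truth_group_ec,
        truth_tpm=truth_tpm,
    )


def write_fixture(fx: Fixture, out_dir) -> dict[str, Path]:
    """Write the bundle in the dialects the toolkit consumes.

    Returns a name -> path map.  Byte-identical output for identical specs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = paths["nodes"] = out / "nodes.dmp"
    with open(p, "w") as fh:
        for taxid, parent, rank, _name in fx.taxonomy_rows:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    p = paths["names"] = out / "names.dmp"
    with open(p, "w") as fh:
        for taxid, _parent, _rank, name in fx.taxonomy_rows:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    p = paths["lineage_tsv"] = out / "lineages.tsv"
    with open(p, "w") as fh:
        fh.write("#taxid\t" + "\t".join(CANONICAL_RANKS) + "\n")
        for taxid in sorted(fx.lineages, key=int):
            fh.write(taxid + "\t" + "\t".join(fx.lineages[taxid]) + "\n")

    paths["hits"] = out / "hits.tsv"
    write_alignment_hits(paths["hits"], fx.hits)
    paths["eggnog_domtbl"] = out / "eggnog.domtbl"
    write_domtblout(paths["eggnog_domtbl"], fx.eggnog_domains,
                    program="hmmsearch")
    paths["dbcan_domtbl"] = out / "dbcan.domtbl"
    write_domtblout(paths["dbcan_domtbl"], fx.dbcan_domains,
                    program="hmmscan")

    p = paths["gene_map"] = out / "gene_map.tsv"
    fx.gene_map.to_csv(p, sep="\t", index=False)
    p = paths["counts"] = out / "counts.tsv"
    fx.counts.to_csv(p, sep="\t")
    p = paths["samples"] = out / "samples.tsv"
    fx.read_lengths.to_frame().to_csv(p, sep="\t")
    p = paths["spike_contigs"] = out / "spike_contigs.txt"
    with open(p, "w") as fh:
        for c in sorted(fx.spike_contig_ids):
            fh.write(c + "\n")

    p = paths["members"] = out / "members.tsv"
    with open(p, "w") as fh:
        fh.write("#group_id\tmembers\n")
        for g in sorted(fx.members):
            fh.write(g + "\t" + ",".join(sorted(fx.members[g])) + "\n")
    p = paths["protein_ec"] = out / "protein_ec.tsv"
    with open(p, "w") as fh:
        fh.write("#protein_id\tec_numbers\n")
        for prot in sorted(fx.protein_ec):
            fh.write(prot + "\t" + ",".join(sorted(fx.protein_ec[prot]))
                     + "\n")

    truth = out / "truth"
    truth.mkdir(exist_ok=True)
    p = paths["truth_gene"] = truth / "gene_taxonomy.tsv"
    with open(p, "w") as fh:
        fh.write("#gene_id\tlineage_taxids\ttotal_weight\n")
        for g in sorted(fx.truth_gene):
            lin, w = fx.truth_gene[g]
            fh.write(f"{g}\t{';'.join(lin)}\t{w:.10g}\n")
    p = paths["truth_contig"] = truth / "contig_taxonomy.tsv"
    with open(p, "w") as fh:
        fh.write("#contig_id\tlineage_taxids\tsupport\n")
        for c in sorted(fx.truth_contig):
            lin, sup = fx.truth_contig[c]
            fh.write(f"{c}\t{';'.join(lin)}\t{sup:.10g}\n")
    p = paths["truth_propagated"] = truth / "propagated_gene_taxonomy.tsv"
    with open(p, "w") as fh:
        fh.write("#gene_id\tlineage_taxids\n")
        for g in sorted(fx.truth_propagated):
            fh.write(f"{g}\t{';'.join(fx.truth_propagated[g])}\n")
    p = paths["truth_group_ec"] = truth / "group_ec.tsv"
    with open(p, "w") as fh:
        fh.write("#group_id\tec_numbers\n")
        for g in sorted(fx.truth_group_ec):
            fh.write(g + "\t" + ",".join(sorted(fx.truth_group_ec[g]))
                     + "\n")
    p = paths["truth_tpm"] = truth / "tpm.tsv"
    fx.truth_tpm.round(6).to_csv(p, sep="\t")
    return paths
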