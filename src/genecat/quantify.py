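"""Per-gene, per-annotation and per-taxon quantification with TPM.

Raw counts are reads (mates) per gene per sample, as delivered by an
upstream counter.  The length- and depth-normalized abundance is TPM
computed analogously to transcriptomics::

    TPM_g = r_g * rl * 1e6 / (fl_g * T),    T = sum_g r_g * rl / fl_g

where ``r_g`` is the read count of gene *g*, ``rl`` the sample's mean read
length, and ``fl_g`` the gene's nucleotide length.  Per sample the TPM
values of all genes sum to one million whenever any count is nonzero.

Annotation eligibility is a separate concern from normalization: only
genes on contigs at or above a length cutoff (default 1 kb) are annotated,
but TPM is computed over all counted genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._io import open_text
from .hmm_filter import (
    SINGLE_ANNOTATION_SOURCES,
    AnnotationRecord,
)
from .lca import GeneAssignment
from .taxonomy import CANONICAL_RANKS

DEFAULT_CONTIG_LENGTH_CUTOFF = 1000  # nt; genes on shorter contigs are not annotated


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig_id: str
    gene_len: int
    eligible: bool

    def __post_init__(self) -> None:
        if self.gene_len < 1:
            raise ValueError(
                f"gene {self.gene_id}: gene_len must be >= 1, "
                f"got {self.gene_len}"
            )


def flag_eligible_genes(
    gene_map: pd.DataFrame,
    cutoff: int = DEFAULT_CONTIG_LENGTH_CUTOFF,
) -> list[GeneRecord]:
    """Flag genes on contigs of length >= ``cutoff`` as annotation-eligible.

    ``gene_map`` needs columns gene_id, contig_id, gene_len, contig_len.
    The boundary is inclusive: a contig of exactly the cutoff length
    qualifies.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    required = {"gene_id", "contig_id", "gene_len", "contig_len"}
    missing = required.difference(gene_map.columns)
    if missing:
        raise ValueError(f"gene map lacks column(s): {sorted(missing)}")
    if gene_map["contig_len"].isna().any():
        bad = gene_map.loc[gene_map["contig_len"].isna(), "gene_id"]
        raise ValueError(
            f"gene(s) referencing unknown contig: {list(bad[:5])}"
        )
    return [
        GeneRecord(
            str(row.gene_id),
            str(row.contig_id),
            int(row.gene_len),
            bool(row.contig_len >= cutoff),
        )
        for row in gene_map.itertuples(index=False)
    ]


def compute_tpm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int] | pd.Series,
    read_lengths: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """TPM-normalize a genes x samples count table.

    ``gene_lengths`` are nucleotide lengths for every counted gene;
    ``read_lengths`` are per-sample mean read lengths (> 0).  A sample with
    all-zero counts yields all-zero TPM.
    """
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()][:5])
        raise ValueError(f"no gene length for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rl = pd.Series(read_lengths, dtype=float).reindex(counts.columns)
    if rl.isna().any() or (rl <= 0).any():
        raise ValueError("every sample needs a mean read length > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")

    rate = counts.div(lengths, axis=0).mul(rl, axis=1)  # r_g * rl / fl_g
    t = rate.sum(axis=0)  # T per sample
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rate.div(t, axis=1) * 1e6
    tpm[tpm.columns[t == 0]] = 0.0
    tpm.attrs["normalizer"] = t
    return tpm


def summarize_by_annotation(
    table: pd.DataFrame,
    annotations: Iterable[AnnotationRecord],
    source: str,
    include_unannotated: bool = False,
) -> pd.DataFrame:
    """Sum a genes x samples table into an annotations x samples table.

    Each (gene, annotation) record contributes the gene's full row; a gene
    carrying the same annotation id twice (two accepted domains)
    contributes twice — multi-domain double counting is deliberate so each
    annotation's abundance is self-contained.  Genes without any record in
    the source are excluded unless ``include_unannotated`` adds a pooled
    "unannotated" row.
    """
    pairs = [
        (r.annotation_id, r.gene_id)
        for r in annotations
        if r.source == source and r.gene_id in table.index
    ]
    if not pairs:
        out = pd.DataFrame(columns=table.columns, dtype=float)
        out.index.name = "annotation_id"
        return out
    df = pd.DataFrame(pairs, columns=["annotation_id", "gene_id"])
    values = table.loc[df["gene_id"]].to_numpy()
    summed = (
        pd.DataFrame(values, columns=table.columns)
        .assign(annotation_id=df["annotation_id"].to_numpy())
        .groupby("annotation_id")
        .sum()
    )
    if include_unannotated:
        annotated_genes = set(df["gene_id"])
        rest = table.loc[[g for g in table.index if g not in annotated_genes]]
        summed.loc["unannotated"] = rest.sum(axis=0)
    summed.index.name = "annotation_id"
    return summed.sort_index()


def summarize_by_taxon(
    table: pd.DataFrame,
    gene_taxonomy: Mapping[str, GeneAssignment],
    depth: int,
    unclassified_label: str = "unclassified",
) -> pd.DataFrame:
    """Sum a genes x samples table by taxon path at a given rank depth.

    Genes whose propagated lineage is shallower than ``depth`` (including
    wholly unassigned genes) pool into an "unclassified" row, so every
    depth's column totals equal the table's totals over genes with a
    taxonomy record.
    """
    if not 1 <= depth <= len(CANONICAL_RANKS):
        raise ValueError(f"depth must be in 1..{len(CANONICAL_RANKS)}")
    paths = []
    genes = []
    for gene_id in table.index:
        ga = gene_taxonomy.get(gene_id)
        if ga is None:
            continue
        genes.append(gene_id)
        if ga.lineage.depth >= depth:
            paths.append(";".join(ga.lineage.names()[:depth]))
        else:
            paths.append(unclassified_label)
    if not genes:
        out = pd.DataFrame(columns=table.columns, dtype=float)
        out.index.name = "taxon_path"
        return out
    out = (
        table.loc[genes]
        .assign(taxon_path=paths)
        .groupby("taxon_path")
        .sum()
        .sort_index()
    )
    out.index.name = "taxon_path"
    return out


def exclude_contigs(
    counts: pd.DataFrame,
    gene_records: Iterable[GeneRecord],
    contig_ids: set[str],
) -> pd.DataFrame:
    """Drop all genes hosted on the listed contigs (e.g. a spike-in).

    Applied before normalization so excluded material does not influence T.
    """
    excluded_genes = {
        g.gene_id for g in gene_records if g.contig_id in contig_ids
    }
    keep = [g for g in counts.index if g not in excluded_genes]
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TSV I/O


def read_count_table(path) -> pd.DataFrame:
    """Read a gene x sample count TSV (first column gene_id)."""
    df = pd.read_csv(open_text(path), sep="\t")
    df.columns = [str(c).lstrip("#") for c in df.columns]
    df = df.set_index("gene_id")
    df.index = df.index.astype(str)
    return df


def read_sample_metadata(path) -> pd.Series:
    """Read sample_id -> mean_read_length from a two-column TSV."""
    df = pd.read_csv(open_text(path), sep="\t")
    df.columns = [str(c).lstrip("#") for c in df.columns]
    return df.set_index("sample_id")["mean_read_length"].astype(float)


def read_gene_map(path) -> pd.DataFrame:
    """Read gene_id, contig_id, gene_len, contig_len from a TSV."""
    df = pd.read_csv(
        open_text(path), sep="\t",
        dtype={"gene_id": str, "contig_id": str},
    )
    df.columns = [str(c).lstrip("#") for c in df.columns]
    return df


def write_table(path, table: pd.DataFrame) -> None:
    with open_text(path, "wt") as fh:
        fh.write("#" + table.index.name + "\t")
        fh.write("\t".join(map(str, table.columns)) + "\n")
        table.to_csv(fh, sep="\t", header=False, float_format="%.6g")
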