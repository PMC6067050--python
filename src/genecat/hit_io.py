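"""Readers (and fixture writers) for search-tool outputs.

Two dialects are supported:

* BLAST/DIAMOND tabular ("outfmt 6" style) with a configurable column
  order.  The default order adds the query length and subject taxid columns
  that the taxonomy-assignment algorithm needs::

      qseqid sseqid pident length evalue bitscore qlen staxids

* HMMER3 per-domain tables (``--domtblout``): whitespace-delimited fixed
  columns, with the free-text target description as the trailing remainder.
  ``hmmscan`` output puts the model first and the query fourth;
  ``hmmsearch`` swaps them — pass ``program=`` accordingly.

Both readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from ._io import open_text


class ParseError(ValueError):
    """A malformed line in a hit file; carries path and line number."""


class ColumnSpecError(ValueError):
    """The configured column order lacks a required column."""


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-alignment record from a tabular search output."""

    query_id: str
    subject_id: str
    subject_taxid: str
    pct_identity: float
    align_len: int
    query_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(
                f"pct_identity {self.pct_identity} outside [0, 100]"
            )
        if self.align_len < 1:
            raise ValueError(f"align_len {self.align_len} < 1")
        if self.query_len >= 1 and self.align_len > 2 * self.query_len:
            raise ValueError(
                f"align_len {self.align_len} exceeds twice query_len "
                f"{self.query_len}"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")


@dataclass(frozen=True)
class DomainHit:
    """One HMMER3 per-domain record (one row of a domtblout file)."""

    query_id: str
    model_id: str
    model_len: int
    full_seq_evalue: float
    full_seq_score: float
    dom_ievalue: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    description: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.hmm_from <= self.hmm_to <= self.model_len:
            raise ValueError(
                f"hmm coordinates {self.hmm_from}-{self.hmm_to} invalid for "
                f"model length {self.model_len}"
            )
        if self.ali_from > self.ali_to:
            raise ValueError(
                f"alignment coordinates {self.ali_from}-{self.ali_to} "
                "inverted"
            )


DEFAULT_ALIGNMENT_COLUMNS: tuple[str, ...] = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "qlen",
    "staxids",
)

_REQUIRED_ALIGNMENT_COLUMNS = frozenset(DEFAULT_ALIGNMENT_COLUMNS)


def read_alignment_hits(
    path,
    column_spec: Sequence[str] = DEFAULT_ALIGNMENT_COLUMNS,
    expand_taxids: bool = True,
) -> Iterator[AlignmentHit]:
    """Stream alignment hits from a tabular search output.

    ``column_spec`` names the columns in file order and must contain all of
    qseqid, sseqid, pident, length, evalue, bitscore, qlen, staxids.  A
    ';'-separated staxids field (emitted for identical reference sequences)
    expands to one hit per taxid, each carrying the full weight, unless
    ``expand_taxids`` is False (then only the first taxid is kept).
    """
    missing = _REQUIRED_ALIGNMENT_COLUMNS.difference(column_spec)
    if missing:
        raise ColumnSpecError(
            f"column_spec lacks required column(s): {sorted(missing)}"
        )
    idx = {name: i for i, name in enumerate(column_spec)}
    ncol = len(column_spec)
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol} columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[idx["pident"]])
                align_len = int(fields[idx["length"]])
                query_len = int(fields[idx["qlen"]])
                evalue = float(fields[idx["evalue"]])
                bitscore = float(fields[idx["bitscore"]])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: malformed numeric field ({exc})"
                ) from None
            taxids = fields[idx["staxids"]].split(";")
            if not expand_taxids:
                taxids = taxids[:1]
            for taxid in taxids:
                taxid = taxid.strip()
                if not taxid:
                    continue
                try:
                    yield AlignmentHit(
                        query_id=fields[idx["qseqid"]],
                        subject_id=fields[idx["sseqid"]],
                        subject_taxid=taxid,
                        pct_identity=pident,
                        align_len=align_len,
                        query_len=query_len,
                        evalue=evalue,
                        bitscore=bitscore,
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None


def write_alignment_hits(
    path,
    hits: Iterable[AlignmentHit],
    column_spec: Sequence[str] = DEFAULT_ALIGNMENT_COLUMNS,
) -> None:
    """Write hits in the tabular dialect read_alignment_hits consumes."""
    getters = {
        "qseqid": lambda h: h.query_id,
        "sseqid": lambda h: h.subject_id,
        "pident": lambda h: format(h.pct_identity, ".3f"),
        "length": lambda h: str(h.align_len),
        "evalue": lambda h: format(h.evalue, ".2e"),
        "bitscore": lambda h: format(h.bitscore, ".1f"),
        "qlen": lambda h: str(h.query_len),
        "staxids": lambda h: h.subject_taxid,
    }
    with open_text(path, "wt") as fh:
        for hit in hits:
            fh.write("\t".join(getters[c](hit) for c in column_spec) + "\n")


# domtblout fixed layout (HMMER3): 22 whitespace-separated columns then the
# free-text description.  Column indices below are 0-based.
_DOMTBL_MIN_COLS = 22


def read_domtblout(path, program: str = "hmmscan") -> Iterator[DomainHit]:
    """Stream per-domain records from a HMMER3 ``--domtblout`` file.

    ``program`` selects the column orientation: ``hmmscan`` reports the
    model as target (columns 1-3) and the query as query (columns 4-6);
    ``hmmsearch`` is the reverse.  The trailing description (which may
    contain spaces) is kept intact.
    """
    if program not in ("hmmscan", "hmmsearch"):
        raise ValueError(f"program must be hmmscan or hmmsearch, got {program!r}")
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split(None, _DOMTBL_MIN_COLS)
            if len(fields) < _DOMTBL_MIN_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} "
                    f"domtblout columns, got {len(fields)}"
                )
            description = fields[22] if len(fields) > 22 else ""
            target_name, target_len = fields[0], fields[2]
            query_name, query_len_aa = fields[3], fields[5]
            if program == "hmmscan":
                model_id, model_len = target_name, target_len
                query_id = query_name
            else:
                model_id, model_len = query_name, query_len_aa
                query_id = target_name
            try:
                yield DomainHit(
                    query_id=query_id,
                    model_id=model_id,
                    model_len=int(model_len),
                    full_seq_evalue=float(fields[6]),
                    full_seq_score=float(fields[7]),
                    dom_ievalue=float(fields[12]),
                    hmm_from=int(fields[15]),
                    hmm_to=int(fields[16]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                    description=description,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None


def write_domtblout(path, hits: Iterable[DomainHit],
                    program: str = "hmmscan") -> None:
    """Write domain hits in the domtblout layout read_domtblout consumes.

    Fields this toolkit does not model (accessions, bias, per-domain
    score, envelope coordinates, acc) are written as placeholders.
    """
    with open_text(path, "wt") as fh:
        fh.write("# synthetic domtblout written by genecat fixtures\n")
        for h in hits:
            if program == "hmmscan":
                tname, tlen = h.model_id, h.model_len
                qname, qlen = h.query_id, h.ali_to
            else:
                tname, tlen = h.query_id, h.ali_to
                qname, qlen = h.model_id, h.model_len
            row = [
                tname, "-", str(tlen), qname, "-", str(qlen),
                format(h.full_seq_evalue, ".2e"),
                format(h.full_seq_score, ".1f"), "0.0",
                "1", "1",
                format(h.dom_ievalue, ".2e"),
                format(h.dom_ievalue, ".2e"),
                format(h.full_seq_score, ".1f"), "0.0",
                str(h.hmm_from), str(h.hmm_to),
                str(h.ali_from), str(h.ali_to),
                str(h.ali_from), str(h.ali_to), "0.90",
            ]
            fh.write(" ".join(row))
            if h.description:
                fh.write(" " + h.description)
            fh.write("\n")
        fh.write("#\n")
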