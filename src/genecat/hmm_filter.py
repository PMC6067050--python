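"""Filtering of raw HMM search hits into accepted functional annotations.

Two selection regimes are implemented, matching how the common profile
databases are used on gene catalogues:

* **top-score** (EggNOG, TIGRFAM): an E-value prefilter followed by keeping
  the single best-scoring model per gene — at most one annotation per gene.
* **dbCAN-style domain filtering**: per-domain rules on model coverage,
  alignment length and independent E-value; every qualifying domain is
  kept, so a gene may carry several annotations.

All comparisons follow strict/non-strict boundaries exactly as configured:
the E-value prefilter removes hits with E *strictly greater* than the
cutoff (a hit at exactly the cutoff survives), dbCAN coverage must be
*strictly greater* than its floor, and dbCAN E-values must be *strictly
less* than their ceilings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from ._io import open_text
from .hit_io import DomainHit

logger = logging.getLogger(__name__)

SINGLE_ANNOTATION_SOURCES = frozenset({"eggnog", "tigrfam"})
MULTI_ANNOTATION_SOURCES = frozenset({"pfam", "dbcan"})
VALID_SOURCES = SINGLE_ANNOTATION_SOURCES | MULTI_ANNOTATION_SOURCES | {"ec"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One accepted (gene, annotation) pair with its supporting scores."""

    gene_id: str
    source: str
    annotation_id: str
    score: float
    evalue: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"unknown annotation source {self.source!r}; "
                f"expected one of {sorted(VALID_SOURCES)}"
            )


def filter_top_score(
    hits: Iterable[DomainHit],
    source: str,
    max_evalue: float = 1e-4,
    use_domain_score: bool = False,
) -> list[AnnotationRecord]:
    """E-value prefilter then best-scoring model per gene.

    Hits with full-sequence E-value strictly above ``max_evalue`` are
    removed; for each remaining gene the hit with the highest score is
    kept (full-sequence score by default).  Score ties break to the
    lexicographically smallest model id for determinism.
    """
    best: dict[str, DomainHit] = {}
    for h in hits:
        if h.full_seq_evalue > max_evalue:
            continue
        score = h.full_seq_score
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        cur_score = cur.full_seq_score
        if (score, _neg_lex(h.model_id)) > (cur_score, _neg_lex(cur.model_id)):
            best[h.query_id] = h
    return [
        AnnotationRecord(
            gene_id=h.query_id,
            source=source,
            annotation_id=h.model_id,
            score=h.full_seq_score,
            evalue=h.full_seq_evalue,
            description=h.description,
        )
        for h in (best[g] for g in sorted(best))
    ]


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller model id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class DbcanThresholds:
    """dbCAN domain-filter thresholds (base rule and strict extras)."""

    min_coverage: float = 0.3
    long_alignment_aa: int = 80
    long_max_evalue: float = 1e-5
    short_max_evalue: float = 1e-3
    strict_max_evalue: float = 1e-18
    strict_min_coverage: float = 0.35


def hmm_coverage(hit: DomainHit) -> float:
    """Fraction of the model's match states spanned by the domain."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.model_len


def filter_dbcan(
    hits: Iterable[DomainHit],
    strict: bool = False,
    thresholds: DbcanThresholds | None = None,
) -> list[AnnotationRecord]:
    """dbCAN-style per-domain filter; every qualifying domain is kept.

    Base rule: model coverage > 0.3, and either alignment length > 80 aa
    with independent E-value < 1e-5, or alignment length <= 80 aa with
    independent E-value < 1e-3.  Strict mode additionally requires
    E < 1e-18 and coverage > 0.35 (the bacteria-oriented recommendation).
    """
    thr = thresholds or DbcanThresholds()
    out = []
    for h in hits:
        cov = hmm_coverage(h)
        ali_len = h.ali_to - h.ali_from + 1
        if cov <= thr.min_coverage:
            continue
        if ali_len > thr.long_alignment_aa:
            if not h.dom_ievalue < thr.long_max_evalue:
                continue
        else:
            if not h.dom_ievalue < thr.short_max_evalue:
                continue
        if strict and not (
            h.dom_ievalue < thr.strict_max_evalue
            and cov > thr.strict_min_coverage
        ):
            continue
        out.append(
            AnnotationRecord(
                gene_id=h.query_id,
                source="dbcan",
                annotation_id=h.model_id,
                score=h.full_seq_score,
                evalue=h.dom_ievalue,
                description=h.description,
            )
        )
    out.sort(key=lambda r: (r.gene_id, r.annotation_id, r.evalue))
    return out


def load_annotation_info(
    path, id_column: int = 0, description_column: int = 1
) -> dict[str, str]:
    """Load an annotation-id -> description map from a TSV.

    Column positions are configurable per source (e.g. Pfam info files put
    the description in a later column).  Duplicate ids keep their first
    occurrence; duplicates are counted and logged, never fatal — these
    files are display metadata only.
    """
    info: dict[str, str] = {}
    duplicates = 0
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max(id_column, description_column):
                continue
            key = fields[id_column]
            if key in info:
                duplicates += 1
                continue
            info[key] = fields[description_column]
    if duplicates:
        logger.warning(
            "%s: %d duplicate annotation id(s); first occurrence kept",
            path, duplicates,
        )
    return info


def attach_descriptions(
    records: Iterable[AnnotationRecord], info: dict[str, str]
) -> tuple[list[AnnotationRecord], int]:
    """Attach descriptions; returns (records, count missing from info)."""
    out = []
    missing = 0
    for r in records:
        desc = info.get(r.annotation_id)
        if desc is None:
            missing += 1
            desc = ""
        out.append(
            AnnotationRecord(
                r.gene_id, r.source, r.annotation_id, r.score, r.evalue, desc
            )
        )
    if missing:
        logger.warning(
            "%d annotation id(s) had no entry in the info file", missing
        )
    return out, missing


def write_annotations(path, records: Iterable[AnnotationRecord]) -> None:
    with open_text(path, "wt") as fh:
        fh.write(
            "#gene_id\tsource\tannotation_id\tscore\tevalue\tdescription\n"
        )
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.source}\t{r.annotation_id}\t"
                f"{r.score:.6g}\t{r.evalue:.6g}\t{r.description}\n"
            )


def read_annotations(path) -> Iterator[AnnotationRecord]:
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, source, ann_id, score, evalue, *rest = line.split("\t")
            yield AnnotationRecord(
                gene_id, source, ann_id, float(score), float(evalue),
                rest[0] if rest else "",
            )
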