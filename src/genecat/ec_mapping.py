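"""Enzyme Commission (EC) number assignment via orthologous groups.

An orthologous group (e.g. an EggNOG model) is built from a set of member
reference proteins, some of which carry curated EC numbers.  The group
receives an EC if a strict majority of its EC-assigned members carry that
EC; because proteins can hold several EC numbers a group can too.  Genes
annotated with the group then inherit its EC set.

Reference proteins with implausibly many EC entries (fusion/identifier
artefacts) are removed up front: anything above ``max_entries`` ECs is
dropped entirely before voting.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

from ._io import open_text
from .hmm_filter import AnnotationRecord

logger = logging.getLogger(__name__)

#: Dotted EC grammar; partial levels ("1.1.-.-" or truncated "1.1.1") allowed.
EC_PATTERN = re.compile(r"^\d+(\.(\d+|-)){0,3}$")

GroupMembership = Mapping[str, frozenset[str]]
ProteinECTable = Mapping[str, frozenset[str]]


def validate_ec(ec: str) -> str:
    if not EC_PATTERN.match(ec):
        raise ValueError(f"malformed EC number: {ec!r}")
    return ec


def drop_ec_outliers(
    table: ProteinECTable, max_entries: int = 10
) -> dict[str, frozenset[str]]:
    """Remove proteins carrying more than ``max_entries`` EC numbers.

    Legitimate multifunctional proteins carry a handful of ECs; entries
    with hundreds are identifier collisions that would dominate any vote.
    """
    if max_entries < 1:
        raise ValueError(f"max_entries must be >= 1, got {max_entries}")
    kept = {p: ecs for p, ecs in table.items() if len(ecs) <= max_entries}
    removed = len(table) - len(kept)
    if removed:
        logger.warning(
            "dropped %d protein(s) with more than %d EC entries",
            removed, max_entries,
        )
    return kept


def assign_ec_to_group(
    group_id: str,
    members: GroupMembership,
    table: ProteinECTable,
    strict_majority: bool = True,
) -> frozenset[str]:
    """EC set of one group by majority vote over its EC-assigned members.

    Let M be the members holding at least one EC.  An EC is assigned iff
    the number of members carrying it exceeds |M|/2 (strictly, by default;
    ``strict_majority=False`` relaxes to >=).  The result may be empty or
    contain several ECs.
    """
    try:
        member_set = members[group_id]
    except KeyError:
        raise KeyError(f"unknown group: {group_id!r}") from None
    voters = [table[p] for p in member_set if table.get(p)]
    if not voters:
        return frozenset()
    counts: dict[str, int] = {}
    for ecs in voters:
        for ec in ecs:
            counts[ec] = counts.get(ec, 0) + 1
    half = len(voters) / 2
    if strict_majority:
        return frozenset(ec for ec, n in counts.items() if n > half)
    return frozenset(ec for ec, n in counts.items() if n >= half)


def assign_ec_to_groups(
    members: GroupMembership,
    table: ProteinECTable,
    strict_majority: bool = True,
) -> dict[str, frozenset[str]]:
    return {
        g: assign_ec_to_group(g, members, table, strict_majority)
        for g in members
    }


def assign_ec_to_genes(
    gene_annotations: Iterable[AnnotationRecord],
    group_ec: Mapping[str, frozenset[str]],
) -> list[AnnotationRecord]:
    """Translate per-gene group annotations into per-gene EC records.

    Each gene annotated with group *g* gains one record per EC assigned to
    *g*, inheriting the group annotation's score and E-value; genes whose
    group has no EC produce nothing.
    """
    out = []
    for rec in gene_annotations:
        for ec in sorted(group_ec.get(rec.annotation_id, ())):
            out.append(
                AnnotationRecord(
                    gene_id=rec.gene_id,
                    source="ec",
                    annotation_id=ec,
                    score=rec.score,
                    evalue=rec.evalue,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV I/O: protein -> comma-separated EC list; group -> comma-separated members


def read_protein_ec_table(path) -> dict[str, frozenset[str]]:
    table: dict[str, frozenset[str]] = {}
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            protein, ecs = line.split("\t")[:2]
            table[protein] = frozenset(
                validate_ec(e.strip()) for e in ecs.split(",") if e.strip()
            )
    return table


def read_group_members(path) -> dict[str, frozenset[str]]:
    groups: dict[str, frozenset[str]] = {}
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            group, members = line.split("\t")[:2]
            member_set = frozenset(
                m.strip() for m in members.split(",") if m.strip()
            )
            if not member_set:
                raise ValueError(f"group {group!r} has no members")
            groups[group] = member_set
    return groups


def write_group_ec(path, group_ec: Mapping[str, frozenset[str]]) -> None:
    with open_text(path, "wt") as fh:
        fh.write("#group_id\tec_numbers\n")
        for g in sorted(group_ec):
            fh.write(f"{g}\t{','.join(sorted(group_ec[g]))}\n")
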