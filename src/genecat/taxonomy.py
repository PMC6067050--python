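"""Taxonomic tree loading and seven-rank lineage projection.

The taxonomy backing a protein search is either an NCBI-style dump
(``nodes.dmp`` / ``names.dmp``, tab-pipe delimited) or a flat TSV mapping a
taxon id to its names at the seven canonical ranks.  Either form is loaded
into a :class:`TaxonomyTree`, and lineages are always projected onto the
canonical rank ladder

    superkingdom > phylum > class > order > family > genus > species

skipping intermediate ranks (``no rank``, ``subfamily``, strains, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._io import open_text

logger = logging.getLogger(__name__)

#: The seven canonical ranks, shallowest first.  Depth d indexes into this
#: list as CANONICAL_RANKS[d - 1].
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_DEPTH: dict[str, int] = {r: i + 1 for i, r in enumerate(CANONICAL_RANKS)}


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (cycle, orphan, bad rank)."""


@dataclass(frozen=True)
class RankedLineage:
    """A taxon path over the canonical ranks, possibly truncated.

    ``taxa`` is a tuple of ``(rank, taxid, name)`` triples, contiguous from
    superkingdom down to some depth in 0-7.  An empty lineage means
    "unassigned".
    """

    taxa: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        for depth, (rank, _taxid, _name) in enumerate(self.taxa, start=1):
            if RANK_DEPTH.get(rank) != depth:
                raise TaxonomyError(
                    f"lineage rank {rank!r} at position {depth} breaks the "
                    f"canonical ladder {CANONICAL_RANKS}"
                )

    @property
    def depth(self) -> int:
        return len(self.taxa)

    def taxon_at(self, depth: int) -> tuple[str, str, str] | None:
        """The (rank, taxid, name) triple at 1-based ``depth``, or None."""
        if 1 <= depth <= len(self.taxa):
            return self.taxa[depth - 1]
        return None

    def prefix(self, depth: int) -> "RankedLineage":
        return RankedLineage(self.taxa[:depth])

    def names(self) -> tuple[str, ...]:
        return tuple(name for _r, _t, name in self.taxa)

    def is_prefix_of(self, other: "RankedLineage") -> bool:
        return self.taxa == other.taxa[: len(self.taxa)]

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return ";".join(self.names()) if self.taxa else "<unassigned>"


@dataclass
class TaxonomyTree:
    """A rooted taxonomy: taxid -> (parent, rank, name).

    Non-canonical ranks are retained in the tree and skipped when lineages
    are projected onto the seven canonical ranks.
    """

    nodes: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    root: str = "1"
    _lineage_cache: dict[str, RankedLineage] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, taxid: object) -> bool:
        return str(taxid) in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        """Check the single-root / no-orphan / acyclic invariants."""
        roots = [t for t, (p, _r, _n) in self.nodes.items() if p == t]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root (parent == self), found {roots!r}"
            )
        self.root = roots[0]
        for taxid, (parent, _rank, _name) in self.nodes.items():
            if parent not in self.nodes:
                raise TaxonomyError(
                    f"orphan node: taxid {taxid} has unknown parent {parent}"
                )
        # Walk every node to the root; a cycle shows up as a revisit before
        # reaching the root.
        ok: set[str] = {self.root}
        for taxid in self.nodes:
            path = []
            cur = taxid
            seen = set()
            while cur not in ok:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur}")
                seen.add(cur)
                path.append(cur)
                cur = self.nodes[cur][0]
            ok.update(path)

    def parent(self, taxid: str) -> str:
        return self.nodes[str(taxid)][0]

    def rank(self, taxid: str) -> str:
        return self.nodes[str(taxid)][1]

    def name(self, taxid: str) -> str:
        return self.nodes[str(taxid)][2]


def lineage_of(tree: TaxonomyTree, taxid: str | int) -> RankedLineage:
    """Project a taxon onto the seven canonical ranks.

    Walks from ``taxid`` to the root collecting ancestors (including the
    taxon itself) whose rank is canonical, then keeps the longest contiguous
    run starting at superkingdom.  A taxid whose own rank is non-canonical
    (e.g. a strain) therefore yields the lineage of its nearest canonical
    ancestor; the root yields the empty lineage.

    Raises
    ------
    KeyError
        If ``taxid`` is not present in the tree.
    """
    key = str(taxid)
    if key in tree._lineage_cache:
        return tree._lineage_cache[key]
    if key not in tree.nodes:
        raise KeyError(f"taxid {key} not found in taxonomy tree")
    by_depth: dict[int, tuple[str, str, str]] = {}
    cur = key
    while True:
        parent, rank, name = tree.nodes[cur]
        d = RANK_DEPTH.get(rank)
        if d is not None and d not in by_depth:
            by_depth[d] = (rank, cur, name)
        if parent == cur:
            break
        cur = parent
    taxa = []
    for d in range(1, 8):
        if d not in by_depth:
            break
        taxa.append(by_depth[d])
    lineage = RankedLineage(tuple(taxa))
    tree._lineage_cache[key] = lineage
    return lineage


# ---------------------------------------------------------------------------
# Loading


def _parse_dmp_line(line: str) -> list[str]:
    # NCBI dump dialect: fields separated by "\t|\t", record ends "\t|".
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_ncbi_dump(nodes_path, names_path) -> TaxonomyTree:
    """Load a taxonomy from NCBI ``nodes.dmp`` and ``names.dmp`` files."""
    tree = TaxonomyTree()
    with open_text(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyError(
                    f"{nodes_path}: expected >=3 dump fields, got {fields!r}"
                )
            taxid, parent, rank = fields[0], fields[1], fields[2]
            tree.nodes[taxid] = (parent, rank, "")
    names: dict[str, str] = {}
    with open_text(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 4:
                raise TaxonomyError(
                    f"{names_path}: expected >=4 dump fields, got {fields!r}"
                )
            taxid, name, _unique, name_class = fields[:4]
            if name_class == "scientific name" or taxid not in names:
                names[taxid] = name
    tree.nodes = {
        t: (p, r, names.get(t, "")) for t, (p, r, _n) in tree.nodes.items()
    }
    tree.validate()
    return tree


_FLAT_COLUMNS = ("taxid",) + CANONICAL_RANKS


def load_flat_lineages(path) -> TaxonomyTree:
    """Load a taxonomy from a flat lineage TSV.

    Columns: taxid, superkingdom, phylum, class, order, family, genus,
    species — names, with empty string for absent ranks.  Internal nodes are
    synthesized (keyed by their name path) so that distinct clades sharing a
    name do not collide; the row's taxid is attached to the deepest named
    rank, making ``lineage_of`` round-trip every input row.
    """
    tree = TaxonomyTree()
    tree.nodes["1"] = ("1", "no rank", "root")
    path_to_id: dict[tuple[str, ...], str] = {}
    n_synth = 0
    with open_text(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if header is None and line.lstrip("#").split("\t")[0] == "taxid":
                    header = line
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "taxid":
                header = line
                continue
            if len(fields) != 8:
                raise TaxonomyError(
                    f"{path}:{lineno}: expected 8 tab-separated columns "
                    f"({', '.join(_FLAT_COLUMNS)}), got {len(fields)}"
                )
            taxid = fields[0]
            names = fields[1:]
            # trailing empty cells mark the truncation depth
            depth = 0
            for i, nm in enumerate(names, start=1):
                if nm == "":
                    break
                depth = i
            if any(nm != "" for nm in names[depth:]):
                raise TaxonomyError(
                    f"{path}:{lineno}: gap in lineage for taxid {taxid} "
                    "(a named rank follows an empty one)"
                )
            parent_id = "1"
            for d in range(1, depth + 1):
                key = tuple(names[:d])
                node_id = path_to_id.get(key)
                if node_id is None:
                    if d == depth:
                        node_id = taxid
                    else:
                        n_synth += 1
                        node_id = f"synth:{n_synth}"
                    path_to_id[key] = node_id
                    tree.nodes[node_id] = (
                        parent_id,
                        CANONICAL_RANKS[d - 1],
                        names[d - 1],
                    )
                parent_id = node_id
            if depth == 0:
                tree.nodes.setdefault(taxid, ("1", "no rank", ""))
            elif taxid not in tree.nodes:
                # row taxid names an already-synthesized interior node: alias
                # it as a child-of-equal-rank is wrong; instead point the
                # taxid at the existing node by re-keying.
                existing = path_to_id[tuple(names[:depth])]
                tree.nodes[taxid] = tree.nodes[existing]
    tree.validate()
    return tree


def load_taxonomy(
    nodes_path=None, names_path=None, lineage_tsv_path=None
) -> TaxonomyTree:
    """Load a taxonomy from either source dialect.

    Supply ``nodes_path`` + ``names_path`` for the NCBI dump dialect, or
    ``lineage_tsv_path`` for the flat seven-rank TSV.
    """
    if lineage_tsv_path is not None:
        return load_flat_lineages(lineage_tsv_path)
    if nodes_path is None or names_path is None:
        raise ValueError(
            "supply nodes_path and names_path, or lineage_tsv_path"
        )
    return load_ncbi_dump(nodes_path, names_path)


def lineages_for(
    tree: TaxonomyTree, taxids: Iterable[str | int], on_missing: str = "warn"
) -> Mapping[str, RankedLineage]:
    """Lineages for many taxids; unknown ids are dropped with a warning.

    ``on_missing``: "warn" (drop + log, the default — database/taxonomy
    version skew is routine), "ignore", or "raise".
    """
    out: dict[str, RankedLineage] = {}
    missing = 0
    for taxid in taxids:
        key = str(taxid)
        if key in out:
            continue
        try:
            out[key] = lineage_of(tree, key)
        except KeyError:
            if on_missing == "raise":
                raise
            missing += 1
    if missing and on_missing == "warn":
        logger.warning(
            "%d subject taxid(s) absent from the taxonomy tree; their hits "
            "will be dropped",
            missing,
        )
    return out
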