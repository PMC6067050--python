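import numpy as np
import pytest

from genecat.fixtures import FixtureSpec, make_fixture, write_fixture
from genecat.taxonomy import CANONICAL_RANKS, TaxonomyTree


@pytest.fixture(scope="session")
def fixture_bundle():
    """One default synthetic dataset shared across the suite."""
    return make_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_paths(fixture_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(fixture_bundle, out)


@pytest.fixture
def toy_tree():
    """Minimal hand-built taxonomy: one full bacterial lineage + archaea."""
    tree = TaxonomyTree()
    rows = [
        ("1", "1", "no rank", "root"),
        ("2", "1", "superkingdom", "Bacteria"),
        ("2157", "1", "superkingdom", "Archaea"),
        ("1224", "2", "phylum", "Proteobacteria"),
        ("1236", "1224", "class", "Gammaproteobacteria"),
        ("91347", "1236", "order", "Enterobacterales"),
        ("543", "91347", "family", "Enterobacteriaceae"),
        ("561", "543", "genus", "Escherichia"),
        ("562", "561", "species", "Escherichia coli"),
        ("83333", "562", "strain", "E. coli K-12"),
        ("1239", "2", "phylum", "Bacillota"),
    ]
    for taxid, parent, rank, name in rows:
        tree.nodes[taxid] = (parent, rank, name)
    tree.validate()
    return tree


def random_tree(rng: np.random.Generator, max_nodes: int = 30):
    """A random small taxonomy plus independently tracked lineage paths.

    Returns (tree, paths) where paths maps every taxid to its tuple of
    canonical-rank ancestor taxids (shallowest first), built during
    generation — not via the production lineage code.
    """
    tree = TaxonomyTree()
    tree.nodes["1"] = ("1", "no rank", "root")
    paths: dict[str, tuple[str, ...]] = {"1": ()}
    next_id = 2
    frontier = [("1", ())]
    for rank in CANONICAL_RANKS:
        new_frontier = []
        for parent, path in frontier:
            for _ in range(int(rng.integers(1, 3))):
                if len(tree.nodes) >= max_nodes:
                    break
                taxid = str(next_id)
                next_id += 1
                tree.nodes[taxid] = (parent, rank, f"{rank[:2]}{taxid}")
                paths[taxid] = path + (taxid,)
                new_frontier.append((taxid, paths[taxid]))
        if not new_frontier:
            break
        frontier = new_frontier
    tree.validate()
    return tree, paths
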