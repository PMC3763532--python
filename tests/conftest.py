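"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mirclust import MicroRNALocus, SpeciesPhylogeny, load_table1_fixture
from mirclust.clustering import pairwise_gap

FIXTURE_NEWICK = (
    "((((dme:1.0,(dsi:0.5,dps:0.5)drosophila_relatives:0.5)Drosophila:1.0,"
    "(aga:1.5,tca:1.5)other_insects:0.5)Insects:1.0,"
    "(cel:2.5,lgi:2.5)lophotrochozoans:0.5)Protostomes:1.0,hsa:4.0)Metazoans;"
)

SEVEN_LEAF_NEWICK = (
    "((((s1:1,(s2:0.5,s3:0.5)n1:0.5)n2:1,(s4:1.5,s5:1.5)n3:0.5)n4:1,"
    "s6:3)n5:1,s7:4)root;"
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def fixture_tree():
    return SpeciesPhylogeny.from_newick(
        FIXTURE_NEWICK, leaf_lineages={"dme": "Melanogaster"}
    )


@pytest.fixture(scope="session")
def seven_leaf_tree():
    return SpeciesPhylogeny.from_newick(SEVEN_LEAF_NEWICK)


# -- oracles ---------------------------------------------------------------


def brute_force_clusters(loci, max_gap):
    """Transitive closure over all pairs at gap < max_gap: the independent
    oracle for single-linkage cluster calling."""
    loci = list(loci)
    n = len(loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = pairwise_gap(loci[i], loci[j])
            if gap is not None and gap < max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(loci[i])
    return {
        frozenset(l.mirna_id for l in group)
        for group in groups.values()
        if len(group) >= 2
    }


def brute_force_mrca(tree: SpeciesPhylogeny, names):
    """MRCA by explicit root-path intersection."""
    paths = [tree.path_to_root(n) for n in names]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    return max(common, key=tree.depth)


def dollo_minimal_gain(tree: SpeciesPhylogeny, present: set[str]):
    """Exhaustive search over all single-gain placements.

    Returns (best_nodes, min_losses): the gain nodes minimising the number
    of whole-subtree losses needed to explain the presence pattern.
    """

    def losses_under(node):
        leaves = tree.leaves_under(node)
        if not any(l in present for l in leaves):
            return 1  # the whole subtree is one loss
        if tree.is_leaf(node):
            return 0
        return sum(losses_under(c) for c in tree.children_of(node))

    candidates = [
        node
        for node in tree.nodes
        if all(l in set(tree.leaves_under(node)) for l in present)
    ]
    scored = {node: losses_under(node) for node in candidates}
    best = min(scored.values())
    return {n for n, s in scored.items() if s == best}, best


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesPhylogeny:
    """Random rooted binary tree with named internal nodes."""
    subtrees = [f"sp{i}" for i in range(n_leaves)]
    counter = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        counter += 1
        subtrees.append(f"({a}:1,{b}:1)in{counter}")
    return SpeciesPhylogeny.from_newick(subtrees[0] + ";")


def random_loci(
    rng: np.random.Generator,
    n: int,
    species: str = "dme",
    n_chroms: int = 2,
    length: int = 200_000,
) -> list[MicroRNALocus]:
    """Random loci dense enough that chains and near-threshold gaps occur."""
    loci = []
    for i in range(n):
        start = int(rng.integers(1, length))
        loci.append(
            MicroRNALocus(
                mirna_id=f"m{i}",
                species_id=species,
                chrom=f"chr{rng.integers(1, n_chroms + 1)}",
                start=start,
                end=start + int(rng.integers(60, 120)),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return loci
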