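"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mtclades import (
    leaf_distance_matrix,
    make_bundle,
    read_newick,
    schematic_hierarchy,
)


@pytest.fixture(scope="session")
def hierarchy():
    return schematic_hierarchy()


@pytest.fixture
def toy_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_leaf_tree():
    return read_newick("(((A:1,B:1):1,(C:1,D:1):1):2,(E:1,F:3):2);")


@pytest.fixture(scope="session")
def bundle():
    """Default-sized synthetic study shared across tests (read-only)."""
    return make_bundle(n_leaves=60, n_pops=4, n_sites=1000, seed=11)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_mrca(hierarchy, names):
    """MRCA by intersecting full ancestor sets and taking the deepest node."""
    ancestor_sets = []
    for name in names:
        ancestor_sets.append(set(hierarchy.path_to_root(name)))
    common = set.intersection(*ancestor_sets)
    # deepest = the common node with the longest root path
    return max(common, key=lambda n: len(hierarchy.path_to_root(n)))


def clade_leafsets(tree):
    """Every clade of the tree as (node, frozenset of leaf labels), postorder."""
    out = []
    below = {}
    for node in tree.postorder:
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        out.append((node, below[id(node)]))
    return out


def exhaustive_max_clade(tree, threshold, atol=1e-12):
    """Maximal valid clades by full enumeration (the clustering oracle).

    A clade is valid iff its leaf-set diameter (from the distance matrix) is
    within the threshold; a valid clade is kept iff it is the root or its
    parent clade is invalid.  Returns the set of leaf frozensets.
    """
    d = leaf_distance_matrix(tree)
    clades = clade_leafsets(tree)
    valid = {}
    for node, leaves in clades:
        sub = d.loc[sorted(leaves), sorted(leaves)].values
        valid[id(node)] = sub.max() <= threshold + atol
    kept = set()
    for node, leaves in clades:
        if valid[id(node)] and (node.parent is None or not valid[id(node.parent)]):
            kept.add(leaves)
    return kept


def partition_leafsets(partition):
    return {frozenset(m) for m in partition.members().values()}


def all_name_subsets(names, max_size):
    for size in range(1, max_size + 1):
        yield from itertools.combinations(names, size)


def path_distance_by_climbing(tree):
    """Leaf distances via explicit ancestor-chain walks (second formula)."""
    parents = {}
    lengths = {}
    for node in tree.postorder:
        for child in node.children:
            parents[id(child)] = node
            lengths[id(child)] = child.branch_length
    leaves = tree.leaves
    n = len(leaves)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc_i = {}
            node, dist = leaves[i], 0.0
            while True:
                anc_i[id(node)] = dist
                if id(node) not in parents:
                    break
                dist += lengths[id(node)]
                node = parents[id(node)]
            node, dist = leaves[j], 0.0
            while id(node) not in anc_i:
                dist += lengths[id(node)]
                node = parents[id(node)]
            out[i, j] = out[j, i] = dist + anc_i[id(node)]
    return out
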