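"""Seeded generators for trees, haplogroup labels, populations, and MSAs.

These emulate the shape of a typical human-mtDNA population study — a rooted
weighted phylogeny of a few hundred samples, nomenclature-consistent leaf
haplogroup labels nested in a hierarchy, population assignments with
population-specific group-frequency profiles, and an alignment evolved along
the tree — so that every analysis in the package can be exercised end to end
without external downloads.  All randomness flows from a single seed;
identical seeds give byte-identical bundles.

Ground truth is kept for everything injected (irregular names, true group
frequencies, distinct label-tuple classes), so generator bookkeeping can
serve as the oracle in tests.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .errors import MtCladesError
from .nomenclature import HaplogroupHierarchy, strip_modifier
from .sequence_distance import Msa
from .tree_model import Phylogeny, TreeNode, _node_stats

__all__ = [
    "simulate_tree",
    "label_haplogroups",
    "assign_populations",
    "simulate_msa",
    "make_bundle",
    "FixtureBundle",
    "LabelBookkeeping",
    "PopulationAssignment",
    "DEFAULT_IRREGULARITY_RATES",
]

#: Default irregular-name injection rates, echoing the rates reported for
#: reference human mtDNA phylogenies: ~1.8% merged-capital names, ~2.8%
#: double-lowercase names, ~19% mutation-annotated names; apostrophe merges
#: are common but unquantified there, so 5% is used as a realistic default.
DEFAULT_IRREGULARITY_RATES = {
    "consecutive_upper": 0.018,
    "consecutive_lower": 0.028,
    "plus_at": 0.19,
    "apostrophe": 0.05,
}


def _derived_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def simulate_tree(
    n_leaves: int,
    model: str = "yule",
    target_diameter: float = 0.01,
    seed: int = 0,
) -> Phylogeny:
    """Simulate a rooted tree and rescale it to an exact leaf-pair diameter.

    Topology and waiting times come from dendropy's tree simulators (a pure
    birth process for ``"yule"``, the Kingman n-coalescent for
    ``"kingman"``); branch lengths are then rescaled uniformly so that the
    largest leaf-pair path distance equals ``target_diameter``.  Leaves are
    relabeled ``S0001..`` in left-to-right order, making output depend only
    on the seed.
    """
    import dendropy
    from dendropy.simulate import treesim

    if n_leaves < 2:
        raise MtCladesError("need at least 2 leaves")
    if target_diameter <= 0:
        raise MtCladesError("target_diameter must be positive")
    rng = random.Random(seed)
    if model == "yule" and n_leaves == 2:
        # a pure-birth process stops immediately at two tips; the only
        # 2-leaf shape is a cherry, scaled below to the target diameter
        root = TreeNode(children=[TreeNode(branch_length=0.5), TreeNode(branch_length=0.5)])
        counter = [0]
        for child in root.children:
            counter[0] += 1
            child.label = f"S{counter[0]:04d}"
        tree = Phylogeny(root)
        tree.scale_branch_lengths(target_diameter)
        return Phylogeny(tree.root)
    if model == "yule":
        dtree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves, rng=rng
        )
    elif model == "kingman":
        tns = dendropy.TaxonNamespace([f"T{i}" for i in range(n_leaves)])
        dtree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0, rng=rng)
    else:
        raise MtCladesError(f"unknown tree model {model!r}")

    def convert(dnode) -> TreeNode:
        node = TreeNode(branch_length=dnode.edge.length or 0.0)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.branch_length = None
    # deterministic labels in left-to-right leaf order
    counter = [0]

    def relabel(node: TreeNode) -> None:
        if not node.children:
            counter[0] += 1
            node.label = f"S{counter[0]:04d}"
        for child in node.children:
            relabel(child)

    relabel(root)
    tree = Phylogeny(root)
    _, diam = _node_stats(tree)
    if diam <= 0:
        raise MtCladesError("simulated tree has zero diameter; cannot rescale")
    tree.scale_branch_lengths(target_diameter / diam)
    return Phylogeny(tree.root)


@dataclass
class LabelBookkeeping:
    """Ground truth for injected naming irregularities.

    ``leaf_flag_counts`` gives, per irregularity flag, the number of leaves
    whose emitted haplogroup label carries it — computed from the injection
    record alone, independently of the name parser.
    """

    injected_names: Dict[str, Set[str]] = field(default_factory=dict)
    plus_at_leaves: Set[str] = field(default_factory=set)
    leaf_flag_counts: Dict[str, int] = field(default_factory=dict)


_CAPITALS = [c for c in string.ascii_uppercase if c != "L"]
_ROOT_POOL = ["L0", "L1", "L2", "L3", "L4", "L5"] + _CAPITALS


def label_haplogroups(
    tree: Phylogeny,
    hierarchy_depth: int = 4,
    irregularity_rates: Optional[Mapping[str, float]] = None,
    seed: int = 0,
):
    """Assign clade-consistent haplogroup names to leaves, with a hierarchy.

    Internal nodes down to ``hierarchy_depth`` are given names that follow
    the strict cladistic grammar, extending the parent's name with
    alternating digit and lowercase-letter tokens (root children draw from a
    pool of principal-cluster style names such as ``L0``, ``L1``, ``A`` …).
    Each leaf is labeled with the name of its nearest named ancestor-or-self,
    so leaves within a clade carry hierarchically related names.

    Irregularities are injected at the given per-event rates, with full
    bookkeeping:

    * ``consecutive_upper`` — a root child named with two merged capitals;
    * ``consecutive_lower`` — a letter token of two lowercase characters;
    * ``apostrophe`` — an internal node renamed to the apostrophe merge of
      its children's tokens (children keep the unmerged base names);
    * ``plus_at`` — a leaf label suffixed with ``+@<position>``.

    Returns ``(leaf_map, hierarchy, bookkeeping)``.
    """
    rates = dict(DEFAULT_IRREGULARITY_RATES if irregularity_rates is None else irregularity_rates)
    for flag, rate in rates.items():
        if not 0 <= rate <= 1:
            raise MtCladesError(f"rate for {flag!r} must be in [0, 1], got {rate}")
    if hierarchy_depth < 1:
        raise MtCladesError("hierarchy_depth must be >= 1 (root children are always named)")
    rng = random.Random(seed)
    root = tree.root
    # published (hierarchy) name per node vs. the base that children extend;
    # they differ only at apostrophe-merged nodes ("M9a'b" publishes the merge
    # while its children extend the unmerged "M9a", "M9b", ... base "M9").
    names: Dict[int, str] = {id(root): "mt-MRCA"}
    ext_base: Dict[int, str] = {id(root): "mt-MRCA"}
    # flags a descendant name inherits because the irregular text is a prefix
    inherited: Dict[int, Set[str]] = {id(root): set()}
    own_flags: Dict[int, Set[str]] = {id(root): set()}
    edges: List[tuple] = []
    used: Set[str] = {"mt-MRCA"}
    root_pool = list(_ROOT_POOL)

    def name_children(node: TreeNode, depth: int) -> None:
        if depth >= hierarchy_depth:
            return
        base = ext_base[id(node)]
        parent_name = names[id(node)]
        parent_inherit = inherited[id(node)]
        is_root = node is root
        for i, child in enumerate(node.children):
            flags = set(parent_inherit)
            if is_root:
                if rng.random() < rates.get("consecutive_upper", 0.0):
                    while True:
                        cand = rng.choice(_CAPITALS) + rng.choice(_CAPITALS)
                        if cand not in used:
                            break
                    name = cand
                    flags.add("consecutive_upper")
                else:
                    name = next(n for n in root_pool if n not in used)
            else:
                if base[-1].isdigit():
                    token = string.ascii_lowercase[i % 26]
                    if rng.random() < rates.get("consecutive_lower", 0.0):
                        token += rng.choice(string.ascii_lowercase)
                        flags.add("consecutive_lower")
                else:
                    token = str(i + 1)
                name = base + token
            own = set(flags)
            label = name
            # apostrophe merges are injected at the deepest named tier, where
            # the merged name is what the leaves below actually inherit
            if (
                not child.is_leaf
                and len(child.children) >= 2
                and depth + 1 == hierarchy_depth
                and not is_root
                and rng.random() < rates.get("apostrophe", 0.0)
            ):
                # publish the apostrophe merge of the children's (expected) tokens
                sub_tokens = (
                    [string.ascii_lowercase[j % 26] for j in range(len(child.children))]
                    if name[-1].isdigit()
                    else [str(j + 1) for j in range(len(child.children))]
                )
                label = name + sub_tokens[0] + "'" + "'".join(sub_tokens[1:])
                own = own | {"apostrophe"}
            while label in used:  # collision safeguard; extend deterministically
                label = label + "x"
            used.add(label)
            names[id(child)] = label
            ext_base[id(child)] = name
            inherited[id(child)] = flags  # apostrophe itself is not inherited
            own_flags[id(child)] = own
            edges.append((label, parent_name))
            name_children(child, depth + 1)

    name_children(root, 0)

    # nearest named ancestor-or-self per leaf
    leaf_map: Dict[str, str] = {}
    leaf_core_flags: Dict[str, Set[str]] = {}

    def walk(node: TreeNode, current: str, cur_flags: Set[str]) -> None:
        if id(node) in names:
            current = names[id(node)]
            cur_flags = own_flags[id(node)]
        if node.is_leaf:
            leaf_map[node.label] = current
            leaf_core_flags[node.label] = set(cur_flags)
        for child in node.children:
            walk(child, current, cur_flags)

    walk(root, "mt-MRCA", set())

    book = LabelBookkeeping()
    book.injected_names = {
        "consecutive_upper": {n for n in used if sum(c.isupper() for c in n) > 1 and n != "mt-MRCA"},
        "apostrophe": {n for n in used if "'" in n},
    }
    for leaf in list(leaf_map):
        if rng.random() < rates.get("plus_at", 0.0):
            leaf_map[leaf] = leaf_map[leaf] + f"+@{rng.randint(100, 16500)}"
            book.plus_at_leaves.add(leaf)
    book.leaf_flag_counts = {
        flag: sum(flag in fl for fl in leaf_core_flags.values())
        for flag in ("consecutive_upper", "consecutive_lower", "apostrophe")
    }
    book.leaf_flag_counts["plus_at"] = len(book.plus_at_leaves)

    hierarchy = HaplogroupHierarchy.from_edges(edges) if edges else HaplogroupHierarchy(
        {"mt-MRCA": None}
    )
    return leaf_map, hierarchy, book


@dataclass
class PopulationAssignment:
    """Leaf→population labels plus the generating group-frequency matrix."""

    population_of: Dict[str, str]
    true_frequencies: pd.DataFrame  # populations × groups, rows sum to 1
    sampled_group_of: Optional[Dict[str, str]] = None


def assign_populations(
    leaves: Sequence[str],
    n_pops: int = 7,
    concentration: float = 1.0,
    seed: int = 0,
    leaf_groups: Optional[Mapping[str, str]] = None,
    n_groups: int = 5,
) -> PopulationAssignment:
    """Assign populations with Dirichlet-distributed group-frequency profiles.

    Per population, a frequency vector over groups is drawn from a symmetric
    Dirichlet with the given concentration.  With ``leaf_groups`` supplied
    (e.g. clade memberships), each leaf's population is drawn in proportion
    to the populations' frequencies for its group, giving populations
    distinct empirical profiles.  Without it, leaves are split into
    equal-sized populations and a categorical group label is sampled for
    each leaf from its population's frequency vector (recorded in
    ``sampled_group_of``), so the true vector is the exact sampling law.
    """
    if n_pops < 1:
        raise MtCladesError("n_pops must be >= 1")
    rng = np.random.default_rng(seed)
    pops = [f"POP{i + 1}" for i in range(n_pops)]
    leaves = list(leaves)
    if leaf_groups is not None:
        groups = sorted(set(leaf_groups.values()))
        freqs = rng.dirichlet([concentration] * len(groups), size=n_pops)
        g_index = {g: j for j, g in enumerate(groups)}
        pop_of = {}
        for leaf in leaves:
            w = freqs[:, g_index[leaf_groups[leaf]]]
            pop_of[leaf] = pops[rng.choice(n_pops, p=w / w.sum())]
        sampled = None
    else:
        groups = [f"G{j + 1}" for j in range(n_groups)]
        freqs = rng.dirichlet([concentration] * n_groups, size=n_pops)
        order = rng.permutation(len(leaves))
        pop_of = {leaves[k]: pops[i * n_pops // len(leaves)] for i, k in enumerate(order)}
        sampled = {
            leaf: groups[rng.choice(n_groups, p=freqs[pops.index(pop_of[leaf])])]
            for leaf in leaves
        }
    true = pd.DataFrame(freqs, index=pops, columns=groups)
    true.index.name = "population"
    return PopulationAssignment(
        population_of=pop_of, true_frequencies=true, sampled_group_of=sampled
    )


def simulate_msa(tree: Phylogeny, n_sites: int = 2000, rate: float = 1.0, seed: int = 0) -> Msa:
    """Evolve an alignment along the tree under the Jukes–Cantor model.

    The root sequence is uniform over {A, C, G, T}; along a branch of length
    *t* (in substitutions/site, scaled by ``rate``) each site differs from
    its parent with the exact JC probability ``(3/4)(1 − e^(−4·rate·t/3))``,
    the substitute drawn uniformly from the three other bases.  No indels
    are simulated: alignment is treated as an upstream given.
    """
    if n_sites < 1:
        raise MtCladesError("n_sites must be >= 1")
    if rate < 0:
        raise MtCladesError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs: Dict[int, np.ndarray] = {id(tree.root): rng.integers(0, 4, size=n_sites)}
    for node in reversed(tree.postorder):  # preorder
        if node is tree.root:
            continue
        parent_seq = seqs[id(node.parent)]
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * rate * node.branch_length / 3.0))
        hit = rng.random(n_sites) < p_diff
        child_seq = parent_seq.copy()
        child_seq[hit] = (parent_seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        seqs[id(node)] = child_seq
    records = [
        (leaf.label, bases[seqs[id(leaf)]].tobytes().decode()) for leaf in tree.leaves
    ]
    return Msa.from_strings(records)


@dataclass
class FixtureBundle:
    """An internally consistent simulated study: tree, names, populations, MSA."""

    tree: Phylogeny
    hierarchy: HaplogroupHierarchy
    leaf_haplogroups: Dict[str, str]
    populations: PopulationAssignment
    msa: Msa
    bookkeeping: LabelBookkeeping
    params: dict

    def grouping_table(self) -> pd.DataFrame:
        """Per-sample table with population and haplogroup columns."""
        rows = [
            {
                "sample_id": leaf,
                "population": self.populations.population_of[leaf],
                "haplogroup": self.leaf_haplogroups[leaf],
            }
            for leaf in self.tree.leaf_labels
        ]
        return pd.DataFrame(rows)


def make_bundle(
    n_leaves: int = 100,
    n_pops: int = 7,
    target_diameter: float = 0.01,
    n_sites: int = 2000,
    hierarchy_depth: int = 4,
    irregularity_rates: Optional[Mapping[str, float]] = None,
    concentration: float = 1.0,
    model: str = "yule",
    seed: int = 0,
) -> FixtureBundle:
    """Generate a full simulated study from one seed.

    Defaults echo a typical mtDNA population survey: 7 populations, ~100
    samples, a tree diameter of 0.01 substitutions/site (so the standard
    0.001–0.008 clustering ladder is meaningful), and a 2 kb alignment.
    """
    s_tree, s_label, s_pop, s_msa = _derived_seeds(seed, 4)
    tree = simulate_tree(n_leaves, model=model, target_diameter=target_diameter, seed=s_tree)
    leaf_map, hierarchy, book = label_haplogroups(
        tree, hierarchy_depth=hierarchy_depth, irregularity_rates=irregularity_rates, seed=s_label
    )
    clade_of = {
        leaf: strip_modifier(name)[0:2] for leaf, name in leaf_map.items()
    }  # coarse clade label for population profiles
    pops = assign_populations(
        tree.leaf_labels, n_pops=n_pops, concentration=concentration,
        seed=s_pop, leaf_groups=clade_of,
    )
    msa = simulate_msa(tree, n_sites=n_sites, rate=1.0, seed=s_msa)
    params = {
        "n_leaves": n_leaves, "n_pops": n_pops, "target_diameter": target_diameter,
        "n_sites": n_sites, "hierarchy_depth": hierarchy_depth,
        "irregularity_rates": dict(
            DEFAULT_IRREGULARITY_RATES if irregularity_rates is None else irregularity_rates
        ),
        "concentration": concentration, "model": model, "seed": seed,
    }
    return FixtureBundle(
        tree=tree, hierarchy=hierarchy, leaf_haplogroups=leaf_map,
        populations=pops, msa=msa, bookkeeping=book, params=params,
    )
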