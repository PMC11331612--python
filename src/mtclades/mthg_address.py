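"""mtHg-addresses: hierarchical haplotype naming over a threshold ladder.

An mtHg-address names a haplotype by its cluster membership at each level of
a strictly decreasing ladder of max-clade thresholds, rendered as dotted
numbers (e.g. ``2.2.4.4.4.5.5.5.5``).  Because partitions at smaller
thresholds refine partitions at larger ones, addresses are prefix-consistent:
two samples that agree at any ladder position agree at all coarser positions.
With a ladder ending at threshold 0, two samples share a full address exactly
when their tree distance is 0 — identical haplotypes, and only they, get
identical names, so polyphyletic pseudo-groups cannot arise.

Selected ladder levels can additionally be published as named grouping tiers
(macro-, meso-, micro-haplogroups), each cluster labeled by the most recent
common ancestor haplogroup of its members in a haplogroup hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .errors import InvalidThresholdError, LevelConfigError
from .nomenclature import HaplogroupHierarchy
from .tree_model import ClusterPartition, Phylogeny, threshold_sweep

__all__ = [
    "DEFAULT_LADDER",
    "DEFAULT_LEVELS",
    "MtHgAddress",
    "NamedLevel",
    "assign_addresses",
    "finest_shared_threshold",
    "name_level",
    "designate_levels",
]

#: Nine-step illustrative ladder from 0.008 down to 0 (substitutions/site).
DEFAULT_LADDER = [0.008, 0.007, 0.006, 0.005, 0.004, 0.003, 0.002, 0.001, 0.0]

#: Illustrative named tiers; real standardization would pick thresholds from
#: the full reference phylogeny, so these are configurable defaults only.
DEFAULT_LEVELS = {"macro": 0.006, "meso": 0.005, "micro": 0.004}


def _validate_ladder(ladder: Sequence[float]) -> List[float]:
    ladder = list(ladder)
    if not ladder:
        raise InvalidThresholdError("ladder must be non-empty")
    if any(t < 0 for t in ladder):
        raise InvalidThresholdError("ladder thresholds must be non-negative")
    if any(b >= a for a, b in zip(ladder, ladder[1:])):
        raise InvalidThresholdError(f"ladder must be strictly decreasing, got {ladder}")
    return ladder


@dataclass(frozen=True)
class MtHgAddress:
    """One sample's ordered cluster memberships across a threshold ladder."""

    sample_id: str
    components: tuple

    def render(self) -> str:
        return ".".join(str(c) for c in self.components)

    def __str__(self) -> str:
        return self.render()


def assign_addresses(
    tree: Phylogeny, ladder: Sequence[float] = DEFAULT_LADDER
) -> Dict[str, MtHgAddress]:
    """Assign an mtHg-address to every leaf of ``tree``.

    Component *i* of each address is the leaf's cluster id in the max-clade
    partition at ladder position *i*.
    """
    ladder = _validate_ladder(ladder)
    partitions = threshold_sweep(tree, ladder)
    return {
        leaf: MtHgAddress(
            sample_id=leaf, components=tuple(p.assignment[leaf] for p in partitions)
        )
        for leaf in tree.leaf_labels
    }


def finest_shared_threshold(
    a: MtHgAddress, b: MtHgAddress, ladder: Sequence[float]
) -> Optional[float]:
    """Smallest ladder threshold at which two addresses still share a group.

    Addresses ``2.2.4.4.4.5.5.5.5`` and ``2.2.4.4.6.6.6.6.6`` on the ladder
    0.008…0 share groups down to 0.005 and diverge from 0.004 on, so the
    result is 0.005.  Returns ``None`` when the addresses already differ at
    the coarsest position.
    """
    ladder = _validate_ladder(ladder)
    if len(a.components) != len(b.components) or len(a.components) != len(ladder):
        raise InvalidThresholdError(
            "addresses and ladder must have matching lengths "
            f"({len(a.components)}, {len(b.components)}, {len(ladder)})"
        )
    shared = None
    for threshold, ca, cb in zip(ladder, a.components, b.components):
        if ca != cb:
            break
        shared = threshold
    return shared


@dataclass(frozen=True)
class NamedLevel:
    """One published grouping tier: a threshold plus cluster→haplogroup names."""

    level: str
    threshold: float
    names: Mapping[int, str]


def name_level(
    partition: ClusterPartition,
    leaf_haplogroups: Mapping[str, str],
    hierarchy: HaplogroupHierarchy,
    level: str = "level",
) -> NamedLevel:
    """Name every cluster of a partition by its members' MRCA haplogroup.

    A cluster whose members all carry one identical haplogroup is named by
    that haplogroup directly, without a hierarchy lookup; mixed clusters are
    named by the MRCA of their members' haplogroups.
    """
    names: Dict[int, str] = {}
    for cid, leaves in partition.members().items():
        hgs = [leaf_haplogroups[leaf] for leaf in leaves]
        if len(set(hgs)) == 1:
            names[cid] = hgs[0]
        else:
            names[cid] = hierarchy.mrca(hgs)
    return NamedLevel(level=level, threshold=partition.threshold, names=names)


def designate_levels(
    tree: Phylogeny,
    leaf_haplogroups: Mapping[str, str],
    hierarchy: HaplogroupHierarchy,
    ladder: Sequence[float] = DEFAULT_LADDER,
    level_config: Mapping[str, float] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Emit the per-sample table of named tiers plus the rendered address.

    Columns: ``sample_id``, ``haplogroup``, one ``<level>_hg`` column per
    configured tier (coarsest first), and ``mthg_address``.

    Raises
    ------
    LevelConfigError
        If a configured level threshold is not a ladder value, or the tiers
        are not ordered coarsest-to-finest as given.
    """
    ladder = _validate_ladder(ladder)
    level_items = list(level_config.items())
    for level, thr in level_items:
        if not any(abs(thr - t) <= 1e-15 for t in ladder):
            raise LevelConfigError(f"level {level!r} threshold {thr} is not on the ladder")
    thrs = [t for _, t in level_items]
    if any(b > a for a, b in zip(thrs, thrs[1:])):
        raise LevelConfigError(
            f"level thresholds must be non-increasing coarsest-first, got {level_config}"
        )

    partitions = threshold_sweep(tree, ladder)
    by_threshold = {p.threshold: p for p in partitions}
    addresses = {
        leaf: MtHgAddress(
            sample_id=leaf, components=tuple(p.assignment[leaf] for p in partitions)
        )
        for leaf in tree.leaf_labels
    }
    named = {
        level: name_level(by_threshold[thr], leaf_haplogroups, hierarchy, level=level)
        for level, thr in level_items
    }
    rows = []
    for leaf in tree.leaf_labels:
        row = {"sample_id": leaf, "haplogroup": leaf_haplogroups[leaf]}
        for level, thr in level_items:
            row[f"{level}_hg"] = named[level].names[by_threshold[thr].assignment[leaf]]
        row["mthg_address"] = addresses[leaf].render()
        rows.append(row)
    return pd.DataFrame(rows)


def check_prefix_consistency(addresses: Mapping[str, MtHgAddress]) -> bool:
    """True iff equality at any address position implies equality at all coarser ones."""
    items = list(addresses.values())
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            agree = [ca == cb for ca, cb in zip(a.components, b.components)]
            seen_disagree = False
            for ok in agree:
                if not ok:
                    seen_disagree = True
                elif seen_disagree:
                    return False
    return True
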