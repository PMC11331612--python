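"""Haplogroup nomenclature: parsing, irregularity classification, and groupings.

Human mtDNA haplogroup names follow (in principle) a cladistic convention: a
single capital letter for a principal cluster, then alternating digit blocks
and single lowercase letters for nested subclusters (``C1d1`` is a subcluster
of ``C1d``, which is nested in ``C1``, which belongs to ``C``).  In practice a
quarter of the names in common reference phylogenies deviate: merged names
with two capitals (``JT``), two consecutive lowercase letters (``H3ag1``),
apostrophe-merged siblings (``M9a'b``), and mutation-annotated suffixes
(``D5a2a1+@16172``).  This module parses names, flags those irregularities,
and computes the common secondary nomenclature-based groupings:

* **SC** (single character) — group by the first letter.
* **SCL** (single character, L with one digit) — like SC, except names
  starting with ``L`` keep their first digit (``L0d2c1a1`` → ``L0``), since
  the deepest-splitting human lineages are all named ``L0``–``L6`` and a bare
  "haplogroup L" does not exist.
* **custom** — longest-prefix match against a user-supplied cluster map.

A :class:`HaplogroupHierarchy` holds a rooted tree of haplogroup names and
answers most-recent-common-ancestor (MRCA) queries, which downstream code
uses to give phylogenetic clusters human-readable haplogroup names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    HierarchyLookupError,
    InvalidNameError,
    NewickError,
    UngroupableNameError,
    UnmappedNameError,
)

__all__ = [
    "HaplogroupName",
    "NameClassificationSummary",
    "HaplogroupHierarchy",
    "parse_name",
    "classify_names",
    "group_sc",
    "group_scl",
    "group_custom",
    "mrca_haplogroup",
    "strip_modifier",
    "schematic_hierarchy",
    "read_haplogroup_calls",
    "annotate_groupings",
]

#: Strict cladistic grammar on the modifier-stripped core: one capital letter,
#: optionally followed by digit blocks alternating with single lowercase
#: letters, ending on either a digit block or a letter.
STRICT_GRAMMAR = re.compile(r"^[A-Z]([0-9]+([a-z][0-9]+)*[a-z]?)?$")

#: Symbols used in reference phylogenies to annotate extra/absent mutations.
IRREGULAR_SYMBOLS = set('*()@+"')

#: Characters at which a trailing mutation-modifier begins (``D5a2a1+@16172``).
_MODIFIER_CHARS = "+@*"

_FLAG_NAMES = (
    "consecutive_upper",
    "consecutive_lower",
    "has_symbols",
    "has_apostrophe",
)


def _normalize(raw: str) -> str:
    """Trim and drop internal whitespace and digit-group commas."""
    return re.sub(r"[\s,]", "", raw.strip())


def strip_modifier(name: str) -> str:
    """Return the clade-identity part of a label, cutting a trailing modifier.

    Modifiers begin at the first ``+``, ``@`` or ``*`` and denote extra or
    absent mutations rather than clade identity.
    """
    name = _normalize(name)
    for i, ch in enumerate(name):
        if ch in _MODIFIER_CHARS:
            return name[:i]
    return name


@dataclass(frozen=True)
class HaplogroupName:
    """A parsed haplogroup label with irregularity flags.

    Attributes
    ----------
    raw : str
        The verbatim input label.
    core : str
        Normalised label with any trailing mutation modifier stripped.
    first_letter : str
        The leading capital letter of ``core``.
    l_prefix : str or None
        ``"L<digit>"`` when the name starts with ``L`` followed by a digit
        (the SCL group), else ``None``.
    consecutive_upper, consecutive_lower, has_symbols, has_apostrophe : bool
        Irregularity flags (two adjacent capitals as in ``JT``; two adjacent
        lowercase letters as in ``H3ag1``; any of ``*()@+"`` in the raw
        label; an apostrophe merge as in ``M9a'b``).
    strict_cladistic : bool
        True iff ``core`` matches the strict grammar and no irregularity
        flag is set.
    """

    raw: str
    core: str
    first_letter: str
    l_prefix: Optional[str]
    consecutive_upper: bool
    consecutive_lower: bool
    has_symbols: bool
    has_apostrophe: bool
    strict_cladistic: bool

    @property
    def flags(self) -> dict:
        return {
            "consecutive_upper": self.consecutive_upper,
            "consecutive_lower": self.consecutive_lower,
            "has_symbols": self.has_symbols,
            "has_apostrophe": self.has_apostrophe,
            "strict_cladistic": self.strict_cladistic,
        }


def parse_name(raw: str) -> HaplogroupName:
    """Parse a haplogroup label and compute its irregularity flags.

    Raises
    ------
    InvalidNameError
        If the label is empty after trimming or does not start with a
        capital letter.
    """
    if not isinstance(raw, str):
        raise InvalidNameError(f"haplogroup name must be a string, got {type(raw).__name__}")
    normalized = _normalize(raw)
    if not normalized:
        raise InvalidNameError("empty haplogroup name")
    if not normalized[0].isupper() or not normalized[0].isalpha():
        raise InvalidNameError(
            f"haplogroup name must start with a capital letter: {raw!r}"
        )
    core = strip_modifier(normalized)
    consecutive_upper = re.search(r"[A-Z]{2}", core) is not None
    consecutive_lower = re.search(r"[a-z]{2}", core) is not None
    has_symbols = any(ch in IRREGULAR_SYMBOLS for ch in normalized)
    has_apostrophe = "'" in core
    strict = (
        STRICT_GRAMMAR.match(core) is not None
        and not (consecutive_upper or consecutive_lower or has_symbols or has_apostrophe)
    )
    l_prefix = core[:2] if len(core) >= 2 and core[0] == "L" and core[1].isdigit() else None
    return HaplogroupName(
        raw=raw,
        core=core,
        first_letter=core[0],
        l_prefix=l_prefix,
        consecutive_upper=consecutive_upper,
        consecutive_lower=consecutive_lower,
        has_symbols=has_symbols,
        has_apostrophe=has_apostrophe,
        strict_cladistic=strict,
    )


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal."""
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class NameClassificationSummary:
    """Irregularity counts and percentages over a list of names."""

    total: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
        }


def classify_names(names: Sequence[str]) -> NameClassificationSummary:
    """Classify a list of haplogroup names by nomenclature irregularity.

    Counts, for each irregularity flag and for strict-cladistic names, how
    many names carry it, with percentages rounded half-up to one decimal.

    Raises
    ------
    InvalidNameError
        Naming the offending element if any name fails to parse.
    """
    names = list(names)
    if not names:
        raise InvalidNameError("classify_names requires a non-empty list")
    counts = {flag: 0 for flag in _FLAG_NAMES}
    counts["strict_cladistic"] = 0
    for raw in names:
        try:
            parsed = parse_name(raw)
        except InvalidNameError as exc:
            raise InvalidNameError(f"cannot parse {raw!r}: {exc}") from exc
        for flag in _FLAG_NAMES:
            counts[flag] += getattr(parsed, flag)
        counts["strict_cladistic"] += parsed.strict_cladistic
    total = len(names)
    percentages = {flag: _pct(n, total) for flag, n in counts.items()}
    return NameClassificationSummary(total=total, counts=counts, percentages=percentages)


def _as_parsed(name) -> HaplogroupName:
    return name if isinstance(name, HaplogroupName) else parse_name(name)


def group_sc(name) -> str:
    """Single Character grouping: the first haplogroup letter.

    ``C1b13c1`` and ``C4a1a3a1`` both map to ``C``.
    """
    return _as_parsed(name).first_letter


def group_scl(name) -> str:
    """Single Character + L-digit grouping.

    Names starting with ``L`` keep their first digit (``L0d2c1a1`` → ``L0``);
    all other names group by first letter.  A bare ``L`` with no digit is an
    error: there is no haplogroup L, and silently emitting one would create
    the polyphyletic pseudo-group this scheme exists to avoid.
    """
    parsed = _as_parsed(name)
    if parsed.first_letter == "L":
        if parsed.l_prefix is None:
            raise UngroupableNameError(
                f"{parsed.raw!r} starts with 'L' but has no digit; "
                "no SCL group exists for a bare L"
            )
        return parsed.l_prefix
    return parsed.first_letter


def group_custom(
    name,
    cluster_map: Mapping[str, str],
    default: Optional[str] = None,
) -> str:
    """Group by longest-prefix match of the core name against ``cluster_map``.

    Supports HaploGrep3-style top-level cluster schemes where e.g. ``HV``
    is its own category alongside ``H``: ``HV1a`` matches the ``HV`` prefix
    in preference to ``H``.

    Raises
    ------
    UnmappedNameError
        If no prefix matches and no ``default`` label was supplied.
    """
    if not cluster_map:
        raise UnmappedNameError("cluster_map must be non-empty")
    core = _as_parsed(name).core
    best = None
    for prefix in cluster_map:
        if core.startswith(prefix) and (best is None or len(prefix) > len(best)):
            best = prefix
    if best is not None:
        return cluster_map[best]
    if default is not None:
        return default
    raise UnmappedNameError(f"no cluster prefix matches {core!r} and no default given")


class HaplogroupHierarchy:
    """A rooted tree of haplogroup names supporting MRCA queries.

    Node names are unique.  Built from ``child<TAB>parent`` edges, or from a
    Newick string whose internal nodes are labeled with haplogroup names.
    """

    def __init__(self, parent_of: Mapping[str, Optional[str]]):
        roots = [n for n, p in parent_of.items() if p is None]
        if len(roots) != 1:
            raise NewickError(f"hierarchy must have exactly one root, found {len(roots)}")
        for name, parent in parent_of.items():
            if parent is not None and parent not in parent_of:
                raise NewickError(f"parent {parent!r} of {name!r} is not a node")
        self._parent = dict(parent_of)
        self.root = roots[0]

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "HaplogroupHierarchy":
        """Build from (child, parent) pairs; the unique parent-less name is the root."""
        parent_of: dict = {}
        for child, parent in edges:
            if child in parent_of and parent_of[child] != parent:
                raise NewickError(f"node {child!r} has two parents")
            parent_of[child] = parent
            parent_of.setdefault(parent, None)
        return cls(parent_of)

    @classmethod
    def from_newick(cls, text: str) -> "HaplogroupHierarchy":
        """Build from a Newick string with labeled internal nodes."""
        import dendropy

        try:
            tree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"cannot parse hierarchy Newick: {exc}") from exc
        edges = []
        def label(node):
            if node.taxon is not None and node.taxon.label:
                return node.taxon.label
            return node.label
        for node in tree.preorder_node_iter():
            name = label(node)
            if name is None:
                raise NewickError("every hierarchy node must carry a haplogroup name")
            if node.parent_node is not None:
                edges.append((name, label(node.parent_node)))
        return cls.from_edges(edges)

    @classmethod
    def from_tsv(cls, path) -> "HaplogroupHierarchy":
        """Build from a two-column ``child<TAB>parent`` TSV (no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
        return cls.from_edges(df.itertuples(index=False, name=None))

    def __contains__(self, name: str) -> bool:
        return name in self._parent

    def __len__(self) -> int:
        return len(self._parent)

    @property
    def names(self):
        return set(self._parent)

    def resolve(self, name: str) -> str:
        """Map a raw label to a hierarchy node, stripping mutation modifiers."""
        core = strip_modifier(name)
        if core not in self._parent:
            raise HierarchyLookupError(f"haplogroup {name!r} (core {core!r}) not in hierarchy")
        return core

    def path_to_root(self, name: str) -> list:
        """Node names from ``name`` up to and including the root."""
        node = self.resolve(name)
        path = [node]
        while self._parent[node] is not None:
            node = self._parent[node]
            path.append(node)
        return path

    def is_ancestor_or_self(self, ancestor: str, descendant: str) -> bool:
        return self.resolve(ancestor) in self.path_to_root(descendant)

    def mrca(self, names: Iterable[str]) -> str:
        """Lowest node that is ancestor-or-self of every named node.

        Raises
        ------
        InvalidNameError
            On an empty name set.
        HierarchyLookupError
            Naming the first label that does not resolve.
        """
        names = list(names)
        if not names:
            raise InvalidNameError("mrca requires at least one haplogroup name")
        # Root-ward paths reversed to start at the root; the MRCA is the last
        # position where all paths agree.
        paths = [self.path_to_root(n)[::-1] for n in names]
        mrca = paths[0][0]
        for level in zip(*paths):
            if len(set(level)) == 1:
                mrca = level[0]
            else:
                break
        return mrca


def mrca_haplogroup(hierarchy: HaplogroupHierarchy, names: Iterable[str]) -> str:
    """MRCA haplogroup of a set of names in a hierarchy (functional form)."""
    return hierarchy.mrca(names)


# Schematic human mtDNA hierarchy, (child, parent) edges.  Mirrors the coarse
# structure of the reference phylogeny: the deepest split separates L0 from
# the composite L1'2'3'4'5'6; M and N sit inside L3; R inside N; the common
# out-of-Africa haplogroups hang off M, N and R.  Intended as a compact,
# well-formed test and demo hierarchy, not a replacement for PhyloTree.
_SCHEMATIC_EDGES = [
    ("L0", "mt-MRCA"),
    ("L1'2'3'4'5'6", "mt-MRCA"),
    ("L0d", "L0"),
    ("L0k", "L0"),
    ("L0d2", "L0d"),
    ("L0d2c", "L0d2"),
    ("L0d2c1", "L0d2c"),
    ("L0d2c1a1", "L0d2c1"),
    ("L0k1a1c", "L0k"),
    ("L1", "L1'2'3'4'5'6"),
    ("L2'3'4'5'6", "L1'2'3'4'5'6"),
    ("L2", "L2'3'4'5'6"),
    ("L3'4'6", "L2'3'4'5'6"),
    ("L5", "L2'3'4'5'6"),
    ("L3'4", "L3'4'6"),
    ("L6", "L3'4'6"),
    ("L3", "L3'4"),
    ("L4", "L3'4"),
    ("M", "L3"),
    ("N", "L3"),
    ("C", "M"),
    ("D", "M"),
    ("M9a'b", "M"),
    ("M9a", "M9a'b"),
    ("M9b", "M9a'b"),
    ("C1", "C"),
    ("C4", "C"),
    ("C1b13c1", "C1"),
    ("C1d", "C1"),
    ("C1d1", "C1d"),
    ("C4a1a3a1", "C4"),
    ("D4", "D"),
    ("D1", "D4"),
    ("D2", "D4"),
    ("D3", "D4"),
    ("D5a2a1", "D"),
    ("A", "N"),
    ("X", "N"),
    ("R", "N"),
    ("B", "R"),
    ("JT", "R"),
    ("U", "R"),
    ("HV", "R"),
    ("H", "HV"),
    ("V", "HV"),
    ("H3ag1", "H"),
    ("B4", "B"),
    ("B4a", "B4"),
    ("B4a1", "B4a"),
    ("B4a1a", "B4a1"),
    ("B4a1a1", "B4a1a"),
    ("B4a1a1b", "B4a1a1"),
    ("J", "JT"),
    ("T", "JT"),
    ("J2", "J"),
    ("J2b", "J2"),
    ("J2b1", "J2b"),
    ("J2b1a", "J2b1"),
]


def schematic_hierarchy() -> HaplogroupHierarchy:
    """The packaged schematic mtDNA haplogroup hierarchy (rooted at mt-MRCA)."""
    return HaplogroupHierarchy.from_edges(_SCHEMATIC_EDGES)


def read_haplogroup_calls(path) -> pd.DataFrame:
    """Read a haplogroup-caller output TSV.

    Requires ``sample_id`` and ``haplogroup`` columns (header row); any other
    columns (quality, ranges, ...) are carried through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "haplogroup"} - set(df.columns)
    if missing:
        raise InvalidNameError(
            f"haplogroup call table lacks required column(s): {sorted(missing)}"
        )
    return df


def annotate_groupings(
    calls: pd.DataFrame,
    cluster_map: Optional[Mapping[str, str]] = None,
    default: Optional[str] = None,
) -> pd.DataFrame:
    """Add ``sc``, ``scl`` (and ``custom`` if a map is given) columns.

    SCL entries that cannot be formed (bare ``L``) raise; use a custom map
    with a default label to triage such inputs instead.
    """
    out = calls.copy()
    parsed = [parse_name(h) for h in out["haplogroup"]]
    out["sc"] = [group_sc(p) for p in parsed]
    out["scl"] = [group_scl(p) for p in parsed]
    if cluster_map is not None:
        out["custom"] = [group_custom(p, cluster_map, default=default) for p in parsed]
    return out
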