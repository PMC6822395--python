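"""Dating a TE insertion from its presence/absence across taxa.

A retrotransposon insertion is effectively a single-gain, no-loss (Dollo)
character: it arises once and is essentially never precisely excised.  The
taxa carrying the insertion must therefore form a clade, and the insertion
happened on the stem branch of that clade — between the age of the clade's
root node and the age of its parent node on a calibrated species tree.

Trees are read from Newick; node ages in millions of years (myr) are taken
from branch lengths (leaves at age 0) or, where branch lengths are absent,
from numeric internal-node labels.  A packaged 10-leaf primate fixture tree
is provided with the calibrations used throughout this package (root at
63 myr, catarrhine/platyrrhine split at 40 myr, hominoid/cercopithecoid
split at 25 myr).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import dendropy

__all__ = [
    "SpeciesTree",
    "PhyleticProfile",
    "IntegrationWindow",
    "HomoplasyError",
    "infer_window",
    "profile_from_amplicons",
    "primate_fixture_tree",
    "PRIMATE_LEAVES",
]


class HomoplasyError(ValueError):
    """The presence set is not monophyletic: the single-gain model is violated."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

_ULTRAMETRIC_RTOL = 1e-6


class SpeciesTree:
    """A rooted, ultrametric species tree with node ages in myr.

    Thin wrapper over a :class:`dendropy.Tree`; every node gets an ``age``
    attribute (leaves at 0, non-decreasing toward the root).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._assign_ages()
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf names in tree")
        self._leaf_names = names

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: Union[str, Path]) -> "SpeciesTree":
        """Read a tree from a Newick string or file path.

        Both age dialects are accepted: branch lengths (ages derived from
        leaf depth) or numeric internal-node labels as ages directly.
        """
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source
        ):
            tree = dendropy.Tree.get(path=str(source), schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     preserve_underscores=True)
        return cls(tree)

    # -- ages ---------------------------------------------------------------

    def _assign_ages(self) -> None:
        tree = self._tree
        has_lengths = any(
            e.length is not None for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        )
        if has_lengths:
            depths: dict = {tree.seed_node: 0.0}
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                length = node.edge.length or 0.0
                depths[node] = depths[node.parent_node] + length
            leaf_depths = [depths[lf] for lf in tree.leaf_node_iter()]
            height = max(leaf_depths)
            tol = _ULTRAMETRIC_RTOL * max(height, 1.0)
            if max(leaf_depths) - min(leaf_depths) > tol:
                raise ValueError(
                    "tree is not ultrametric: leaf depths range "
                    f"{min(leaf_depths)}..{max(leaf_depths)}"
                )
            for node in tree.preorder_node_iter():
                node.age = height - depths[node]
        else:
            # node-label dialect: internal labels are ages, leaves at 0
            for node in tree.preorder_node_iter():
                if node.is_leaf():
                    node.age = 0.0
                else:
                    if node.label is None:
                        raise ValueError(
                            "tree has neither branch lengths nor node-label ages"
                        )
                    node.age = float(node.label)
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None and node.age > node.parent_node.age:
                raise ValueError("node ages must be non-decreasing toward the root")

    # -- queries ------------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return list(self._leaf_names)

    @property
    def root_age(self) -> float:
        return self._tree.seed_node.age

    def node_label(self, node) -> Optional[str]:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def age_of(self, label: str) -> float:
        for node in self._tree.preorder_node_iter():
            if self.node_label(node) == label:
                return node.age
        raise KeyError(label)

    def find_node(self, label: str):
        for node in self._tree.preorder_node_iter():
            if self.node_label(node) == label:
                return node
        raise KeyError(label)

    def leaves_under(self, label: str) -> set[str]:
        node = self.find_node(label)
        return {lf.taxon.label for lf in node.leaf_iter()}

    def mrca(self, leaf_names) -> "dendropy.Node":
        wanted = set(leaf_names)
        missing = wanted - set(self._leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        leaf_nodes = [
            lf for lf in self._tree.leaf_node_iter() if lf.taxon.label in wanted
        ]
        node = leaf_nodes[0]
        covered = {node.taxon.label}
        while covered < wanted:
            node = node.parent_node
            covered = {lf.taxon.label for lf in node.leaf_iter()}
        return node

    def internal_labels(self) -> list[str]:
        return [
            node.label
            for node in self._tree.preorder_node_iter()
            if not node.is_leaf() and node.label
        ]


# ---------------------------------------------------------------------------
# Profiles and windows
# ---------------------------------------------------------------------------

_STATES = ("present", "absent", "unknown")


@dataclass
class PhyleticProfile:
    """Per-taxon presence/absence of one insertion locus."""

    states: dict[str, str]

    def __post_init__(self):
        for taxon, state in self.states.items():
            if state not in _STATES:
                raise ValueError(f"{taxon}: state must be one of {_STATES}")
        if not self.present_leaves:
            raise ValueError("profile must mark at least one leaf present")

    @property
    def present_leaves(self) -> set[str]:
        return {t for t, s in self.states.items() if s == "present"}

    @property
    def unknown_leaves(self) -> set[str]:
        return {t for t, s in self.states.items() if s == "unknown"}

    @classmethod
    def from_presence(cls, present, all_leaves) -> "PhyleticProfile":
        present = set(present)
        return cls({t: ("present" if t in present else "absent") for t in all_leaves})


@dataclass
class IntegrationWindow:
    """The branch and age interval on which an insertion arose.

    ``upper_age`` is ``None`` (open) when the inferred branch is the root
    stem — the insertion predates the sampled taxa's common ancestor.
    """

    branch: tuple[Optional[str], Optional[str]]
    lower_age: float
    upper_age: Optional[float]

    def __post_init__(self):
        if self.upper_age is not None and not (self.lower_age < self.upper_age):
            raise ValueError("lower_age must be < upper_age when bounded")


def infer_window(tree: SpeciesTree, profile: PhyleticProfile) -> IntegrationWindow:
    """Infer the integration branch and age window under the Dollo model.

    The insertion is placed on the stem of the minimal clade containing all
    ``present`` leaves.  ``unknown`` leaves are excluded from the monophyly
    test but may fall inside the clade.  A presence set that is not
    monophyletic raises :class:`HomoplasyError`.
    """
    present = profile.present_leaves
    unknown = profile.unknown_leaves
    extra = set(profile.states) - set(tree.leaf_names)
    if extra:
        raise KeyError(f"profile names leaves not in tree: {sorted(extra)}")
    node = tree.mrca(present)
    clade = {lf.taxon.label for lf in node.leaf_iter()}
    required = clade - unknown
    if present != required:
        raise HomoplasyError(
            "presence set is not monophyletic on the tree: clade under "
            f"{tree.node_label(node) or '<mrca>'} requires presence in "
            f"{sorted(required)} but profile marks {sorted(present)}"
        )
    parent = node.parent_node
    return IntegrationWindow(
        branch=(tree.node_label(parent) if parent is not None else None,
                tree.node_label(node)),
        lower_age=node.age,
        upper_age=parent.age if parent is not None else None,
    )


def profile_from_amplicons(
    bands: Mapping[str, Optional[float]],
    expected_with: float,
    expected_without: float,
    tolerance: float,
) -> PhyleticProfile:
    """Classify per-taxon PCR amplicon sizes into a phyletic profile.

    A band within ``tolerance`` of ``expected_with`` (locus carrying the
    insertion) is ``present``; within ``tolerance`` of ``expected_without``
    is ``absent``; anything else — including a missing band (``None``) — is
    ``unknown`` and flagged for sequencing.  Amplicon size alone can
    mislead (an unrelated insertion of similar length mimics presence),
    which is why the two expectation intervals must not overlap.
    """
    if expected_with <= expected_without:
        raise ValueError("expected_with must exceed expected_without")
    if expected_with - tolerance <= expected_without + tolerance:
        raise ValueError(
            "tolerance intervals around the two expected sizes overlap; "
            "reduce tolerance or re-measure expectations"
        )
    states = {}
    for taxon, band in bands.items():
        if band is None:
            states[taxon] = "unknown"
        elif abs(band - expected_with) <= tolerance:
            states[taxon] = "present"
        elif abs(band - expected_without) <= tolerance:
            states[taxon] = "absent"
        else:
            states[taxon] = "unknown"
    return PhyleticProfile(states)


# ---------------------------------------------------------------------------
# Packaged primate fixture tree
# ---------------------------------------------------------------------------

PRIMATE_LEAVES = (
    "human", "chimpanzee", "gibbon",
    "rhesus_macaque", "crab_eating_macaque", "african_green_monkey", "colobus",
    "marmoset", "squirrel_monkey",
    "ring_tailed_lemur",
)

# (label, children); leaves are bare strings
_PRIMATE_TOPOLOGY = (
    "primates", [
        ("simiiformes", [
            ("catarrhini", [
                ("hominoidea", [
                    ("hominini", ["human", "chimpanzee"]),
                    "gibbon",
                ]),
                ("cercopithecidae", [
                    ("cercopithecinae", [
                        ("macaca", ["rhesus_macaque", "crab_eating_macaque"]),
                        "african_green_monkey",
                    ]),
                    "colobus",
                ]),
            ]),
            ("platyrrhini", ["marmoset", "squirrel_monkey"]),
        ]),
        "ring_tailed_lemur",
    ],
)

_DEFAULT_AGES = {
    "primates": 63.0,        # simian + prosimian common ancestor
    "simiiformes": 40.0,     # catarrhine / platyrrhine split
    "catarrhini": 25.0,      # hominoid / cercopithecoid split
    "hominoidea": 20.0,
    "hominini": 6.0,
    "cercopithecidae": 18.0,
    "cercopithecinae": 10.0,
    "macaca": 5.0,
    "platyrrhini": 20.0,
}


def _render_newick(node, ages: dict[str, float], parent_age: Optional[float]) -> str:
    if isinstance(node, str):  # leaf
        return f"{node}:{parent_age:g}"
    label, children = node
    age = ages[label]
    inner = ",".join(_render_newick(c, ages, age) for c in children)
    if parent_age is None:
        return f"({inner}){label}"
    return f"({inner}){label}:{parent_age - age:g}"


def primate_fixture_tree(**age_overrides: float) -> SpeciesTree:
    """The packaged 10-leaf primate tree used throughout this package.

    Leaves: human, chimpanzee, gibbon (hominoids); rhesus, crab-eating and
    African green monkeys, colobus (Old World monkeys); marmoset, squirrel
    monkey (New World monkeys); ring-tailed lemur (prosimian).  Internal
    node ages (myr) default to root 63, catarrhine/platyrrhine 40,
    hominoid/cercopithecoid 25, and can be overridden by label, e.g.
    ``primate_fixture_tree(primates=70)``.
    """
    ages = dict(_DEFAULT_AGES)
    for label, age in age_overrides.items():
        if label not in ages:
            raise KeyError(f"unknown internal node {label!r}; have {sorted(ages)}")
        ages[label] = float(age)
    newick = _render_newick(_PRIMATE_TOPOLOGY, ages, None) + ";"
    return SpeciesTree.from_newick(newick)
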