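"""Newick I/O, validation, and individual-to-species mapping.

Parsing and serialization are delegated to dendropy; trees are then held in a
lightweight node structure (`PhyloTree`) that the simulator and the quartet
aggregation code can traverse cheaply.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence

import dendropy

logger = logging.getLogger("castles")

__all__ = [
    "Node",
    "PhyloTree",
    "TaxonMap",
    "TreeError",
    "NewickParseError",
    "ValidationError",
    "parse_newick",
    "write_newick",
    "read_gene_trees",
    "read_mapping",
    "validate_inputs",
    "ValidatedBundle",
]


class TreeError(ValueError):
    """Base class for tree input errors."""


class NewickParseError(TreeError):
    """Malformed newick input."""


class ValidationError(TreeError):
    """Structurally valid tree that violates a pipeline precondition."""


class Node:
    """A tree node: leaf if it has no children.

    ``length`` is the substitution-unit length of the edge above the node
    (``None`` on the root and on topology-only trees).  ``label`` holds the
    taxon name for leaves and any internal label/support text otherwise.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length})"


class PhyloTree:
    """Rooted or unrooted tree with optional SU branch lengths."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), self.rooted)

    def __len__(self) -> int:
        return len(self.leaves())

    def __str__(self) -> str:
        return write_newick(self, precision=10, require_lengths=False)


# ---------------------------------------------------------------------------
# newick parsing / writing
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(label=dnode.label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def parse_newick(text: str, expect_lengths: bool = False) -> PhyloTree:
    """Parse a single newick tree.

    With ``expect_lengths`` every edge below the root must carry a ``:length``;
    a missing one raises :class:`ValidationError` naming the edge.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            # leaf labels stay plain labels: duplicate labels (multiple
            # individuals of one species) are legal in gene trees and are
            # vetted later against the taxon map
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    for node in tree.preorder():
        if node.is_leaf and (node.label is None or node.label == ""):
            raise ValidationError("leaf with empty label")
        if node.length is not None and not _finite(node.length):
            raise ValidationError(f"non-finite branch length above {_edge_name(node)}")
    if expect_lengths:
        for node in tree.preorder():
            if node is tree.root:
                continue
            if node.length is None:
                raise ValidationError(f"missing branch length above {_edge_name(node)}")
    return tree


def _finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))


def _edge_name(node: Node) -> str:
    if node.is_leaf:
        return f"leaf {node.label!r}"
    tips = []
    stack = [node]
    while stack and len(tips) < 3:
        n = stack.pop()
        if n.is_leaf:
            tips.append(n.label)
        else:
            stack.extend(n.children)
    return "clade containing " + ", ".join(repr(t) for t in tips)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _format_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(
    tree: PhyloTree, precision: int = 10, require_lengths: bool = True
) -> str:
    """Serialize to newick. Round-trip stable to ``precision`` significant digits."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            core = _format_label(node.label)
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                core += _format_label(node.label)
        if node.parent is None:
            return core
        if node.length is None:
            if require_lengths:
                raise ValidationError(
                    f"cannot serialize: missing length above {_edge_name(node)}"
                )
            return core
        return core + ":" + format(node.length, f".{precision}g")

    return fmt(tree.root) + ";"


def read_gene_trees(path_or_text, expect_lengths: bool = True) -> List[PhyloTree]:
    """Read one-newick-per-line gene trees from a path or file-like object."""
    if hasattr(path_or_text, "read"):
        content = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            content = fh.read()
    trees = []
    for i, line in enumerate(content.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line, expect_lengths=expect_lengths))
        except TreeError as exc:
            raise type(exc)(f"gene tree on line {i}: {exc}") from exc
    return trees


# ---------------------------------------------------------------------------
# taxon mapping
# ---------------------------------------------------------------------------


@dataclass
class TaxonMap:
    """Individual-label -> species-label mapping; identity when empty."""

    mapping: Dict[str, str] = field(default_factory=dict)

    def species_of(self, individual: str) -> str:
        return self.mapping.get(individual, individual)

    def __contains__(self, individual: str) -> bool:
        return individual in self.mapping

    @property
    def is_identity(self) -> bool:
        return not self.mapping


def read_mapping(path_or_text) -> TaxonMap:
    """Parse a mapping file.

    Accepts two-column lines ``individual<TAB>species`` (whitespace tolerated)
    and the ``species: ind1,ind2`` style on a single line.
    """
    if hasattr(path_or_text, "read"):
        content = path_or_text.read()
    elif "\n" in str(path_or_text):
        content = str(path_or_text)
    else:
        with open(path_or_text) as fh:
            content = fh.read()
    mapping: Dict[str, str] = {}
    for i, raw in enumerate(content.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line:
            species, _, inds = line.partition(":")
            species = species.strip()
            for ind in re.split(r"[,\s]+", inds.strip()):
                if ind:
                    mapping[ind] = species
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"mapping line {i}: expected two columns, got {raw!r}")
            ind, species = parts
            mapping[ind] = species
    return TaxonMap(mapping)


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidatedBundle:
    species: PhyloTree
    genes: List[PhyloTree]
    taxon_map: TaxonMap
    gene_flags: List[str]  # "ok" | "zero_information" | "no_signal"

    @property
    def usable_genes(self) -> List[PhyloTree]:
        return [g for g, f in zip(self.genes, self.gene_flags) if f == "ok"]


def _check_species_tree(species: PhyloTree) -> None:
    if len(species.root.children) != 2:
        raise ValidationError(
            "species tree must be rooted with a bifurcating root "
            f"(root has {len(species.root.children)} children)"
        )
    labels = []
    for node in species.preorder():
        if node.is_leaf:
            labels.append(node.label)
        elif node is not species.root and len(node.children) != 2:
            raise ValidationError(
                f"species tree must be binary ({_edge_name(node)} has "
                f"{len(node.children)} children)"
            )
    if len(labels) < 4:
        raise ValidationError(f"species tree needs >= 4 leaves, found {len(labels)}")
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValidationError(f"duplicate species labels: {sorted(dupes)}")


def validate_inputs(
    species: PhyloTree,
    genes: Sequence[PhyloTree],
    taxon_map: Optional[TaxonMap] = None,
) -> ValidatedBundle:
    """Check the species tree / gene trees / mapping bundle.

    Species-tree input branch lengths, if any, are discarded (lengths are
    annotated from scratch).  Gene trees with fewer than four distinct mapped
    species are kept but flagged ``zero_information``; gene trees whose branch
    lengths are all zero are flagged ``no_signal``.
    """
    taxon_map = taxon_map or TaxonMap()
    _check_species_tree(species)
    species = species.copy()
    had_lengths = any(
        n.length is not None for n in species.preorder() if n is not species.root
    )
    if had_lengths:
        logger.warning("species tree input branch lengths are ignored")
        for node in species.preorder():
            node.length = None

    species_labels = set(species.leaf_labels())
    for ind, sp in taxon_map.mapping.items():
        if sp not in species_labels:
            raise ValidationError(
                f"mapping assigns {ind!r} to species {sp!r} absent from the species tree"
            )

    flags: List[str] = []
    for gi, gene in enumerate(genes):
        unmapped = []
        seen_labels: Dict[str, int] = {}
        mapped_species = set()
        lengths = []
        for node in gene.preorder():
            if node.is_leaf:
                seen_labels[node.label] = seen_labels.get(node.label, 0) + 1
                sp = taxon_map.species_of(node.label)
                if sp not in species_labels:
                    unmapped.append(node.label)
                mapped_species.add(sp)
            if node is not gene.root and node.length is None:
                raise ValidationError(
                    f"gene tree {gi} lacks a branch length above {_edge_name(node)}"
                )
            if node.length is not None:
                lengths.append(node.length)
        if unmapped:
            raise ValidationError(
                f"gene tree {gi} has leaves not mappable to the species tree: "
                f"{sorted(set(unmapped))}"
            )
        dupes = sorted(l for l, c in seen_labels.items() if c > 1 and l not in taxon_map)
        if dupes:
            raise ValidationError(
                f"gene tree {gi} repeats leaf labels {dupes} without a mapping entry"
            )
        if len(mapped_species) < 4:
            flags.append("zero_information")
        elif lengths and all(x == 0 for x in lengths):
            logger.warning("gene tree %d has all-zero branch lengths; excluded", gi)
            flags.append("no_signal")
        else:
            flags.append("ok")
    return ValidatedBundle(species, list(genes), taxon_map, flags)
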