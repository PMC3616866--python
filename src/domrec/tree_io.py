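"""Rooted phylogenetic trees, annotation tables, and input validation.

Trees are plain rooted node structures with ordered children, optional
branch lengths and optional internal labels.  Newick parsing is delegated
to :mod:`dendropy`; the rest of the pipeline only ever sees
:class:`PhyloTree`.  Leaf annotations bind each gene to a species and to a
binary protein architecture: ``FUSED`` for the composite receptor kinase
(extracellular S domain + transmembrane + kinase) and ``SPLIT`` for the
kinase-only cytoplasmic form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

FUSED = "FUSED"
SPLIT = "SPLIT"
STATES = (FUSED, SPLIT)


class TreeError(ValueError):
    """Malformed tree input (syntax or structural invariant violation)."""


class AnnotationError(ValueError):
    """Malformed or inconsistent leaf annotation table."""


class Node:
    """A node of a rooted tree with ordered children.

    Attributes
    ----------
    label : str or None
        Leaf labels are mandatory and unique; internal labels optional.
    branch_length : float or None
        Length of the edge above this node; carried but never used by
        inference (the event model is topology-only).
    """

    __slots__ = ("label", "children", "branch_length", "parent")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["Node"]] = None,
                 branch_length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.branch_length = branch_length
        self.parent: Optional[Node] = None
        for c in children or []:
            self.add_child(c)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


@dataclass
class PhyloTree:
    """A rooted tree with uniquely-labelled leaves."""

    root: Node

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def validate(self) -> None:
        """Check leaf-label uniqueness and non-emptiness."""
        labels = self.leaf_labels()
        if any(not lab for lab in labels):
            raise TreeError("every leaf must carry a non-empty label")
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise TreeError(f"duplicate leaf label: {lab!r}")
            seen.add(lab)

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.label, branch_length=n.branch_length)
            for c in n.children:
                m.add_child(rec(c))
            return m
        return PhyloTree(rec(self.root))


def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(label=label, branch_length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(text: str) -> PhyloTree:
    """Parse a single rooted tree from a newick string.

    Quoted labels and ``[...]`` comments are accepted; duplicate leaf
    labels and syntax errors raise :class:`TreeError` (with the position
    reported by the underlying parser).  An unrooted-style trifurcating
    root is accepted here and rejected later by :func:`bind`, so that
    utility code can still inspect such trees.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate leaf label: {exc}") from exc
    except Exception as exc:  # dendropy raises several reader error types
        raise TreeError(f"newick parse error: {exc}") from exc
    tree = PhyloTree(_from_dendropy(dtree.seed_node))
    tree.validate()
    return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(tree: PhyloTree) -> str:
    """Serialize to newick; inverse of :func:`read_newick` up to quoting."""
    buf = io.StringIO()

    def rec(n: Node) -> None:
        if n.children:
            buf.write("(")
            for i, c in enumerate(n.children):
                if i:
                    buf.write(",")
                rec(c)
            buf.write(")")
        if n.label is not None:
            buf.write(_quote(n.label))
        if n.branch_length is not None:
            buf.write(":" + _fmt_length(n.branch_length))

    rec(tree.root)
    buf.write(";")
    return buf.getvalue()


@dataclass(frozen=True)
class LeafAnnotation:
    """One gene leaf bound to its species and architecture state."""

    gene_id: str
    species_id: str
    architecture: str

    def __post_init__(self):
        if self.architecture not in STATES:
            raise AnnotationError(
                f"unknown architecture {self.architecture!r} for gene "
                f"{self.gene_id!r}; expected FUSED or SPLIT")


_ANNOT_HEADER = ("gene_id", "species_id", "architecture")


def read_annotations(text: str) -> list[LeafAnnotation]:
    """Parse a tab-separated annotation table.

    Expects a header row ``gene_id\\tspecies_id\\tarchitecture``; the
    architecture column is case-insensitive (``fused``/``FUSED``).
    Duplicate gene ids are rejected.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("empty annotation table")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != _ANNOT_HEADER:
        raise AnnotationError(
            f"bad header {header!r}; expected {_ANNOT_HEADER!r}")
    out: list[LeafAnnotation] = []
    seen: set[str] = set()
    for i, ln in enumerate(lines[1:], start=2):
        cols = [c.strip() for c in ln.split("\t")]
        if len(cols) != 3:
            raise AnnotationError(f"line {i}: expected 3 columns, got {len(cols)}")
        gene, species, arch = cols
        arch = arch.upper()
        if arch not in STATES:
            raise AnnotationError(
                f"line {i}: unknown architecture token {cols[2]!r}")
        if gene in seen:
            raise AnnotationError(f"line {i}: duplicate gene_id {gene!r}")
        seen.add(gene)
        out.append(LeafAnnotation(gene, species, arch))
    return out


def write_annotations(annotations: list[LeafAnnotation]) -> str:
    rows = ["\t".join(_ANNOT_HEADER)]
    rows += [f"{a.gene_id}\t{a.species_id}\t{a.architecture}"
             for a in annotations]
    return "\n".join(rows) + "\n"


@dataclass
class BoundDataset:
    """A gene tree, species tree and annotations validated together.

    After :func:`bind` both trees are strictly binary, every internal node
    carries a unique label (auto-assigned ``gn*``/``sn*`` in preorder when
    absent), and per-leaf species / architecture lookups are populated.
    """

    gene_tree: PhyloTree
    species_tree: PhyloTree
    annotations: list[LeafAnnotation]
    species_of: dict[str, str] = field(default_factory=dict)
    state_of: dict[str, str] = field(default_factory=dict)


def _ensure_internal_labels(tree: PhyloTree, prefix: str) -> None:
    used = set(n.label for n in tree.preorder() if n.label)
    i = 0
    for n in tree.preorder():
        if n.is_leaf:
            continue
        if not n.label or n.label in ("",):
            while True:
                i += 1
                cand = f"{prefix}{i}"
                if cand not in used:
                    break
            n.label = cand
            used.add(cand)


def _check_unique_node_labels(tree: PhyloTree, role: str) -> None:
    seen: set[str] = set()
    for n in tree.preorder():
        if n.label in seen:
            raise TreeError(f"{role}: duplicate node label {n.label!r}")
        seen.add(n.label)


def bind(gene_tree: PhyloTree, species_tree: PhyloTree,
         annotations: list[LeafAnnotation]) -> BoundDataset:
    """Validate the triple and return a dataset ready for reconciliation.

    Raises on: non-binary nodes (polytomies are never resolved
    implicitly), unannotated gene leaves, annotations referencing unknown
    species, and annotation rows for genes absent from the tree.
    """
    gene_tree = gene_tree.copy()
    species_tree = species_tree.copy()
    for tree, role in ((gene_tree, "gene tree"), (species_tree, "species tree")):
        tree.validate()
        for n in tree.preorder():
            if len(n.children) not in (0, 2):
                raise TreeError(
                    f"{role}: non-binary node with {len(n.children)} children"
                    + (f" (label {n.label!r})" if n.label else ""))
    _ensure_internal_labels(gene_tree, "gn")
    _ensure_internal_labels(species_tree, "sn")
    _check_unique_node_labels(gene_tree, "gene tree")
    _check_unique_node_labels(species_tree, "species tree")

    species_leaves = set(species_tree.leaf_labels())
    by_gene = {a.gene_id: a for a in annotations}
    if len(by_gene) != len(annotations):
        raise AnnotationError("duplicate gene_id in annotations")
    species_of: dict[str, str] = {}
    state_of: dict[str, str] = {}
    for leaf in gene_tree.leaf_labels():
        ann = by_gene.get(leaf)
        if ann is None:
            raise AnnotationError(f"gene leaf {leaf!r} has no annotation row")
        if ann.species_id not in species_leaves:
            raise AnnotationError(
                f"gene {leaf!r} refers to unknown species {ann.species_id!r}")
        species_of[leaf] = ann.species_id
        state_of[leaf] = ann.architecture
    extra = set(by_gene) - set(species_of)
    if extra:
        raise AnnotationError(
            f"annotation rows for genes absent from the tree: {sorted(extra)}")
    return BoundDataset(gene_tree, species_tree, annotations,
                        species_of, state_of)


def ladderize_polytomies(tree: PhyloTree) -> PhyloTree:
    """Deterministically resolve polytomies by left-ladderization.

    A convenience utility only — inference itself always rejects
    polytomies, so any resolution is an explicit, visible preprocessing
    step.
    """
    tree = tree.copy()
    for n in list(tree.preorder()):
        while len(n.children) > 2:
            last = n.children.pop()
            penult = n.children.pop()
            joint = Node(children=[penult, last])
            n.add_child(joint)
    return tree
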