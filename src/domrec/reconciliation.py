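"""Duplication–loss parsimony reconciliation by LCA mapping.

Each gene-tree node is mapped to the most recent common ancestor (in the
species tree) of the species of its descendant genes.  Under this mapping
the implied numbers of duplications and losses are simultaneously minimal
over all valid reconciliations; internal nodes are labelled ``duplication``
when the mapping coincides with a child's mapping and ``speciation``
otherwise, and every loss is placed on the specific species-tree branch it
skips.  Dating is categorical: a duplication mapped to species node *s*
happened on the branch entering *s* (for the species root, on a virtual
root stem).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .tree_io import BoundDataset, Node

SPECIATION = "speciation"
DUPLICATION = "duplication"

#: Branch identifier for the virtual branch above the species-tree root.
ROOT_STEM = "__root_stem__"


@dataclass
class SpeciesIndex:
    """Constant-time ancestry queries on a labelled binary species tree."""

    root: Node
    nodes: dict[str, Node] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    parent: dict[str, str | None] = field(default_factory=dict)

    @classmethod
    def build(cls, root: Node) -> "SpeciesIndex":
        idx = cls(root)
        stack = [(root, 0, None)]
        while stack:
            node, d, par = stack.pop()
            idx.nodes[node.label] = node
            idx.depth[node.label] = d
            idx.parent[node.label] = par
            for c in node.children:
                stack.append((c, d + 1, node.label))
        return idx

    def lca(self, a: str, b: str) -> str:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a != b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def is_ancestor_or_equal(self, anc: str, desc: str) -> bool:
        return self.lca(anc, desc) == anc

    def path_length(self, anc: str, desc: str) -> int:
        """Number of species-tree edges from ``anc`` down to ``desc``."""
        d = self.depth[desc] - self.depth[anc]
        if d < 0 or not self.is_ancestor_or_equal(anc, desc):
            raise ValueError(f"{anc!r} is not ancestral to {desc!r}")
        return d

    def path_down(self, anc: str, desc: str) -> list[str]:
        """Node labels from ``anc`` to ``desc`` inclusive, top first."""
        path = [desc]
        while path[-1] != anc:
            p = self.parent[path[-1]]
            if p is None:
                raise ValueError(f"{anc!r} is not ancestral to {desc!r}")
            path.append(p)
        return list(reversed(path))

    def sibling(self, label: str) -> str:
        par = self.parent[label]
        if par is None:
            raise ValueError("species root has no sibling")
        a, b = (c.label for c in self.nodes[par].children)
        return b if a == label else a

    def branch_of(self, label: str) -> str:
        """Identifier of the branch entering a species node.

        Branches are named by their child node; the branch above the
        species root is the virtual :data:`ROOT_STEM`.
        """
        return label if self.parent[label] is not None else ROOT_STEM


@dataclass
class Reconciliation:
    """LCA mapping with event labels and dated losses."""

    dataset: BoundDataset
    species_index: SpeciesIndex
    #: gene node label -> species node label (the LCA mapping M)
    mapping: dict[str, str]
    #: gene internal node label -> "speciation" | "duplication"
    event_label: dict[str, str]
    #: species branch (child-node label or ROOT_STEM) -> loss count
    losses: Counter
    #: per gene edge (child gene label) -> list of species branches lost
    loss_branches_by_edge: dict[str, list[str]]
    dup_count: int
    loss_count: int

    def events_at_node(self, gene_label: str) -> str:
        return self.event_label[gene_label]


def lca_map(dataset: BoundDataset) -> tuple[dict[str, str], SpeciesIndex]:
    """Compute the LCA mapping M for a bound dataset."""
    idx = SpeciesIndex.build(dataset.species_tree.root)
    mapping: dict[str, str] = {}
    for node in dataset.gene_tree.postorder():
        if node.is_leaf:
            mapping[node.label] = dataset.species_of[node.label]
        else:
            left, right = node.children
            mapping[node.label] = idx.lca(mapping[left.label],
                                          mapping[right.label])
    return mapping, idx


def label_events(dataset: BoundDataset,
                 mapping: dict[str, str]) -> tuple[dict[str, str], int]:
    """Label internal gene nodes as duplication or speciation."""
    labels: dict[str, str] = {}
    dup_count = 0
    for node in dataset.gene_tree.preorder():
        if node.is_leaf:
            continue
        m = mapping[node.label]
        if any(mapping[c.label] == m for c in node.children):
            labels[node.label] = DUPLICATION
            dup_count += 1
        else:
            labels[node.label] = SPECIATION
    return labels, dup_count


def count_losses(dataset: BoundDataset, mapping: dict[str, str],
                 event_label: dict[str, str], idx: SpeciesIndex,
                 ) -> tuple[Counter, dict[str, list[str]], int]:
    """Place every implied loss on the species branch it skips.

    On the gene edge (v, c) the lineage descends from M(v) to M(c).  At
    each species node passed strictly between the two (plus M(v) itself
    when v is a duplication, since a duplicate lineage is present above
    the speciation at M(v)), the sister branch not taken carries one loss.
    """
    losses: Counter = Counter()
    by_edge: dict[str, list[str]] = {}
    for node in dataset.gene_tree.preorder():
        if node.is_leaf:
            continue
        mv = mapping[node.label]
        for child in node.children:
            mc = mapping[child.label]
            path = idx.path_down(mv, mc)  # [mv, ..., mc]
            # species nodes at which the lineage takes one daughter branch
            # and the other daughter carries a loss:
            start = 0 if event_label[node.label] == DUPLICATION else 1
            edge_losses: list[str] = []
            for i in range(start, len(path) - 1):
                taken = path[i + 1]
                lost = idx.sibling(taken)
                edge_losses.append(lost)
            if edge_losses:
                by_edge[child.label] = edge_losses
                losses.update(edge_losses)
    return losses, by_edge, sum(losses.values())


def date_event(gene_label: str, mapping: dict[str, str],
               event_label: dict[str, str], idx: SpeciesIndex) -> str:
    """Date an event at a gene node to a species branch or node.

    Duplications (and the fusion/fission events attached to a node by the
    architecture module) are dated to the branch entering the mapped
    species node; a mapping to the species root dates to the root stem.
    Speciation nodes date exactly to their species node, returned as the
    node label itself.
    """
    m = mapping[gene_label]
    if event_label.get(gene_label) == SPECIATION:
        return m
    return idx.branch_of(m)


def reconcile(dataset: BoundDataset) -> Reconciliation:
    """Full duplication-loss parsimony reconciliation."""
    mapping, idx = lca_map(dataset)
    event_label, dup_count = label_events(dataset, mapping)
    losses, by_edge, loss_count = count_losses(dataset, mapping,
                                               event_label, idx)
    return Reconciliation(dataset, idx, mapping, event_label, losses,
                          by_edge, dup_count, loss_count)


def to_report(rec: Reconciliation) -> dict:
    """JSON-serializable reconciliation report."""
    return {
        "mapping": dict(sorted(rec.mapping.items())),
        "event_label": dict(sorted(rec.event_label.items())),
        "losses_per_branch": dict(sorted(rec.losses.items())),
        "dup_count": rec.dup_count,
        "loss_count": rec.loss_count,
    }


def annotated_newick(rec: Reconciliation) -> str:
    """Gene tree with internal labels replaced by D/S event codes."""
    from .tree_io import write_newick

    tree = rec.dataset.gene_tree.copy()
    for n in tree.preorder():
        if not n.is_leaf:
            code = "D" if rec.event_label[n.label] == DUPLICATION else "S"
            n.label = f"{n.label}_{code}"
    return write_newick(tree)
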