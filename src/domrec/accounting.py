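"""Per-branch evolutionary ledgers over the species tree.

For every species-tree branch the ledger tallies gene gains
(duplications dated to the branch), losses, fusions and fissions, and for
every species node the number of gene lineages crossing its speciation
("ancestor count"), split by architecture class.  The counts obey the
bookkeeping identity

    count(s) = count(parent(s)) + gains(branch into s) - losses(branch into s)

and, class-wise, the FUSED count additionally changes by
``+fusions - fissions`` on the branch (SPLIT symmetrically).  The identity
is enforced as an internal audit on every ledger the pipeline produces,
never assumed.

A lineage is counted as *crossing* the speciation at species node ``s``
when its gene edge (p, c) starts before that speciation — M(p) a strict
ancestor of ``s``, or M(p) = s with p a duplication, or p the virtual
parent above the gene root with M(root) at or below ``s`` — and ends at or
after it: M(c) = s with c a speciation or leaf, or M(c) a strict
descendant of ``s``.  At a species leaf the crossing count is simply the
number of extant genes of that species.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .architecture import ArchAssignment
from .reconciliation import DUPLICATION, ROOT_STEM, Reconciliation
from .tree_io import FUSED, SPLIT


class LedgerAuditError(RuntimeError):
    """The bookkeeping identity failed — an internal inconsistency."""


@dataclass
class BranchLedger:
    """One row per species node (branch identified by its child node)."""

    table: pd.DataFrame  # indexed by species node label
    n_root_lineages: int = 1

    def row(self, species: str) -> pd.Series:
        return self.table.loc[species]

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t")

    def to_json_dict(self) -> dict:
        return {
            "n_root_lineages": self.n_root_lineages,
            "branches": {
                s: {k: int(v) for k, v in row.items() if k != "branch"}
                | {"branch": row["branch"]}
                for s, row in self.table.iterrows()
            },
        }


def _crossing_edges(rec: Reconciliation, s: str):
    """Yield (parent_label_or_None, child_label) gene edges crossing the
    speciation at species node ``s`` (None marks the virtual root edge)."""
    idx = rec.species_index
    M = rec.mapping
    genes = rec.dataset.gene_tree

    def predates(p_label: str | None) -> bool:
        if p_label is None:  # virtual parent above the gene root
            return idx.is_ancestor_or_equal(s, M[genes.root.label])
        mp = M[p_label]
        if mp == s:
            return rec.event_label.get(p_label) == DUPLICATION
        return idx.is_ancestor_or_equal(mp, s) and mp != s

    def reaches(c_label: str) -> bool:
        mc = M[c_label]
        if mc == s:
            node_is_internal = c_label in rec.event_label
            return (not node_is_internal
                    or rec.event_label[c_label] != DUPLICATION)
        return idx.is_ancestor_or_equal(s, mc)

    if predates(None) and reaches(genes.root.label):
        yield None, genes.root.label
    for node in genes.preorder():
        for c in node.children:
            if predates(node.label) and reaches(c.label):
                yield node.label, c.label


def ancestor_count(rec: Reconciliation, species_node: str) -> int:
    """Number of gene lineages crossing the speciation at an internal
    species node."""
    node = rec.species_index.nodes.get(species_node)
    if node is None:
        raise ValueError(f"unknown species node {species_node!r}")
    if node.is_leaf:
        raise ValueError(
            f"{species_node!r} is a species leaf; ancestor counts are "
            "defined at speciation (internal) nodes")
    return sum(1 for _ in _crossing_edges(rec, species_node))


def ledger(rec: Reconciliation, assignment: ArchAssignment,
           n_root_lineages: int = 1) -> BranchLedger:
    """Build the full per-branch ledger and audit its invariants.

    ``n_root_lineages`` is the number of gene lineages entering the root
    stem; inference always implies 1 (the gene-tree root subtends the
    whole family), but a ground-truth ledger from the simulator may start
    with more.
    """
    idx = rec.species_index
    state = assignment.state
    genes = rec.dataset.gene_tree
    species_nodes = [n.label for n in rec.dataset.species_tree.preorder()]

    cols = ["branch", "gains", "losses", "fusions", "fissions",
            "gains_FUSED", "gains_SPLIT", "losses_FUSED", "losses_SPLIT",
            "count", "count_FUSED", "count_SPLIT"]
    rows = {s: dict.fromkeys(cols, 0) for s in species_nodes}
    for s in species_nodes:
        rows[s]["branch"] = idx.branch_of(s)

    branch_to_species = {idx.branch_of(s): s for s in species_nodes}

    # gains: duplications dated to the branch entering their mapped node
    for g, ev in rec.event_label.items():
        if ev != DUPLICATION:
            continue
        s = rec.mapping[g]
        rows[s]["gains"] += 1
        rows[s][f"gains_{state[g]}"] += 1

    # losses: placed per skipped branch; class = state of the gene edge's
    # parent end (architecture changes happen on the branch entering the
    # child's mapped node, below every loss point of the edge)
    for node in genes.preorder():
        for c in node.children:
            for lost_branch in rec.loss_branches_by_edge.get(c.label, ()):  # noqa: B909
                s = branch_to_species[lost_branch]
                rows[s]["losses"] += 1
                rows[s][f"losses_{state[node.label]}"] += 1

    # stem losses: the ledger is conditioned on the family existing at the
    # species root (the virtual lineage above the gene root crosses every
    # speciation down to M(gene root)), so each branch it skips on the way
    # carries one implied loss even though duplication-loss parsimony does
    # not charge it to loss_count
    m_root = rec.mapping[genes.root.label]
    root_state = state[genes.root.label]
    stem_path = idx.path_down(rec.dataset.species_tree.root.label, m_root)
    for i in range(len(stem_path) - 1):
        lost = idx.sibling(stem_path[i + 1])
        rows[lost]["losses"] += 1
        rows[lost][f"losses_{root_state}"] += 1

    for e in assignment.events:
        s = branch_to_species[e.species_branch]
        rows[s][e.kind + "s"] += 1

    # crossing counts at every species node, class-wise
    for s in species_nodes:
        for p_label, c_label in _crossing_edges(rec, s):
            cls = (state[c_label] if rec.mapping[c_label] == s
                   else state[c_label] if p_label is None
                   else state[p_label])
            rows[s]["count"] += 1
            rows[s][f"count_{cls}"] += 1

    table = pd.DataFrame.from_dict(rows, orient="index").loc[species_nodes]
    led = BranchLedger(table=table, n_root_lineages=n_root_lineages)
    from collections import Counter
    audit(led, idx, extant=Counter(rec.dataset.species_of.values()))
    return led


def audit(led: BranchLedger, idx, extant=None) -> None:
    """Verify the bookkeeping identities; raise on any violation.

    ``idx`` is a :class:`~domrec.reconciliation.SpeciesIndex`; ``extant``
    optionally maps species leaf labels to observed gene counts for the
    terminal sanity check.
    """
    t = led.table
    # invert the root stem's own deltas to recover the lineages entering
    # the stem; must equal n_root_lineages and be non-negative class-wise
    entering = {FUSED: 0, SPLIT: 0}
    s = idx.root.label
    for cls in (FUSED, SPLIT):
        entering[cls] = int(t.loc[s, f"count_{cls}"]
                            - t.loc[s, f"gains_{cls}"]
                            + t.loc[s, f"losses_{cls}"])
    entering[FUSED] -= int(t.loc[s, "fusions"] - t.loc[s, "fissions"])
    entering[SPLIT] -= int(t.loc[s, "fissions"] - t.loc[s, "fusions"])
    if entering[FUSED] + entering[SPLIT] != led.n_root_lineages:
        raise LedgerAuditError(
            f"root stem: {entering} entering lineages inconsistent with "
            f"n_root_lineages={led.n_root_lineages}")
    if min(entering.values()) < 0:
        raise LedgerAuditError(f"negative entering class count: {entering}")

    for s in t.index:
        parent = idx.parent[s]
        if parent is None:
            continue
        lhs = int(t.loc[s, "count"])
        rhs = int(t.loc[parent, "count"] + t.loc[s, "gains"]
                  - t.loc[s, "losses"])
        if lhs != rhs:
            raise LedgerAuditError(
                f"branch into {s!r}: count {lhs} != parent {parent!r} count "
                f"+ gains - losses = {rhs}")
        for cls, gain_evt, loss_evt in ((FUSED, "fusions", "fissions"),
                                        (SPLIT, "fissions", "fusions")):
            lhs_c = int(t.loc[s, f"count_{cls}"])
            rhs_c = int(t.loc[parent, f"count_{cls}"]
                        + t.loc[s, f"gains_{cls}"]
                        - t.loc[s, f"losses_{cls}"]
                        + t.loc[s, gain_evt] - t.loc[s, loss_evt])
            if lhs_c != rhs_c:
                raise LedgerAuditError(
                    f"branch into {s!r}, class {cls}: count {lhs_c} != "
                    f"bookkeeping value {rhs_c}")
    if (t[["count", "count_FUSED", "count_SPLIT"]] < 0).any().any():
        raise LedgerAuditError("negative lineage count in ledger")

    # terminal sanity: leaf crossing counts must equal extant gene counts
    if extant is not None:
        for s in t.index:
            if (idx.nodes[s].is_leaf
                    and int(t.loc[s, "count"]) != extant.get(s, 0)):
                raise LedgerAuditError(
                    f"species {s!r}: ledger count {int(t.loc[s, 'count'])} "
                    f"!= extant gene count {extant.get(s, 0)}")


def expansion_ratio(count_a: int, count_ref: int,
                    genome_size_a: float, genome_size_ref: float) -> float:
    """Genome-size-normalized family expansion of lineage *a* over the
    reference lineage: ``(count_a / genome_size_a) / (count_ref /
    genome_size_ref)``.

    Genome sizes are user-supplied (any common unit — Mb, gene count —
    since the ratio is invariant under common rescaling).
    """
    if genome_size_a <= 0 or genome_size_ref <= 0:
        raise ValueError("genome sizes must be positive")
    if count_ref <= 0:
        raise ValueError("reference count must be positive")
    return (count_a / genome_size_a) / (count_ref / genome_size_ref)
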