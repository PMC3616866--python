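"""Ancestral protein-architecture inference by weighted two-state parsimony.

Every gene-tree node carries one of two architecture states: ``FUSED``
(the composite receptor kinase, S domain + transmembrane + kinase) or
``SPLIT`` (the kinase-only cytoplasmic protein).  Leaves are fixed at
their observed architecture; ancestral states are chosen to minimize the
total event cost on the reconciled tree.  A SPLIT→FUSED change along an
edge is a gene fusion, FUSED→SPLIT a gene fission; each is charged its own
cost on top of the duplication/speciation cost of the node at which it is
called, so an event-bearing node costs 2 at unit costs.

The optimization is exact dynamic programming over the two-state space
(Sankoff recursion with asymmetric transition costs), which attains the
minimum total cost by construction.  Ties are broken deterministically and
configurably: the root prefers SPLIT (the split component proteins are the
ancestral form), a tied non-root node inherits its parent's selected
state, and any residual tie resolves to SPLIT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .reconciliation import DUPLICATION, ROOT_STEM, Reconciliation
from .tree_io import FUSED, SPLIT, STATES


@dataclass(frozen=True)
class CostModel:
    """Per-event costs; all unit by default to avoid prior bias."""

    c_dup: float = 1.0
    c_loss: float = 1.0
    c_spec: float = 1.0
    c_fusion: float = 1.0
    c_fission: float = 1.0

    def __post_init__(self):
        for name in ("c_dup", "c_loss", "c_spec", "c_fusion", "c_fission"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"cost {name} must be finite and >= 0, got {v}")

    def transition(self, parent_state: str, child_state: str) -> float:
        if parent_state == child_state:
            return 0.0
        return self.c_fusion if child_state == FUSED else self.c_fission


@dataclass(frozen=True)
class TieBreak:
    """Deterministic tie-break policy for equal-cost state choices."""

    root_prior: str = SPLIT
    inherit_parent: bool = True
    fallback: str = SPLIT

    def __post_init__(self):
        if self.root_prior not in STATES or self.fallback not in STATES:
            raise ValueError("tie-break states must be FUSED or SPLIT")


@dataclass(frozen=True)
class ArchEvent:
    """A called fusion or fission, attached to the gene node that first
    shows the new architecture and dated to a species branch."""

    kind: str  # "fusion" | "fission"
    gene_node: str
    species_branch: str


@dataclass
class ArchAssignment:
    """Minimum-cost ancestral architecture assignment."""

    state: dict[str, str]
    total_cost: float
    events: list[ArchEvent] = field(default_factory=list)

    @property
    def fusion_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "fusion")

    @property
    def fission_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "fission")


def base_cost(rec: Reconciliation, cost_model: CostModel) -> float:
    """State-independent cost: duplications, speciations and losses."""
    spec_count = sum(1 for v in rec.event_label.values() if v != DUPLICATION)
    return (cost_model.c_dup * rec.dup_count
            + cost_model.c_spec * spec_count
            + cost_model.c_loss * rec.loss_count)


def infer_states(rec: Reconciliation,
                 cost_model: CostModel | None = None,
                 tie_break: TieBreak | None = None) -> ArchAssignment:
    """Exact minimum-cost ancestral states on the reconciled gene tree.

    Up pass: for each node and state, the minimum cost of its subtree
    given the node takes that state (edge transitions charged to the child
    end).  Down pass: root state by minimum (ties to the root prior), each
    child by minimum of transition + subtree cost (ties inherit the
    parent's chosen state, then the fallback state).
    """
    cost_model = cost_model or CostModel()
    tie_break = tie_break or TieBreak()
    tree = rec.dataset.gene_tree
    state_of = rec.dataset.state_of

    sub: dict[str, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            st = state_of.get(node.label)
            if st is None:
                raise ValueError(f"leaf {node.label!r} has no architecture state")
            sub[node.label] = {s: (0.0 if s == st else math.inf) for s in STATES}
        else:
            table = {}
            for s in STATES:
                total = 0.0
                for c in node.children:
                    total += min(cost_model.transition(s, t) + sub[c.label][t]
                                 for t in STATES)
                table[s] = total
            sub[node.label] = table

    def argmin_states(costs: dict[str, float]) -> list[str]:
        m = min(costs.values())
        return [s for s in STATES if costs[s] == m]

    chosen: dict[str, str] = {}
    root = tree.root
    best = argmin_states(sub[root.label])
    chosen[root.label] = (tie_break.root_prior if tie_break.root_prior in best
                          else best[0])
    for node in tree.preorder():
        if node.is_leaf:
            continue
        ps = chosen[node.label]
        for c in node.children:
            cand = {t: cost_model.transition(ps, t) + sub[c.label][t]
                    for t in STATES}
            best = argmin_states(cand)
            if len(best) == 1:
                chosen[c.label] = best[0]
            elif tie_break.inherit_parent and ps in best:
                chosen[c.label] = ps
            else:
                chosen[c.label] = (tie_break.fallback if tie_break.fallback
                                   in best else best[0])

    total = base_cost(rec, cost_model) + min(sub[root.label].values())
    assignment = ArchAssignment(state=chosen, total_cost=total)
    assignment.events = call_events(assignment, rec)
    return assignment


def call_events(assignment: ArchAssignment,
                rec: Reconciliation) -> list[ArchEvent]:
    """Collect and date every state change along the gene tree.

    Each SPLIT→FUSED edge yields a fusion at the child node (the MRCA that
    first shows the composite architecture), dated to the species branch
    entering the child's mapped species node; FUSED→SPLIT yields a dated
    fission.  Events are sorted by species-tree preorder of the dated
    branch, then gene node label.
    """
    idx = rec.species_index
    events: list[ArchEvent] = []
    state = assignment.state
    for node in rec.dataset.gene_tree.preorder():
        for c in node.children:
            ps, cs = state[node.label], state[c.label]
            if ps == cs:
                continue
            kind = "fusion" if cs == FUSED else "fission"
            branch = idx.branch_of(rec.mapping[c.label])
            events.append(ArchEvent(kind, c.label, branch))

    preorder_rank = {ROOT_STEM: -1}
    for i, label in enumerate(n.label for n in
                              rec.dataset.species_tree.preorder()):
        preorder_rank[label] = i
    events.sort(key=lambda e: (preorder_rank[e.species_branch], e.gene_node))
    return events


def assignment_cost(assignment: ArchAssignment, rec: Reconciliation,
                    cost_model: CostModel | None = None) -> float:
    """Recompute the total cost of an assignment from first principles.

    Independent auditor for :func:`infer_states`: walks every node and
    edge, charging duplication/speciation, loss, and transition costs.
    """
    cost_model = cost_model or CostModel()
    state = assignment.state
    for leaf, st in rec.dataset.state_of.items():
        if state.get(leaf) != st:
            raise ValueError(
                f"assignment state {state.get(leaf)!r} at leaf {leaf!r} "
                f"contradicts its annotation {st!r}")
    total = base_cost(rec, cost_model)
    for node in rec.dataset.gene_tree.preorder():
        for c in node.children:
            total += cost_model.transition(state[node.label], state[c.label])
    return total


def with_root_prior(tie_break: TieBreak, prior: str) -> TieBreak:
    """Convenience: same policy with a different root prior."""
    return replace(tie_break, root_prior=prior)


def to_report(assignment: ArchAssignment, rec: Reconciliation) -> dict:
    """JSON-serializable architecture report."""
    return {
        "state": dict(sorted(assignment.state.items())),
        "total_cost": assignment.total_cost,
        "fusion_count": assignment.fusion_count,
        "fission_count": assignment.fission_count,
        "events": [
            {"kind": e.kind, "gene_node": e.gene_node,
             "species_branch": e.species_branch}
            for e in assignment.events
        ],
    }


def annotated_newick(assignment: ArchAssignment, rec: Reconciliation) -> str:
    """Gene tree with internal labels suffixed by the inferred state."""
    from .tree_io import write_newick

    tree = rec.dataset.gene_tree.copy()
    for n in tree.preorder():
        if not n.is_leaf:
            n.label = f"{n.label}_{assignment.state[n.label]}"
    return write_newick(tree)
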