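"""Birth–death gene-family simulation along a dated species tree.

Each gene lineage evolves independently down the species tree by a
continuous-time Markov process: duplication copies the lineage in place,
loss terminates it, fusion flips a SPLIT lineage to FUSED, fission flips
FUSED back to SPLIT; at every speciation each surviving lineage enters
both daughter branches.  Waiting times are exponential (Gillespie), so
simultaneous events have probability zero.  The returned gene tree
contains surviving lineages only, but every event — including losses
inside fully extinct subtrees — is retained in the ground-truth log,
together with a per-branch ledger built from the actual lineage counts,
which is what makes end-to-end tests of reconciliation, architecture
inference and bookkeeping possible without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .accounting import BranchLedger, audit
from .reconciliation import SpeciesIndex
from .tree_io import (FUSED, SPLIT, STATES, LeafAnnotation, Node, PhyloTree,
                      write_annotations, write_newick)

_RATE_KEYS = ("rate_dup", "rate_loss", "rate_fusion", "rate_fission")


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; the seed fully determines the output.

    Rates are per lineage per unit branch length.  ``rate_fusion``
    applies only to SPLIT lineages, ``rate_fission`` only to FUSED ones.
    ``rate_overrides`` maps a species-branch id (child-node label) to a
    dict of rate-name -> value, letting tests plant an event on a chosen
    branch via a locally elevated rate.
    """

    species_tree: PhyloTree
    rate_dup: float = 0.0
    rate_loss: float = 0.0
    rate_fusion: float = 0.0
    rate_fission: float = 0.0
    n_root_lineages: int = 1
    root_state: str = SPLIT
    seed: int = 0
    rate_overrides: dict | None = None

    def __post_init__(self):
        for k in _RATE_KEYS:
            v = getattr(self, k)
            if not (v >= 0 and np.isfinite(v)):
                raise ValueError(f"{k} must be finite and >= 0, got {v}")
        if self.n_root_lineages < 1:
            raise ValueError("n_root_lineages must be >= 1")
        if self.root_state not in STATES:
            raise ValueError("root_state must be FUSED or SPLIT")

    def rates_on(self, branch: str) -> dict[str, float]:
        base = {k: getattr(self, k) for k in _RATE_KEYS}
        if self.rate_overrides and branch in self.rate_overrides:
            base.update(self.rate_overrides[branch])
        return base


@dataclass(frozen=True)
class TruthEvent:
    kind: str           # duplication | loss | fusion | fission
    species_branch: str  # child-node label of the branch it occurred on
    time: float          # absolute time since the species root
    state: str           # lineage architecture when the event fired


@dataclass
class SimulatedFamily:
    """A simulated family with full ground truth.

    ``gene_tree`` is None when every lineage went extinct (flagged, not
    raised).
    """

    params: SimParams
    gene_tree: Optional[PhyloTree]
    leaf_annotations: list[LeafAnnotation]
    truth: list[TruthEvent]
    true_ledger: BranchLedger

    @property
    def extinct(self) -> bool:
        return self.gene_tree is None

    def truth_counts(self) -> dict[str, int]:
        out = {"duplication": 0, "loss": 0, "fusion": 0, "fission": 0}
        for e in self.truth:
            out[e.kind] += 1
        return out

    def truth_log_tsv(self) -> str:
        rows = ["kind\tspecies_branch\ttime"]
        rows += [f"{e.kind}\t{e.species_branch}\t{e.time:.6f}"
                 for e in self.truth]
        return "\n".join(rows) + "\n"

    def annotations_tsv(self) -> str:
        return write_annotations(self.leaf_annotations)

    def gene_tree_newick(self) -> str:
        if self.gene_tree is None:
            raise ValueError("family went extinct; no gene tree")
        return write_newick(self.gene_tree)


_LEDGER_COLS = ["branch", "gains", "losses", "fusions", "fissions",
                "gains_FUSED", "gains_SPLIT", "losses_FUSED", "losses_SPLIT",
                "count", "count_FUSED", "count_SPLIT"]


class _Sim:
    def __init__(self, params: SimParams):
        self.p = params
        self.idx = SpeciesIndex.build(params.species_tree.root)
        self.rng = np.random.default_rng(params.seed)
        self.events: list[TruthEvent] = []
        self.leaf_counter = 0
        self.annotations: list[LeafAnnotation] = []
        nodes = [n.label for n in params.species_tree.preorder()]
        self.rows = {s: dict.fromkeys(_LEDGER_COLS, 0) for s in nodes}
        for s in nodes:
            self.rows[s]["branch"] = self.idx.branch_of(s)
        self.node_order = nodes

    def run(self) -> SimulatedFamily:
        root = self.p.species_tree.root
        survivors: list[Node] = []
        for _ in range(self.p.n_root_lineages):
            sub = self._speciate(root, self.p.root_state, 0.0)
            if sub is not None:
                survivors.append(sub)
        gene_tree = None
        if survivors:
            joined = survivors[0]
            for nxt in survivors[1:]:
                joined = Node(children=[joined, nxt])
            gene_tree = PhyloTree(joined)
        table = pd.DataFrame.from_dict(self.rows, orient="index")
        table = table.loc[self.node_order]
        led = BranchLedger(table=table,
                           n_root_lineages=self.p.n_root_lineages)
        extant: dict[str, int] = {}
        for a in self.annotations:
            extant[a.species_id] = extant.get(a.species_id, 0) + 1
        audit(led, self.idx, extant=extant)
        return SimulatedFamily(self.p, gene_tree, self.annotations,
                               self.events, led)

    # -- internals ---------------------------------------------------------

    def _speciate(self, snode: Node, state: str, t_now: float
                  ) -> Optional[Node]:
        """A lineage arriving at species node ``snode``: count the
        crossing, then enter both daughters (or terminate at a leaf)."""
        s = snode.label
        self.rows[s]["count"] += 1
        self.rows[s][f"count_{state}"] += 1
        if snode.is_leaf:
            self.leaf_counter += 1
            gid = f"g{self.leaf_counter}"
            self.annotations.append(LeafAnnotation(gid, s, state))
            return Node(label=gid)
        children = [self._evolve_branch(c, state, t_now)
                    for c in snode.children]
        alive = [c for c in children if c is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        return Node(children=alive)

    def _evolve_branch(self, snode: Node, state: str, t_start: float
                       ) -> Optional[Node]:
        """Evolve one lineage along the whole branch entering ``snode``."""
        length = snode.branch_length or 0.0
        return self._evolve_tail(snode, state, t_start, length,
                                 self.p.rates_on(snode.label))

    def _evolve_tail(self, snode: Node, state: str, t_now: float,
                     remaining: float, rates: dict) -> Optional[Node]:
        """Evolve a lineage over the remaining part of a branch (the whole
        branch, or the tail below a duplication point)."""
        while True:
            change = rates["rate_fusion"] if state == SPLIT \
                else rates["rate_fission"]
            total = rates["rate_dup"] + rates["rate_loss"] + change
            if total <= 0:
                break
            wait = self.rng.exponential(1.0 / total)
            if wait >= remaining:
                break
            remaining -= wait
            t_now += wait
            branch = snode.label
            u = self.rng.random() * total
            if u < rates["rate_dup"]:
                self.events.append(TruthEvent("duplication", branch,
                                              t_now, state))
                self.rows[branch]["gains"] += 1
                self.rows[branch][f"gains_{state}"] += 1
                a = self._evolve_tail(snode, state, t_now, remaining, rates)
                b = self._evolve_tail(snode, state, t_now, remaining, rates)
                if a is None:
                    return b
                if b is None:
                    return a
                return Node(children=[a, b])
            if u < rates["rate_dup"] + rates["rate_loss"]:
                self.events.append(TruthEvent("loss", branch, t_now, state))
                self.rows[branch]["losses"] += 1
                self.rows[branch][f"losses_{state}"] += 1
                return None
            kind = "fusion" if state == SPLIT else "fission"
            self.events.append(TruthEvent(kind, branch, t_now, state))
            self.rows[branch][kind + "s"] += 1
            state = FUSED if state == SPLIT else SPLIT
        end_time = t_now + remaining
        return self._speciate(snode, state, end_time)


def simulate(params: SimParams) -> SimulatedFamily:
    """Run one family simulation; fully reproducible from the seed."""
    return _Sim(params).run()


def recovery_report(family: SimulatedFamily, rec, assignment) -> dict:
    """Compare inferred events against the ground-truth log.

    An inferred event matches a true one when kind and species branch
    agree (multiset matching per branch).  Precision/recall are None
    (reported as JSON null) when their denominator is zero.  Count errors
    are inferred minus true totals (non-positive whenever the parsimony
    under-count bound holds).
    """
    from collections import Counter

    true_c: dict[str, Counter] = {k: Counter() for k in
                                  ("duplication", "loss", "fusion", "fission")}
    for e in family.truth:
        true_c[e.kind][e.species_branch] += 1

    inf_c: dict[str, Counter] = {k: Counter() for k in true_c}
    for g, ev in rec.event_label.items():
        if ev == "duplication":
            inf_c["duplication"][rec.species_index.branch_of(rec.mapping[g])] += 1
    for branch, n in rec.losses.items():
        inf_c["loss"][branch] += n
    for e in assignment.events:
        inf_c[e.kind][e.species_branch] += 1

    def pr(kind: str):
        t, i = true_c[kind], inf_c[kind]
        matched = sum(min(t[b], i[b]) for b in set(t) | set(i))
        n_true, n_inf = sum(t.values()), sum(i.values())
        precision = matched / n_inf if n_inf else None
        recall = matched / n_true if n_true else None
        return precision, recall, n_true, n_inf

    fus_p, fus_r, _, _ = pr("fusion")
    fis_p, fis_r, _, _ = pr("fission")
    return {
        "fusion_precision": fus_p,
        "fusion_recall": fus_r,
        "fission_precision": fis_p,
        "fission_recall": fis_r,
        "dup_count_error": sum(inf_c["duplication"].values())
        - sum(true_c["duplication"].values()),
        "loss_count_error": sum(inf_c["loss"].values())
        - sum(true_c["loss"].values()),
        "true_counts": {k: sum(c.values()) for k, c in true_c.items()},
        "inferred_counts": {k: sum(c.values()) for k, c in inf_c.items()},
        "matched_fusions": sum(min(true_c["fusion"][b], inf_c["fusion"][b])
                               for b in set(true_c["fusion"])
                               | set(inf_c["fusion"])),
    }
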