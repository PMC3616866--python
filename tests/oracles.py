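"""Independent brute-force oracles and random instance generators.

Everything here recomputes quantities by exhaustive enumeration, entirely
separately from the package's dynamic programming, so the tests compare
two independent routes to the same optimum.
"""

from __future__ import annotations

import itertools

import numpy as np

from domrec import FUSED, SPLIT, LeafAnnotation, Node, PhyloTree, SpeciesIndex


# ---------------------------------------------------------------------------
# random instances


def random_bifurcating_tree(rng: np.random.Generator, labels: list[str]
                            ) -> PhyloTree:
    """Random topology by repeated random joins (uniform-ish shapes)."""
    nodes = [Node(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    return PhyloTree(nodes[0])


def random_instance(rng: np.random.Generator, max_leaves: int = 8,
                    max_species: int = 4):
    """A random species tree, gene tree and annotations."""
    n_species = int(rng.integers(2, max_species + 1))
    species = [chr(ord("A") + i) for i in range(n_species)]
    sp_tree = random_bifurcating_tree(rng, species)
    n_leaves = int(rng.integers(2, max_leaves + 1))
    genes = [f"g{i}" for i in range(n_leaves)]
    gene_tree = random_bifurcating_tree(rng, genes)
    ann = [LeafAnnotation(g, species[int(rng.integers(n_species))],
                          FUSED if rng.random() < 0.5 else SPLIT)
           for g in genes]
    return gene_tree, sp_tree, ann


# ---------------------------------------------------------------------------
# duplication-loss reconciliation oracle


def brute_force_dl_minimum(dataset) -> int:
    """Minimum dup+loss over every valid reconciliation map.

    A map is valid when each internal gene node is assigned a species
    node ancestral-or-equal to both children's assignments; a node is a
    speciation exactly when its children's images lie under distinct
    children of its own image, a duplication otherwise; each gene edge
    (v, c) implies dist(M(v), M(c)) losses if v is a duplication and one
    fewer if v is a speciation.
    """
    idx = SpeciesIndex.build(dataset.species_tree.root)

    def ancestors_up(label: str) -> list[str]:
        out = [label]
        while idx.parent[out[-1]] is not None:
            out.append(idx.parent[out[-1]])
        return out

    gnodes = list(dataset.gene_tree.postorder())
    internal = [n for n in gnodes if not n.is_leaf]
    base = {n.label: dataset.species_of[n.label]
            for n in gnodes if n.is_leaf}

    best = [np.inf]

    def cost_of(assign: dict[str, str]) -> float:
        dups = losses = 0
        for v in internal:
            m = assign[v.label]
            l, r = (assign[c.label] for c in v.children)
            is_spec = (idx.lca(l, r) == m and l != m and r != m)
            if not is_spec:
                dups += 1
            for c in v.children:
                d = idx.path_length(m, assign[c.label])
                losses += d if not is_spec else d - 1
        return dups + losses

    def rec(i: int, assign: dict[str, str]) -> None:
        if i == len(internal):
            best[0] = min(best[0], cost_of(assign))
            return
        v = internal[i]
        l, r = (assign[c.label] for c in v.children)
        for m in ancestors_up(idx.lca(l, r)):
            assign[v.label] = m
            rec(i + 1, assign)
        del assign[v.label]

    # assign children before parents: internal list is postorder already
    rec(0, dict(base))
    return int(best[0])


# ---------------------------------------------------------------------------
# two-state architecture parsimony oracle


def brute_force_state_minimum(rec, c_fusion: float, c_fission: float
                              ) -> float:
    """Minimum state-dependent (transition) cost over all 2^n internal
    assignments, by vectorized enumeration; excludes the constant
    duplication/speciation/loss base cost."""
    tree = rec.dataset.gene_tree
    internal = [n for n in tree.preorder() if not n.is_leaf]
    index = {n.label: i for i, n in enumerate(internal)}
    n = len(internal)
    assert n <= 20
    codes = np.arange(2 ** n, dtype=np.int64)
    # bit 1 = FUSED
    states = (codes[:, None] >> np.arange(n)) & 1

    cost = np.zeros(2 ** n)
    for v in internal:
        pv = states[:, index[v.label]]
        for c in v.children:
            if c.is_leaf:
                cv = np.full_like(pv,
                                  1 if rec.dataset.state_of[c.label] == FUSED
                                  else 0)
            else:
                cv = states[:, index[c.label]]
            cost += np.where(pv == cv, 0.0,
                             np.where(cv == 1, c_fusion, c_fission))
    return float(cost.min())


def count_events_of_assignment(rec, state: dict[str, str]) -> tuple[int, int]:
    """(fusions, fissions) implied by an explicit state map."""
    fus = fis = 0
    for v in rec.dataset.gene_tree.preorder():
        for c in v.children:
            if state[v.label] != state[c.label]:
                if state[c.label] == FUSED:
                    fus += 1
                else:
                    fis += 1
    return fus, fis
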