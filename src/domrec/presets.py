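"""Built-in study systems: the five-land-plant species tree, a coarse
S-domain receptor-like kinase (SRLK) family tree with the reported group
structure, and reference simulation regimes.

The SRLK family is the motivating system: composite receptor kinases
(FUSED: extracellular S domain + transmembrane + kinase) coexist with
kinase-only cytoplasmic relatives (SPLIT, the SRLCKs) across land plants.
The coarse family tree encodes the observed grouping — a basal stratum of
17 split-kinase lineages, one large clade of 390 fused receptor kinases
spanning all five species, and a split clade of 79 cytoplasmic kinases
containing a nested fused cherry of two moss genes — without any sequence
data, which is enough to exercise event inference and dating end to end.
"""

from __future__ import annotations

from .simulate import SimParams
from .tree_io import (FUSED, SPLIT, LeafAnnotation, Node, PhyloTree,
                      read_newick)

SPECIES = ("Populus_trichocarpa", "Arabidopsis_thaliana", "Oryza_sativa",
           "Selaginella_moellendorffii", "Physcomitrella_patens")
MOSS = "Physcomitrella_patens"

#: Rooted five-species land-plant tree; internal labels name the clades.
SPECIES_NEWICK = (
    "((((Populus_trichocarpa,Arabidopsis_thaliana)rosids,"
    "Oryza_sativa)angiosperms,Selaginella_moellendorffii)vascular_plants,"
    "Physcomitrella_patens)land_plants;"
)

#: Same topology with branch lengths in millions of years, from commonly
#: cited divergence ages (moss split 450 My, lycophyte split 420 My,
#: monocot/dicot split 150 My, poplar/Arabidopsis split 100 My).
SPECIES_NEWICK_DATED = (
    "((((Populus_trichocarpa:100,Arabidopsis_thaliana:100)rosids:50,"
    "Oryza_sativa:150)angiosperms:270,"
    "Selaginella_moellendorffii:420)vascular_plants:30,"
    "Physcomitrella_patens:450)land_plants;"
)


def species_tree(dated: bool = False) -> PhyloTree:
    return read_newick(SPECIES_NEWICK_DATED if dated else SPECIES_NEWICK)


def unit_species_tree() -> PhyloTree:
    """The five-species topology with every branch length 1 — the neutral
    time scale used by the simulation test regimes."""
    tree = species_tree()
    for n in tree.preorder():
        if n.parent is not None:
            n.branch_length = 1.0
    return tree


def _ladder(leaves: list[Node]) -> Node:
    """Right-nested caterpillar: (l1,(l2,(...,(ln-1,ln))))."""
    node = leaves[-1]
    for leaf in reversed(leaves[:-1]):
        node = Node(children=[leaf, node])
    return node


def coarse_srlk_family(n_basal: int = 17, n_fused: int = 390,
                       n_srlck: int = 79, n_moss_fused: int = 2,
                       ) -> tuple[PhyloTree, list[LeafAnnotation]]:
    """Coarse SRLK/SRLCK gene tree with the reported group structure.

    Topology: a basal ladder of ``n_basal`` SPLIT lineages subtending a
    sister pair of clades — one of ``n_fused`` FUSED receptor kinases
    (spanning all five species, moss included), one of ``n_srlck`` SPLIT
    cytoplasmic kinases with a nested FUSED cherry of ``n_moss_fused``
    moss genes.  Species are assigned cyclically within each group, which
    pins the fused clade's ancestor to the species root and the moss
    cherry's ancestor to the moss terminal branch.
    """
    annotations: list[LeafAnnotation] = []

    def make_leaves(prefix: str, n: int, state: str,
                    species_cycle: tuple[str, ...]) -> list[Node]:
        out = []
        for i in range(n):
            gid = f"{prefix}{i + 1}"
            sp = species_cycle[i % len(species_cycle)]
            annotations.append(LeafAnnotation(gid, sp, state))
            out.append(Node(label=gid))
        return out

    basal = make_leaves("basal", n_basal, SPLIT, SPECIES)
    fused = make_leaves("srlk", n_fused, FUSED, SPECIES)
    # the cytoplasmic-kinase clade is restricted to non-moss species so
    # that the nested moss cherry is the clade's only moss content
    srlck = make_leaves("srlck", n_srlck, SPLIT,
                        tuple(s for s in SPECIES if s != MOSS))
    moss_cherry = Node(children=make_leaves("moss_srlk", n_moss_fused,
                                            FUSED, (MOSS,)))

    srlck_clade_members = srlck[:1] + [moss_cherry] + srlck[1:]
    core = Node(children=[_ladder(fused), _ladder(srlck_clade_members)])
    root = _ladder(basal + [core])
    return PhyloTree(root), annotations


def low_rate_params(seed: int, planted_fusion_branch: str | None = None,
                    ) -> SimParams:
    """The low-event-rate simulation regime used by the recovery and
    bookkeeping studies: expected total events per lineage per branch
    below 0.1 on the unit-length five-species tree.

    With ``planted_fusion_branch`` set, loss and fission are switched off
    and a near-certain fusion is planted on the named species branch via
    a locally elevated rate.
    """
    if planted_fusion_branch is not None:
        return SimParams(
            species_tree=unit_species_tree(),
            rate_dup=0.0, rate_loss=0.0, rate_fusion=0.0, rate_fission=0.0,
            n_root_lineages=1, root_state=SPLIT, seed=seed,
            rate_overrides={planted_fusion_branch: {"rate_fusion": 200.0}},
        )
    return SimParams(
        species_tree=unit_species_tree(),
        rate_dup=0.03, rate_loss=0.02, rate_fusion=0.03, rate_fission=0.01,
        n_root_lineages=1, root_state=SPLIT, seed=seed,
    )


def demo_params(seed: int) -> SimParams:
    """Demo preset on the dated five-species tree (time in My): rates
    tuned so a typical draw shows a large FUSED clade and rare fissions.
    For demonstrations only, never for acceptance numbers."""
    return SimParams(
        species_tree=species_tree(dated=True),
        rate_dup=0.004, rate_loss=0.002,
        rate_fusion=0.0015, rate_fission=0.0001,
        n_root_lineages=2, root_state=SPLIT, seed=seed,
    )
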