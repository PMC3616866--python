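import numpy as np
import pytest

import domrec
from domrec import presets


@pytest.fixture()
def two_species():
    """Species tree (A,B) with unit branch lengths."""
    return domrec.read_newick("(A:1,B:1);")


@pytest.fixture()
def coarse_family():
    """Coarse SRLK/SRLCK family bound to the five-species tree."""
    gene_tree, annotations = presets.coarse_srlk_family()
    return domrec.bind(gene_tree, presets.species_tree(), annotations)


def make_bound(gene_newick: str, species_newick: str,
               annotations: dict[str, tuple[str, str]]):
    """Bind a toy instance; annotations map gene -> (species, state)."""
    ann = [domrec.LeafAnnotation(g, sp, st)
           for g, (sp, st) in annotations.items()]
    return domrec.bind(domrec.read_newick(gene_newick),
                       domrec.read_newick(species_newick), ann)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
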