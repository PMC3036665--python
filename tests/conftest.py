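import numpy as np
import pytest

from esudelim.matrices import LabelledMatrix
from esudelim.seqmodels import Alignment, SubstitutionModel
from esudelim import datasets


@pytest.fixture
def rng():
    return np.random.default_rng(20110209)


@pytest.fixture
def jc():
    return SubstitutionModel.jc()


@pytest.fixture
def table1():
    """COI unit-level divergence fixture, ESU labels harmonised."""
    return datasets.table1_coi(esu_labels=True)


@pytest.fixture
def table2():
    return datasets.table2_28s()


@pytest.fixture
def morph46():
    return datasets.table3_morphology()


def random_alignment(rng, n=4, length=60, labels=None) -> Alignment:
    labels = labels or [f"t{i}" for i in range(n)]
    seqs = ["".join(rng.choice(list("ACGT"), length)) for _ in labels]
    return Alignment(labels, seqs)


def random_additive_tree(rng, n):
    """Random unrooted topology with strictly positive branch lengths;
    returns (newick, labels, patristic LabelledMatrix)."""
    import dendropy
    labels = [f"t{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=taxa, rng=_PyRandom(rng))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    vals = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                vals[i, j] = vals[j, i] = pdm.patristic_distance(a, b)
    newick = tree.as_string(schema="newick", unquoted_underscores=True)
    dm = LabelledMatrix([t.label for t in taxa], vals)
    return newick, dm


class _PyRandom:
    """Adapter: dendropy wants a stdlib-like Random."""

    def __init__(self, rng):
        self._rng = rng

    def __getattr__(self, name):
        import random
        r = random.Random(int(self._rng.integers(2**31)))
        return getattr(r, name)
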