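import dendropy
import numpy as np
import pytest

from lsepipe import gy94
from lsepipe import simulate as sim
from lsepipe import sitemodels as sm
from lsepipe.trees import parse_newick


@pytest.fixture(scope="session")
def species_tree():
    return sim.default_species_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def six_taxon_tree():
    return parse_newick(
        "((A_1:0.3,B_1:0.3):0.2,(C_1:0.2,D_1:0.2):0.3,(E_1:0.4,F_1:0.4):0.1);"
    )


@pytest.fixture(scope="session")
def small_alignment(six_taxon_tree):
    """500-codon alignment simulated under M1a on the six-taxon tree."""
    rng = np.random.default_rng(7)
    spec = sm.m1a(0.7, 0.2)
    params = gy94.Gy94Params(kappa=2.0)
    aln, truth = sim.simulate_codon_alignment(six_taxon_tree, spec, params, 500, rng)
    return aln, truth


def random_rooted_tree(
    rng: np.random.Generator, leaf_labels: list[str]
) -> dendropy.Tree:
    """Random rooted binary topology by sequential joins, unit-ish lengths."""
    ns = dendropy.TaxonNamespace()
    nodes = []
    for lab in leaf_labels:
        nd = dendropy.Node()
        nd.taxon = ns.new_taxon(lab)
        nd.edge.length = float(rng.uniform(0.05, 0.5))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 0.5))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree
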