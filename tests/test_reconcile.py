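import numpy as np
import pytest
from scipy.stats import chisquare

from lsepipe import reconcile as rec
from lsepipe import simulate as sim
from lsepipe.qc import CodonAlignment
from lsepipe.trees import parse_newick, species_of_label
from .conftest import random_rooted_tree

SPECIES4 = parse_newick("((W:1,X:1):1,(Y:1,Z:1):1);")


# ---------------------------------------------------------------- oracles --
def _leaf_species_sets(species_tree):
    """species-tree node -> frozenset of descendant species labels."""
    out = {}
    for nd in species_tree.postorder_node_iter():
        if nd.is_leaf():
            out[id(nd)] = frozenset([nd.taxon.label])
        else:
            s = frozenset()
            for ch in nd.child_nodes():
                s |= out[id(ch)]
            out[id(nd)] = s
    return out


def brute_force_labels(gene_tree, species_tree):
    """Independent per-node LCA recomputation via smallest covering node."""
    cover = _leaf_species_sets(species_tree)
    nodes = list(species_tree.postorder_node_iter())

    def lca(species_set):
        candidates = [nd for nd in nodes if species_set <= cover[id(nd)]]
        return min(candidates, key=lambda nd: len(cover[id(nd)]))

    labels = {}
    below = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([species_of_label(nd.taxon.label)])
            continue
        s = frozenset()
        for ch in nd.child_nodes():
            s |= below[id(ch)]
        below[id(nd)] = s
        m = lca(s)
        dup = any(lca(below[id(ch)]) is m for ch in nd.child_nodes())
        labels[id(nd)] = "duplication" if dup else "speciation"
    return labels


def brute_force_up(gene_tree, min_size):
    """All maximal single-species subtrees, by exhaustive node enumeration."""
    found = []
    for nd in gene_tree.preorder_node_iter():
        leaves = [lf.taxon.label for lf in nd.leaf_iter()]
        species = {species_of_label(x) for x in leaves}
        if len(species) != 1:
            continue
        parent = nd.parent_node
        if parent is not None:
            pl = {species_of_label(lf.taxon.label) for lf in parent.leaf_iter()}
            if len(pl) == 1:
                continue  # not maximal
        if len(leaves) >= min_size:
            found.append(frozenset(leaves))
    return set(found)


def brute_force_so(gene_tree, min_size):
    def all_spec(nd):
        return all(
            getattr(x, rec.EVENT_ATTR) == "speciation"
            for x in nd.preorder_internal_node_iter()
        )

    found = []
    for nd in gene_tree.preorder_node_iter():
        if not all_spec(nd):
            continue
        parent = nd.parent_node
        if parent is not None and all_spec(parent):
            continue
        leaves = [lf.taxon.label for lf in nd.leaf_iter()]
        if len(leaves) >= min_size:
            found.append(frozenset(leaves))
    return set(found)


def _random_gene_tree(seed, n_leaves, species):
    rng = np.random.default_rng(seed)
    labels = [
        f"{species[rng.integers(len(species))]}_g{i}" for i in range(n_leaves)
    ]
    return random_rooted_tree(rng, labels)


# ------------------------------------------------------------------ tests --
def test_congruent_tree_has_zero_duplications(species_tree):
    newick = sim.to_newick(species_tree)
    for sp in [lf.taxon.label for lf in species_tree.leaf_node_iter()]:
        newick = newick.replace(sp + ":", sp + "_g1:")
    gene = parse_newick(newick)
    rec.reconcile_label(gene, species_tree)
    assert rec.duplication_count(gene) == 0


def test_single_species_burst_all_duplications():
    # six leaves of one species: every internal node is a duplication
    gene = parse_newick(
        "(((((W_1:1,W_2:1):1,W_3:1):1,W_4:1):1,W_5:1):1,W_6:1);"
    )
    rec.reconcile_label(gene, SPECIES4)
    assert rec.duplication_count(gene) == 5
    ups = rec.extract_up_clusters(gene, min_size=6)
    assert len(ups) == 1 and ups[0].size == 6


def test_workflow_figure_topology():
    # single-species burst clade next to a clean speciation clade
    gene = parse_newick(
        "((((W_a:1,X_a:1):1,(Y_a:1,Z_a:1):1):1,"
        "(((((W_1:1,W_2:1):1,W_3:1):1,W_4:1):1,W_5:1):1,W_6:1):1):1,"
        "(W_b:1,X_b:1):1);"
    )
    rec.reconcile_label(gene, SPECIES4)
    ups = rec.extract_up_clusters(gene, min_size=4, tree_id="t")
    sos = rec.extract_so_clusters(gene, min_size=4, tree_id="t")
    assert [u.size for u in ups] == [6]
    assert [s.size for s in sos] == [4]  # {W_a, X_a, Y_a, Z_a}; (W_b, X_b) too small
    cats = rec.partition_categories({"t": ups + sos})
    assert {c.category for c in cats} == {"UP1", "SO1"}


@pytest.mark.parametrize("seed", range(12))
def test_labels_match_brute_force_oracle(seed):
    gene = _random_gene_tree(seed, 8, ["W", "X", "Y", "Z"])
    rec.reconcile_label(gene, SPECIES4)
    expected = brute_force_labels(gene, SPECIES4)
    for nd in gene.preorder_internal_node_iter():
        assert getattr(nd, rec.EVENT_ATTR) == expected[id(nd)]


@pytest.mark.parametrize("seed", range(15))
@pytest.mark.parametrize("min_size", [2, 3])
def test_extraction_matches_enumeration(seed, min_size):
    n = int(np.random.default_rng(seed).integers(4, 13))
    gene = _random_gene_tree(seed + 100, n, ["W", "X", "Y", "Z"])
    rec.reconcile_label(gene, SPECIES4)
    ups = rec.extract_up_clusters(gene, min_size=min_size)
    sos = rec.extract_so_clusters(gene, min_size=min_size)
    assert {frozenset(c.members) for c in ups} == brute_force_up(gene, min_size)
    assert {frozenset(c.members) for c in sos} == brute_force_so(gene, min_size)
    # invariants
    for c in ups:
        assert len(set(c.species)) == 1
    for c in sos:
        assert len(set(c.species)) == len(c.species)
        assert c.size <= 4
    # same-type clusters are leaf-disjoint
    for group in (ups, sos):
        seen = set()
        for c in group:
            assert not (seen & set(c.members))
            seen |= set(c.members)


def test_unknown_species_raises():
    gene = parse_newick("((W_1:1,Q_1:1):1,X_1:1);")
    with pytest.raises(rec.ReconciliationError, match="Q_1"):
        rec.reconcile_label(gene, SPECIES4)


def test_loss_free_simulation_recovers_truth(species_tree):
    cfg = sim.SimulationConfig(seed=5, loss_rate=0.0)
    rng = np.random.default_rng(5)
    for k in range(10):
        tree, truth = sim.simulate_gene_family(species_tree, cfg, rng, f"f{k}")
        rec.reconcile_label(tree, species_tree)
        inferred = {
            nd.label: getattr(nd, rec.EVENT_ATTR)
            for nd in tree.preorder_internal_node_iter()
        }
        assert inferred == truth.events
        got_up = {frozenset(c.members) for c in rec.extract_up_clusters(tree, 2, "f")}
        assert got_up == {frozenset(m) for m in truth.up_clusters}
        got_so = {frozenset(c.members) for c in rec.extract_so_clusters(tree, 2, "f")}
        assert got_so == {frozenset(m) for m in truth.so_clusters}


def test_partition_only_up_is_up2():
    c = rec.Cluster("t:UP1", "t", "UP", ["W_1", "W_2"], ["W", "W"])
    out = rec.partition_categories({"t": [c]})
    assert out[0].category == "UP2"


def test_partition_only_so_is_so2():
    c = rec.Cluster("t:SO1", "t", "SO", ["W_1", "X_1"], ["W", "X"])
    out = rec.partition_categories({"t": [c]})
    assert out[0].category == "SO2"


def _mk_up(tree_id, k):
    return rec.Cluster(f"{tree_id}:UP{k}", tree_id, "UP", ["W_1", "W_2"], ["W", "W"])


def test_sample_one_per_tree_keeps_one():
    clusters = [_mk_up("t", k) for k in range(3)]
    kept = rec.sample_one_per_tree(clusters, seed=0)
    assert len(kept) == 1


def test_sample_one_per_tree_keeps_up_and_so():
    up = _mk_up("t", 1)
    so = rec.Cluster("t:SO1", "t", "SO", ["W_1", "X_1"], ["W", "X"])
    kept = rec.sample_one_per_tree([up, so], seed=0)
    assert len(kept) == 2


def test_sampling_deterministic_and_uniform():
    clusters = [_mk_up("t", k) for k in range(3)]
    first = [rec.sample_one_per_tree(clusters, seed=s)[0].cluster_id for s in range(3000)]
    again = [rec.sample_one_per_tree(clusters, seed=s)[0].cluster_id for s in range(3000)]
    assert first == again
    counts = [first.count(c.cluster_id) for c in clusters]
    assert chisquare(counts).pvalue > 0.01


def test_estimate_gene_tree_too_few():
    aln = CodonAlignment(ids=["a", "b"], seqs=["AAA", "AAA"])
    with pytest.raises(ValueError):
        rec.estimate_gene_tree(aln)


def test_estimate_gene_tree_identical_sequences():
    aln = CodonAlignment(ids=["a", "b", "c"], seqs=["AAATTT"] * 3)
    tree = rec.estimate_gene_tree(aln)
    assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"a", "b", "c"}
    total = sum(
        nd.edge.length or 0.0 for nd in tree.preorder_node_iter()
    )
    assert total == pytest.approx(0.0, abs=1e-9)


def test_estimate_gene_tree_recovers_topology(six_taxon_tree):
    import dendropy
    from lsepipe import gy94, sitemodels as sm

    rng = np.random.default_rng(17)
    aln, _ = sim.simulate_codon_alignment(
        six_taxon_tree, sm.m1a(0.5, 0.3), gy94.Gy94Params(kappa=2.0), 3000, rng
    )
    est = rec.estimate_gene_tree(aln)
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=sim.to_newick(six_taxon_tree), schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=sim.to_newick(est), schema="newick", taxon_namespace=ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2, is_bipartitions_updated=True)
    assert rf == 0


def test_root_minimizing_duplications():
    # correct rooting separates the two species cleanly -> 2 duplications
    gene = parse_newick("((W_1:1,W_2:1):1,(X_1:1,X_2:1):1);")
    rec.reconcile_label(gene, SPECIES4)
    best = rec.root_minimizing_duplications(gene, SPECIES4)
    rec.reconcile_label(best, SPECIES4)
    assert rec.duplication_count(best) <= rec.duplication_count(gene)
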