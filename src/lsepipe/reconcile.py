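"""LCA reconciliation of gene trees against a species tree, and extraction
of ultraparalog (UP) and superortholog (SO) clusters.

A gene-tree internal node is a *duplication* when its species-tree LCA
mapping equals the mapping of at least one child, a *speciation* otherwise.
UP clusters are maximal single-species subtrees (lineage-specific
expansions); SO clusters are maximal subtrees whose internal nodes are all
speciations, hence at most one gene per species.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .trees import extract_subtree, species_of_label

EVENT_ATTR = "reconciliation_event"
DEFAULT_MIN_CLUSTER_SIZE = 6


@dataclass
class Cluster:
    cluster_id: str
    tree_id: str
    cluster_type: str  # "UP" | "SO"
    members: list[str]
    species: list[str]
    category: str = ""  # UP1/UP2/SO1/SO2, set by partition_categories
    upps: bool = False

    def __post_init__(self):
        if self.cluster_type not in ("UP", "SO"):
            raise ValueError(f"bad cluster type {self.cluster_type!r}")
        if self.cluster_type == "UP" and len(set(self.species)) != 1:
            raise ValueError("UP cluster must contain genes of exactly one species")
        if self.cluster_type == "SO" and len(set(self.species)) != len(self.species):
            raise ValueError("SO cluster has more than one gene for a species")
        if self.upps and self.cluster_type != "UP":
            raise ValueError("upps flag only applies to UP clusters")

    @property
    def size(self) -> int:
        return len(self.members)


class ReconciliationError(ValueError):
    pass


def _species_lca_table(species_tree: dendropy.Tree):
    """Per species-tree node: its index and leaf bitmask, for LCA queries."""
    nodes = list(species_tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    leaves = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    leaf_pos = {name: k for k, name in enumerate(leaves)}
    masks = np.zeros(len(nodes), dtype=object)
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            masks[i] = 1 << leaf_pos[nd.taxon.label]
        else:
            m = 0
            for ch in nd.child_nodes():
                m |= masks[index[id(ch)]]
            masks[i] = m
    # node order is postorder, so the first node whose mask covers a query
    # mask is the LCA of that leaf set
    return nodes, masks, leaf_pos


def reconcile_label(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    mapping: dict[str, str] | None = None,
) -> dendropy.Tree:
    """Label every internal node as 'duplication' or 'speciation' (in place).

    Standard LCA reconciliation; multifurcations are soft polytomies (a
    polytomy is a duplication when any child shares its mapping).
    """
    if gene_tree.seed_node is None:
        raise ReconciliationError("empty gene tree")
    nodes, masks, leaf_pos = _species_lca_table(species_tree)
    n = len(nodes)

    def lca_of_mask(mask: int) -> int:
        for i in range(n):
            if masks[i] & mask == mask:
                return i
        raise ReconciliationError("species-tree LCA lookup failed")

    node_map: dict[int, int] = {}
    node_mask: dict[int, int] = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            sp = species_of_label(nd.taxon.label, mapping)
            if sp not in leaf_pos:
                raise ReconciliationError(
                    f"leaf {nd.taxon.label!r} maps to unknown species {sp!r}"
                )
            node_mask[id(nd)] = 1 << leaf_pos[sp]
            node_map[id(nd)] = lca_of_mask(node_mask[id(nd)])
        else:
            mask = 0
            for ch in nd.child_nodes():
                mask |= node_mask[id(ch)]
            node_mask[id(nd)] = mask
            m = lca_of_mask(mask)
            node_map[id(nd)] = m
            dup = any(node_map[id(ch)] == m for ch in nd.child_nodes())
            setattr(nd, EVENT_ATTR, "duplication" if dup else "speciation")
    return gene_tree


def duplication_count(gene_tree: dendropy.Tree) -> int:
    return sum(
        1
        for nd in gene_tree.preorder_internal_node_iter()
        if getattr(nd, EVENT_ATTR, None) == "duplication"
    )


def root_minimizing_duplications(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    mapping: dict[str, str] | None = None,
) -> dendropy.Tree:
    """Root an unrooted gene tree at the edge minimising duplication count.

    Ties resolve to the first candidate edge in a deterministic preorder
    traversal of the input.
    """
    best = None
    best_count = None
    edges = [
        e for e in gene_tree.preorder_edge_iter()
        if e.head_node is not gene_tree.seed_node
    ]
    for k, edge in enumerate(edges):
        t = gene_tree.clone(depth=1)
        t_edges = [
            e for e in t.preorder_edge_iter() if e.head_node is not t.seed_node
        ]
        e = t_edges[k]
        half = (e.length or 0.0) / 2.0
        t.reroot_at_edge(e, length1=half, length2=half, update_bipartitions=False)
        t.is_rooted = True
        reconcile_label(t, species_tree, mapping)
        c = duplication_count(t)
        if best_count is None or c < best_count:
            best, best_count = t, c
    if best is None:
        raise ReconciliationError("gene tree has no internal edge to root on")
    return best


def _maximal_nodes(tree: dendropy.Tree, predicate) -> list:
    """Nodes satisfying `predicate` whose parent does not."""
    flags: dict[int, bool] = {}
    for nd in tree.postorder_node_iter():
        flags[id(nd)] = predicate(nd, flags)
    out = []
    for nd in tree.preorder_node_iter():
        if flags[id(nd)] and (
            nd.parent_node is None or not flags[id(nd.parent_node)]
        ):
            out.append(nd)
    return out


def _require_labeled(tree: dendropy.Tree):
    for nd in tree.preorder_internal_node_iter():
        if getattr(nd, EVENT_ATTR, None) not in ("duplication", "speciation"):
            raise ReconciliationError("gene tree has unlabeled internal nodes")


def extract_up_clusters(
    labeled_tree: dendropy.Tree,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    tree_id: str = "tree",
    mapping: dict[str, str] | None = None,
) -> list[Cluster]:
    """Maximal single-species subtrees with at least `min_size` leaves."""
    _require_labeled(labeled_tree)
    species: dict[int, set[str]] = {}

    def single_species(nd, flags):
        if nd.is_leaf():
            species[id(nd)] = {species_of_label(nd.taxon.label, mapping)}
            return True
        sp = set()
        for ch in nd.child_nodes():
            sp |= species[id(ch)]
        species[id(nd)] = sp
        return len(sp) == 1

    clusters = []
    for k, nd in enumerate(_maximal_nodes(labeled_tree, single_species)):
        leaves = [lf.taxon.label for lf in nd.leaf_iter()]
        if len(leaves) < min_size:
            continue
        clusters.append(
            Cluster(
                cluster_id=f"{tree_id}:UP{len(clusters) + 1}",
                tree_id=tree_id,
                cluster_type="UP",
                members=leaves,
                species=[species_of_label(m, mapping) for m in leaves],
            )
        )
    return clusters


def extract_so_clusters(
    labeled_tree: dendropy.Tree,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    tree_id: str = "tree",
    mapping: dict[str, str] | None = None,
) -> list[Cluster]:
    """Maximal all-speciation subtrees with at least `min_size` leaves."""
    _require_labeled(labeled_tree)

    def all_speciation(nd, flags):
        if nd.is_leaf():
            return True
        if getattr(nd, EVENT_ATTR) != "speciation":
            return False
        return all(flags[id(ch)] for ch in nd.child_nodes())

    clusters = []
    for nd in _maximal_nodes(labeled_tree, all_speciation):
        leaves = [lf.taxon.label for lf in nd.leaf_iter()]
        if len(leaves) < min_size:
            continue
        clusters.append(
            Cluster(
                cluster_id=f"{tree_id}:SO{len(clusters) + 1}",
                tree_id=tree_id,
                cluster_type="SO",
                members=leaves,
                species=[species_of_label(m, mapping) for m in leaves],
            )
        )
    return clusters


def partition_categories(
    clusters_by_tree: dict[str, list[Cluster]]
) -> list[Cluster]:
    """Assign UP1/UP2/SO1/SO2 categories from per-tree co-occurrence."""
    out = []
    for tree_id, clusters in clusters_by_tree.items():
        has_up = any(c.cluster_type == "UP" for c in clusters)
        has_so = any(c.cluster_type == "SO" for c in clusters)
        for c in clusters:
            if c.cluster_type == "UP":
                c.category = "UP1" if has_so else "UP2"
            else:
                c.category = "SO1" if has_up else "SO2"
            out.append(c)
    return out


def sample_one_per_tree(clusters: list[Cluster], seed: int) -> list[Cluster]:
    """Keep at most one UP and one SO cluster per tree, chosen uniformly."""
    rng = random.Random(seed)
    by_key: dict[tuple[str, str], list[Cluster]] = {}
    for c in clusters:
        by_key.setdefault((c.tree_id, c.cluster_type), []).append(c)
    kept = []
    for key in sorted(by_key):
        group = by_key[key]
        kept.append(group[rng.randrange(len(group))] if len(group) > 1 else group[0])
    return kept


def estimate_gene_tree(alignment, override_tree=None) -> dendropy.Tree:
    """Baseline neighbor-joining tree on JC69-corrected nucleotide distances.

    Stands in for a full ML tree search; an externally inferred tree can be
    passed straight through via `override_tree`.
    """
    if override_tree is not None:
        return override_tree
    if alignment.n_seqs < 3:
        raise ValueError("tree estimation needs at least 3 sequences")
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    n = alignment.n_seqs
    matrix = []
    for i in range(n):
        row = []
        for j in range(i + 1):
            if i == j:
                row.append(0.0)
                continue
            a, b = alignment.seqs[i], alignment.seqs[j]
            pairs = [
                (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
            ]
            if not pairs:
                row.append(0.0)
                continue
            p = sum(x != y for x, y in pairs) / len(pairs)
            p = min(p, 0.74)  # keep the JC69 correction finite
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            row.append(float(d))
        matrix.append(row)
    dm = DistanceMatrix(names=list(alignment.ids), matrix=matrix)
    nj = DistanceTreeConstructor().nj(dm)
    for clade in nj.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
    newick = nj.format("newick")
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


@dataclass
class ClusterTableRow:
    cluster_id: str
    tree_id: str
    cluster_type: str
    category: str
    size: int
    member_ids: str = field(default="")


def clusters_to_table(clusters: list[Cluster]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "tree_id": c.tree_id,
                "type": c.cluster_type,
                "category": c.category,
                "size": c.size,
                "member_ids": ";".join(c.members),
            }
            for c in clusters
        ]
    )
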