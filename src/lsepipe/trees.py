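"""Tree I/O and indexing helpers.

Trees are handled as dendropy objects at the API surface; numerical code
(likelihood, substitution mapping, simulation) works on a flat
:class:`TreeIndex` built once per tree.

Leaf labels follow the ``SPECIES_GENEID`` convention (species id = text
before the first underscore) unless an explicit gene->species mapping is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a single rooted newick tree from a string."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    )


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def species_of_label(label: str, mapping: dict[str, str] | None = None) -> str:
    """Species id for a gene leaf label.

    With no mapping, the species is the prefix before the first underscore.
    """
    if mapping is not None:
        try:
            return mapping[label]
        except KeyError:
            raise KeyError(f"leaf {label!r} missing from gene->species mapping")
    if "_" not in label:
        raise ValueError(
            f"leaf label {label!r} is not SPECIES_GENEID and no mapping given"
        )
    return label.split("_", 1)[0]


def read_species_mapping(path) -> dict[str, str]:
    """Two-column TSV: gene id, species id."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, species = line.split("\t")[:2]
            mapping[gene] = species
    return mapping


@dataclass
class TreeIndex:
    """Flat postorder view of a rooted tree.

    nodes are numbered 0..n-1 with the root last in `postorder`; `parent[i]`
    is -1 for the root; `length[i]` is the length of the edge above node i
    (0 for the root); `leaf_index` maps leaf label -> node id.
    """

    parent: np.ndarray
    length: np.ndarray
    postorder: np.ndarray
    children: list[list[int]]
    leaf_index: dict[str, int]
    node_refs: list  # dendropy Node per index

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def is_internal_edge(self, i: int) -> bool:
        """True when the edge above node i leads to an internal node."""
        return bool(self.children[i]) and self.parent[i] != -1

    def edge_nodes(self) -> np.ndarray:
        """Node ids that have a subtending edge (everything but the root)."""
        return self.postorder[:-1]


def index_tree(tree: dendropy.Tree) -> TreeIndex:
    nodes = list(tree.postorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n, dtype=float)
    children: list[list[int]] = [[] for _ in range(n)]
    leaf_index: dict[str, int] = {}
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = ids[id(nd.parent_node)]
            length[i] = nd.edge.length if nd.edge.length is not None else 0.0
            children[parent[i]].append(i)
        if nd.is_leaf():
            leaf_index[nd.taxon.label] = i
    postorder = np.arange(n, dtype=np.int64)
    return TreeIndex(
        parent=parent,
        length=length,
        postorder=postorder,
        children=children,
        leaf_index=leaf_index,
        node_refs=nodes,
    )


def extract_subtree(tree: dendropy.Tree, leaf_names: list[str]) -> dendropy.Tree:
    """Induced rooted subtree on the given leaves (unifurcations collapsed)."""
    sub = tree.extract_tree_with_taxa_labels(labels=set(leaf_names))
    sub.is_rooted = True
    # collapse a degree-one root left over from extraction
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        if child.is_leaf():
            break
        sub.seed_node = child
        child.parent_node = None
        child.edge.length = None
    sub.update_taxon_namespace()
    return sub
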