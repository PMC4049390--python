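"""Synthetic studies: species tree, duplication/loss gene families and codon
alignments evolved under known site-class mixtures, with ground truth.

All randomness flows from a single seed; regenerating a study with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import geneticcode as gc
from . import gy94
from . import sitemodels as sm
from .qc import CodonAlignment, write_fasta
from .reconcile import EVENT_ATTR, extract_so_clusters, extract_up_clusters
from .trees import index_tree, parse_newick, to_newick

TRUE_EVENT_ATTR = "true_event"


def default_species_tree(
    n_per_clade: int = 5, depth: float = 1.0
) -> dendropy.Tree:
    """Ultrametric two-clade species tree (monocot/dicot-like layout).

    Each clade is a ladder of `n_per_clade` species; clade stems attach to
    the root at `depth` time units before the present.
    """

    def clade(prefix: str) -> str:
        ages = np.linspace(0.15, 0.8, n_per_clade - 1) * depth
        nwk = f"{prefix}1:{ages[0]:.10g}"
        for k in range(1, n_per_clade):
            age = ages[k - 1]
            stem = (ages[k] - age) if k < n_per_clade - 1 else (0.8 * depth - age)
            tip = f"{prefix}{k + 1}:{age:.10g}"
            nwk = f"({nwk},{tip}):{stem:.10g}" if k < n_per_clade - 1 else f"({nwk},{tip})"
        return nwk

    stem = 0.2 * depth
    newick = f"({clade('mono')}:{stem:.10g},{clade('dico')}:{stem:.10g});"
    return parse_newick(newick)


@dataclass
class SimulationConfig:
    seed: int
    n_families: int = 50
    n_per_clade: int = 5
    dup_rate: float = 0.08
    loss_rate: float = 0.0
    burst_multiplier: float = 170.0
    burst_fraction: float = 0.6
    # burst hosts default to the short-tipped species so expansions stay
    # in the tens of copies, not thousands
    lse_species: tuple[str, ...] = ("mono1", "mono2", "dico1", "dico2")
    n_codons: int = 300
    kappa: float = 2.0
    tree_scale: float = 0.3
    pos_fraction: float = 0.2
    neutral_spec: dict = field(
        default_factory=lambda: {"p0": 0.75, "omega0": 0.15}
    )
    pos_spec: dict = field(
        default_factory=lambda: {"p0": 0.6, "p1": 0.25, "omega0": 0.15, "omega2": 4.0}
    )
    max_retries: int = 100

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.dup_rate, self.loss_rate, self.burst_multiplier):
            if r < 0:
                raise ValueError("rates must be nonnegative")


@dataclass
class FamilyTruth:
    family_id: str
    events: dict[str, str] = field(default_factory=dict)  # node label -> event
    up_clusters: list[list[str]] = field(default_factory=list)
    so_clusters: list[list[str]] = field(default_factory=list)
    site_class: np.ndarray | None = None
    site_omega: np.ndarray | None = None
    branch_counts: dict[str, tuple[float, float]] = field(default_factory=dict)
    selected: bool = False
    burst_species: str | None = None


class SimulationError(RuntimeError):
    pass


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    k = 0
    for nd in tree.postorder_node_iter():
        if not nd.is_leaf() and nd.label is None:
            nd.label = f"n{k}"
        k += 1


def simulate_gene_family(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
    family_id: str = "fam",
) -> tuple[dendropy.Tree, FamilyTruth]:
    """Birth-death gene family along the species tree.

    Duplications occur at `dup_rate` per lineage per unit time. With
    probability `burst_fraction` the family hosts a lineage-specific
    expansion: one species (drawn from `lse_species`, or from all species
    when that tuple is empty) has its terminal-edge duplication rate
    multiplied by `burst_multiplier`. Losses prune lineages. Internal nodes
    carry their true duplication/speciation labels.
    """
    counter = [0]
    taxon_ns = dendropy.TaxonNamespace()
    candidates = config.lse_species or tuple(
        lf.taxon.label for lf in species_tree.leaf_node_iter()
    )
    burst_species: str | None = None
    if config.burst_multiplier > 0 and rng.random() < config.burst_fraction:
        burst_species = candidates[rng.integers(len(candidates))]

    def new_leaf(species: str) -> dendropy.Node:
        counter[0] += 1
        nd = dendropy.Node()
        taxon = taxon_ns.new_taxon(f"{species}_g{counter[0]:04d}")
        nd.taxon = taxon
        nd.edge.length = 0.0
        return nd

    def dup_rate_for(sp_node) -> float:
        if sp_node.is_leaf() and sp_node.taxon.label == burst_species:
            return config.dup_rate * config.burst_multiplier
        return config.dup_rate

    def at_node(sp_node) -> dendropy.Node | None:
        if sp_node.is_leaf():
            return new_leaf(sp_node.taxon.label)
        kids = []
        for ch in sp_node.child_nodes():
            sub = along_edge(ch, ch.edge.length)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        nd = dendropy.Node()
        nd.edge.length = 0.0
        setattr(nd, TRUE_EVENT_ATTR, "speciation")
        for k in kids:
            nd.add_child(k)
        return nd

    def along_edge(sp_node, time_left: float) -> dendropy.Node | None:
        rate_d = dup_rate_for(sp_node)
        total = rate_d + config.loss_rate
        t_event = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t_event < time_left:
            if rng.random() < rate_d / total:  # duplication
                left = along_edge(sp_node, time_left - t_event)
                right = along_edge(sp_node, time_left - t_event)
                survivors = [x for x in (left, right) if x is not None]
                if not survivors:
                    return None
                if len(survivors) == 1:
                    survivors[0].edge.length += t_event
                    return survivors[0]
                nd = dendropy.Node()
                nd.edge.length = t_event
                setattr(nd, TRUE_EVENT_ATTR, "duplication")
                for k in survivors:
                    nd.add_child(k)
                return nd
            return None  # loss
        nd = at_node(sp_node)
        if nd is not None:
            nd.edge.length += time_left
        return nd

    for _ in range(config.max_retries):
        counter[0] = 0
        taxon_ns = dendropy.TaxonNamespace()
        root = at_node(species_tree.seed_node)
        if root is not None and len(root.leaf_nodes() if not root.is_leaf() else [root]) >= 2:
            break
    else:
        raise SimulationError(
            f"{family_id}: all gene copies lost in {config.max_retries} attempts"
        )

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    root.parent_node = None
    root.edge.length = None
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= config.tree_scale
    _label_internal_nodes(tree)

    truth = FamilyTruth(family_id=family_id, burst_species=burst_species)
    for nd in tree.preorder_internal_node_iter():
        event = getattr(nd, TRUE_EVENT_ATTR, None)
        if event is None:  # unifurcation-collapsed artifacts cannot occur
            raise SimulationError("internal node without a true event")
        truth.events[nd.label] = event
        setattr(nd, EVENT_ATTR, event)  # extraction on truth labels
    truth.up_clusters = [
        c.members for c in extract_up_clusters(tree, min_size=2, tree_id=family_id)
    ]
    truth.so_clusters = [
        c.members for c in extract_so_clusters(tree, min_size=2, tree_id=family_id)
    ]
    return tree, truth


def simulate_codon_alignment(
    gene_tree: dendropy.Tree,
    spec: sm.SiteModelSpec,
    params: gy94.Gy94Params,
    n_codons: int,
    rng: np.random.Generator,
) -> tuple[CodonAlignment, dict]:
    """Evolve a codon alignment along the tree under a site-class mixture.

    Site classes are drawn once per site; sequences evolve by exact
    Gillespie simulation of the 61-state chain. Every realised substitution
    is recorded with its synonymous/nonsynonymous label per branch.
    """
    pi = params.pi
    if np.any(pi <= 0):
        raise ValueError("pi must be strictly positive")
    qs = gy94.mixture_generators(params.kappa, spec.omegas, spec.weights, pi)
    exit_rates, jump_cums = [], []
    for q in qs:
        rates = -np.diag(q)
        jumps = np.where(rates[:, None] > 0, q / np.maximum(rates[:, None], 1e-300), 0.0)
        np.fill_diagonal(jumps, 0.0)
        jump_cums.append(np.cumsum(jumps, axis=1))
        exit_rates.append(rates)

    idx = index_tree(gene_tree)
    site_class = rng.choice(len(spec.weights), size=n_codons, p=spec.weights)
    root_states = rng.choice(gc.N_CODONS, size=n_codons, p=pi)

    states = {idx.root: root_states.copy()}
    branch_counts: dict[str, tuple[float, float]] = {}
    seqs: dict[str, np.ndarray] = {}

    for i in idx.postorder[::-1]:
        if i == idx.root:
            pass
        else:
            parent_states = states[idx.parent[i]]
            t = idx.length[i]
            out = parent_states.copy()
            n_s = n_ns = 0
            for s in range(n_codons):
                c = site_class[s]
                state = out[s]
                remaining = t
                while True:
                    r = exit_rates[c][state]
                    if r <= 0:
                        break
                    dt = rng.exponential(1.0 / r)
                    if dt >= remaining:
                        break
                    remaining -= dt
                    u = rng.random() * jump_cums[c][state, -1]
                    nxt = int(np.searchsorted(jump_cums[c][state], u, side="right"))
                    nxt = min(nxt, gc.N_CODONS - 1)
                    if gc.SYNONYMOUS[state, nxt]:
                        n_s += 1
                    else:
                        n_ns += 1
                    state = nxt
                out[s] = state
            states[i] = out
            nd = idx.node_refs[i]
            label = nd.taxon.label if nd.is_leaf() else nd.label or f"node{i}"
            branch_counts[label] = (float(n_s), float(n_ns))
        nd = idx.node_refs[i]
        if nd.is_leaf():
            seqs[nd.taxon.label] = states[i]

    ids = sorted(seqs)
    aln = CodonAlignment(
        ids=ids,
        seqs=["".join(gc.CODONS[j] for j in seqs[name]) for name in ids],
    )
    truth = {
        "site_class": site_class,
        "site_omega": spec.omegas[site_class],
        "branch_counts": branch_counts,
    }
    return aln, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixture_study(
    config: SimulationConfig, outdir, overwrite: bool = False
) -> dict:
    """Write a self-contained study directory the pipeline can consume.

    Layout: species.nwk, families/<fam>.fasta + .nwk, truth_*.tsv and a
    manifest.json recording the configuration, seed and content digests.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty")
    (outdir / "families").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    species_tree = default_species_tree(config.n_per_clade)
    (outdir / "species.nwk").write_text(to_newick(species_tree) + "\n")

    params = gy94.Gy94Params(kappa=config.kappa)
    ev_rows, cl_rows, site_rows, br_rows, fam_rows = [], [], [], [], []
    for f in range(config.n_families):
        fam = f"fam{f + 1:04d}"
        selected = bool(rng.random() < config.pos_fraction)
        spec = (
            sm.m2a(**config.pos_spec) if selected else sm.m1a(**config.neutral_spec)
        )
        tree, truth = simulate_gene_family(species_tree, config, rng, family_id=fam)
        aln, aln_truth = simulate_codon_alignment(
            tree, spec, params, config.n_codons, rng
        )
        truth.selected = selected
        write_fasta(zip(aln.ids, aln.seqs), outdir / "families" / f"{fam}.fasta")
        (outdir / "families" / f"{fam}.nwk").write_text(to_newick(tree) + "\n")
        fam_rows.append(
            f"{fam}\t{int(selected)}\t{spec.model}\t{truth.burst_species or 'none'}"
        )
        for label, event in sorted(truth.events.items()):
            ev_rows.append(f"{fam}\t{label}\t{event}")
        for kind, groups in (("UP", truth.up_clusters), ("SO", truth.so_clusters)):
            for k, members in enumerate(groups):
                cl_rows.append(f"{fam}\t{kind}\t{k + 1}\t{';'.join(sorted(members))}")
        for s in range(config.n_codons):
            site_rows.append(
                f"{fam}\t{s + 1}\t{aln_truth['site_class'][s]}"
                f"\t{aln_truth['site_omega'][s]:g}"
            )
        for label, (n_s, n_ns) in sorted(aln_truth["branch_counts"].items()):
            br_rows.append(f"{fam}\t{label}\t{n_s:g}\t{n_ns:g}")

    def write_tsv(name: str, header: str, rows: list[str]):
        (outdir / name).write_text("\n".join([header] + rows) + "\n")

    write_tsv("truth_families.tsv", "family\tselected\tmodel\tburst_species", fam_rows)
    write_tsv("truth_events.tsv", "family\tnode\tevent", ev_rows)
    write_tsv("truth_clusters.tsv", "family\ttype\tindex\tmembers", cl_rows)
    write_tsv("truth_sites.tsv", "family\tsite\tclass\tomega", site_rows)
    write_tsv("truth_branches.tsv", "family\tbranch\tnbS_true\tnbNS_true", br_rows)

    digests = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "digests": digests,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
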