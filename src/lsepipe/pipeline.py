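"""End-to-end workflow: reconcile -> extract/partition/sample -> QC ->
site-model fits + LRTs + site calls -> substitution mapping + branch omega
-> comparative statistics, with a run manifest accounting for every filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import fit as fitmod
from . import mapping as mapmod
from . import reconcile as rec
from . import stats as statsmod
from .qc import (CleaningConfig, CodonAlignment, apply_min_size,
                 clean_alignment, read_fasta, validate_cds_cluster)
from .trees import extract_subtree, read_species_mapping, read_tree

log = logging.getLogger("lsepipe")

STAGES = ("reconcile", "qc", "fit", "map", "stats")


@dataclass
class PipelineConfig:
    seed: int = 1
    min_cluster_size: int = 6
    min_sequences_post_clean: int = 4
    gap_fraction_cutoff: float = 0.5
    models: tuple[str, ...] = ("M1a", "M2a")
    n_starts: int = 3
    alpha: float = 0.05
    posterior_cutoff: float = 0.95
    omega_gt1: float = 1.0
    omega_strong: float = 1.2
    window_width: float = 0.01
    window_min_per_group: int = 100
    estimate_trees: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


@dataclass
class ClusterWork:
    cluster: rec.Cluster
    alignment: CodonAlignment | None = None
    tree: dendropy.Tree | None = None
    fits: dict = field(default_factory=dict)
    lrts: list = field(default_factory=list)
    counts: fitmod.SiteCounts | None = None
    flagged: list[int] = field(default_factory=list)
    posterior: np.ndarray | None = None
    under_selection: bool = False
    reject_reason: str = ""


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_study(study_dir: Path):
    species_tree = read_tree(study_dir / "species.nwk")
    families = {}
    for fasta in sorted((study_dir / "families").glob("*.fasta")):
        fam = fasta.stem
        nwk = fasta.with_suffix(".nwk")
        families[fam] = {
            "fasta": fasta,
            "tree": nwk if nwk.exists() else None,
        }
    # optional two-column TSV overriding the SPECIES_GENEID label convention
    mapping_path = study_dir / "gene_species_map.tsv"
    mapping = read_species_mapping(mapping_path) if mapping_path.exists() else None
    return species_tree, families, mapping


def _divergence_times(species_tree: dendropy.Tree) -> dict[str, float]:
    """Time to the most closely related species (half patristic distance)."""
    pdm = species_tree.phylogenetic_distance_matrix()
    taxa = list(species_tree.taxon_namespace)
    out = {}
    for t1 in taxa:
        dists = [
            pdm.patristic_distance(t1, t2) / 2.0 for t2 in taxa if t2 is not t1
        ]
        out[t1.label] = min(dists)
    return out


def run_pipeline(
    study_dir,
    outdir,
    config: PipelineConfig | None = None,
    until: str = "stats",
) -> dict:
    """Run the workflow on a study directory and write report tables.

    Returns the run manifest. `until` stops after the named stage
    (one of reconcile/qc/fit/map/stats).
    """
    config = config or PipelineConfig()
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    study_dir, outdir = Path(study_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    species_tree, families, species_map = _load_study(study_dir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "study": str(study_dir),
        "counts": {},
        "stages": {},
    }

    # ---- reconcile / extract / partition / sample -------------------------
    clusters_by_tree: dict[str, list[rec.Cluster]] = {}
    gene_trees: dict[str, dendropy.Tree] = {}
    for fam, paths in families.items():
        tree = read_tree(paths["tree"]) if paths["tree"] else None
        if tree is None:
            raise FileNotFoundError(f"{fam}: no gene tree provided")
        rec.reconcile_label(tree, species_tree, mapping=species_map)
        gene_trees[fam] = tree
        ups = rec.extract_up_clusters(
            tree, config.min_cluster_size, tree_id=fam, mapping=species_map
        )
        sos = rec.extract_so_clusters(
            tree, config.min_cluster_size, tree_id=fam, mapping=species_map
        )
        clusters_by_tree[fam] = ups + sos
    all_clusters = rec.partition_categories(clusters_by_tree)
    sampled = rec.sample_one_per_tree(all_clusters, seed=config.seed)
    manifest["counts"]["clusters_extracted"] = len(all_clusters)
    manifest["counts"]["clusters_after_sampling"] = len(sampled)
    manifest["stages"]["reconcile"] = {"elapsed_s": round(time.time() - t0, 3)}
    rec.clusters_to_table(sampled).to_csv(
        outdir / "clusters_extracted.tsv", sep="\t", index=False
    )
    work = [ClusterWork(cluster=c) for c in sampled]
    if last < STAGES.index("qc"):
        return _finalize(manifest, outdir)

    # ---- QC ---------------------------------------------------------------
    t1 = time.time()
    fam_alignments = {
        fam: dict(read_fasta(paths["fasta"])) for fam, paths in families.items()
    }
    cleaning = CleaningConfig(gap_fraction_cutoff=config.gap_fraction_cutoff)
    n_rejected_cds = n_rejected_size = 0
    for w in work:
        c = w.cluster
        seqs = {m: fam_alignments[c.tree_id][m] for m in c.members}
        val = validate_cds_cluster(seqs)
        if not val.ok:
            w.reject_reason = "cds: " + "; ".join(val.reasons)
            n_rejected_cds += 1
            continue
        aln = CodonAlignment(
            ids=sorted(val.sequences), seqs=[val.sequences[k] for k in sorted(val.sequences)]
        )
        aln = clean_alignment(aln, mask=None, config=cleaning)
        if not apply_min_size(aln, config.min_sequences_post_clean):
            w.reject_reason = "fewer than minimum sequences after cleaning"
            n_rejected_size += 1
            continue
        w.alignment = aln
    manifest["counts"]["rejected_cds"] = n_rejected_cds
    manifest["counts"]["rejected_min_size"] = n_rejected_size
    manifest["counts"]["clusters_qc_pass"] = sum(
        1 for w in work if w.alignment is not None
    )
    manifest["stages"]["qc"] = {"elapsed_s": round(time.time() - t1, 3)}
    if last < STAGES.index("fit"):
        return _finalize(manifest, outdir)

    # ---- per-cluster trees + site-model fits ------------------------------
    t2 = time.time()
    for w in work:
        if w.alignment is None:
            continue
        c = w.cluster
        if config.estimate_trees:
            w.tree = rec.estimate_gene_tree(w.alignment)
        else:
            w.tree = extract_subtree(gene_trees[c.tree_id], w.alignment.ids)
        try:
            w.fits = fitmod.fit_model_pairs(
                w.alignment, w.tree, models=config.models, n_starts=config.n_starts
            )
        except fitmod.FitError as exc:
            log.error("fit failed for %s: %s", c.cluster_id, exc)
            w.reject_reason = f"fit: {exc}"
            continue
        for null, alt in (("M1a", "M2a"), ("M8a", "M8")):
            if null in w.fits and alt in w.fits:
                w.lrts.append(
                    fitmod.lrt_positive_selection(w.fits[null], w.fits[alt])
                )
        null_model = "M1a" if "M1a" in w.fits else next(iter(w.fits))
        w.counts = fitmod.count_syn_nonsyn_sites(
            w.alignment, w.fits[null_model].kappa
        )
        alt_model = "M2a" if "M2a" in w.fits else ("M8" if "M8" in w.fits else None)
        if alt_model:
            w.posterior, w.flagged = fitmod.site_posterior_omega_gt1(
                w.fits[alt_model]
            )

    # Bonferroni within each category; positive call = any LRT significant
    # after correction AND at least one flagged site.
    fitted = [w for w in work if w.fits]
    for category in ("UP1", "UP2", "SO1", "SO2"):
        members = [w for w in fitted if w.cluster.category == category]
        m = len(members)
        for w in members:
            significant = False
            for lrt in w.lrts:
                lrt.p_adjusted = float(
                    fitmod.bonferroni_adjust([lrt.p_value], max(m, 1))[0]
                )
                lrt.significant = lrt.p_adjusted < config.alpha
                significant = significant or lrt.significant
            w.under_selection = significant and bool(w.flagged)
            w.cluster.upps = w.cluster.cluster_type == "UP" and w.under_selection
    manifest["counts"]["clusters_fitted"] = len(fitted)
    manifest["counts"]["clusters_under_selection"] = sum(
        w.under_selection for w in fitted
    )
    manifest["counts"]["bonferroni_family_sizes"] = {
        cat: sum(1 for w in fitted if w.cluster.category == cat)
        for cat in ("UP1", "UP2", "SO1", "SO2")
    }
    manifest["stages"]["fit"] = {"elapsed_s": round(time.time() - t2, 3)}
    _write_fit_reports(work, outdir)
    if last < STAGES.index("map"):
        return _finalize(manifest, outdir)

    # ---- substitution mapping + branch omega ------------------------------
    t3 = time.time()
    tables = {}
    for w in fitted:
        null_model = "M1a" if "M1a" in w.fits else next(iter(w.fits))
        mapped = mapmod.map_substitutions(w.alignment, w.tree, w.fits[null_model])
        tables[w.cluster.cluster_id] = mapmod.branch_table(
            w.cluster.cluster_id, mapped, w.counts
        )
    branches, dropped = mapmod.filter_and_classify_branches(tables)
    manifest["counts"]["clusters_mapped"] = len(tables) - len(dropped)
    manifest["counts"]["clusters_dropped_no_substitutions"] = len(dropped)
    manifest["counts"]["branches_analysed"] = len(branches)
    manifest["stages"]["map"] = {"elapsed_s": round(time.time() - t3, 3)}
    branches.to_csv(outdir / "branches.tsv", sep="\t", index=False)
    if last < STAGES.index("stats"):
        return _finalize(manifest, outdir)

    # ---- comparative statistics -------------------------------------------
    t4 = time.time()
    cluster_df = _cluster_frame(work)
    cluster_df.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    # only clusters that survived QC and fitting enter the statistics
    cluster_df = cluster_df[~cluster_df["rejected"].astype(bool)].reset_index(
        drop=True
    )

    category_of = dict(zip(cluster_df["cluster_id"], cluster_df["category"]))
    extended = branches.copy()
    extended["category"] = extended["cluster_id"].map(category_of)
    extras = []
    upps_ids = set(cluster_df.loc[cluster_df["upps"].astype(bool), "cluster_id"])
    up_mask = (
        extended["category"].astype("string").str.startswith("UP").fillna(False)
    )
    upint = extended[up_mask & extended["is_internal"]].copy()
    upint["category"] = "UPint"
    extras.append(upint)
    upps = extended[extended["cluster_id"].isin(upps_ids)].copy()
    upps["category"] = "UPps"
    extras.append(upps)
    summary_input = pd.concat([extended] + extras, ignore_index=True)
    table3 = _summarize_with_categories(summary_input)
    table3.to_csv(outdir / "table3_branch_summary.tsv", sep="\t", index=False)

    table1 = statsmod.summarize_dataset(cluster_df, branches)
    table1.to_csv(outdir / "table1_dataset.tsv", sep="\t", index=False)

    rows = statsmod.build_size_category_rows(cluster_df, branches)
    table4 = statsmod.fisher_by_size_category(rows)
    table4.to_csv(outdir / "table4_fisher.tsv", sep="\t", index=False)

    so_branches = extended[~up_mask]
    windows = statsmod.sliding_window_ds_test(
        upint, so_branches,
        width=config.window_width,
        min_per_group=config.window_min_per_group,
    )
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)

    div = _divergence_times(species_tree)
    up_counts = {
        sp: 0 for sp in div
    }
    for w in work:
        if w.cluster.cluster_type == "UP":
            up_counts[w.cluster.species[0]] = up_counts.get(w.cluster.species[0], 0) + 1
    species = sorted(div)
    counts_vec = [up_counts[s] for s in species]
    if len(species) >= 3 and len(set(counts_vec)) > 1:
        rho, p = statsmod.spearman_clusters_vs_divergence(
            counts_vec, [div[s] for s in species]
        )
        manifest["spearman_up_vs_divergence"] = {"rho": rho, "p": p}
    manifest["stages"]["stats"] = {"elapsed_s": round(time.time() - t4, 3)}
    return _finalize(manifest, outdir)


def _summarize_with_categories(summary_input: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cat, grp in summary_input.groupby("category", sort=True):
        fake_map = {cid: cat for cid in grp["cluster_id"]}
        part = statsmod.summarize_branch_categories(
            grp.drop(columns=["category"]), fake_map
        )
        rows.append(part)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


_CLUSTER_COLUMNS = [
    "cluster_id", "tree_id", "type", "category", "size", "upps", "rejected",
    "reject_reason", "n_codons", "alignment_length_bp", "under_selection",
    "n_flagged_sites",
]


def _cluster_frame(work: list[ClusterWork]) -> pd.DataFrame:
    rows = []
    for w in work:
        c = w.cluster
        row = {
            "cluster_id": c.cluster_id,
            "tree_id": c.tree_id,
            "type": c.cluster_type,
            "category": c.category,
            "size": c.size,
            "upps": c.upps,
            "rejected": bool(w.reject_reason),
            "reject_reason": w.reject_reason,
            "n_codons": w.alignment.n_codons if w.alignment else 0,
            "alignment_length_bp": w.alignment.n_cols if w.alignment else 0,
            "under_selection": w.under_selection,
            "n_flagged_sites": len(w.flagged),
        }
        for model, f in w.fits.items():
            row[f"lnL_{model}"] = f.lnL
        for lrt in w.lrts:
            tag = f"{lrt.null_model}_{lrt.alt_model}"
            row[f"lrt_{tag}"] = lrt.statistic
            row[f"p_{tag}"] = lrt.p_value
            row[f"padj_{tag}"] = lrt.p_adjusted
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in _CLUSTER_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=object)
    return df


def _write_fit_reports(work: list[ClusterWork], outdir: Path) -> None:
    site_rows = []
    for w in work:
        if w.posterior is None:
            continue
        for pos0, post in enumerate(w.posterior):
            site_rows.append(
                {
                    "cluster_id": w.cluster.cluster_id,
                    "codon_position": pos0 + 1,
                    "posterior_omega_gt1": float(post),
                    "flagged": bool(post > fitmod.POSTERIOR_FLAG_CUTOFF),
                }
            )
    pd.DataFrame(
        site_rows,
        columns=["cluster_id", "codon_position", "posterior_omega_gt1", "flagged"],
    ).to_csv(outdir / "sites.tsv", sep="\t", index=False)


def _finalize(manifest: dict, outdir: Path) -> dict:
    digests = {
        p.name: _sha256_file(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["digests"] = digests
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
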