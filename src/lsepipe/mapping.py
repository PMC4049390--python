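"""Per-branch expected substitution counts and the branch-omega statistic.

Expected numbers of synonymous (nbS) and nonsynonymous (nbNS) substitutions
per branch are posterior expectations of labelled Markov jumps given the
data and a fitted site-class model, computed analytically with the
eigendecomposition integral (no stochastic draws). Branch omega is
(nbNS/NSsites) / (nbS/Ssites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geneticcode as gc
from . import gy94
from . import likelihood as lk
from .fit import SiteCounts, SiteModelFit, count_syn_nonsyn_sites
from .qc import CodonAlignment

OMEGA_GT1_THRESHOLD = 1.0
OMEGA_STRONG_THRESHOLD = 1.2


@dataclass
class BranchRecord:
    cluster_id: str
    branch_id: int
    parent_label: str
    child_label: str
    is_internal: bool
    nbNS: float
    nbS: float
    omega: float = np.nan
    dS: float = np.nan
    selection_class: str = ""


def _labelled_count_integral(decomp, q: np.ndarray, mask: np.ndarray, t: float) -> np.ndarray:
    """J(t) = integral_0^t exp(Qs) R exp(Q(t-s)) ds for R = Q*mask.

    Computed in the symmetric basis of the reversible generator; J[i, j]
    contributes the expected number of mask-labelled jumps on a branch of
    length t joint with start state i and end state j.
    """
    w, v, d = decomp
    r = np.where(mask, q, 0.0)
    r_sym = r * d[:, np.newaxis] / d[np.newaxis, :]
    m = v.T @ r_sym @ v
    ew = np.exp(w * t)
    diff = w[:, np.newaxis] - w[np.newaxis, :]
    near = np.abs(diff) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = (ew[:, np.newaxis] - ew[np.newaxis, :]) / diff
    kernel[near] = (t * ew[:, np.newaxis] * np.ones_like(kernel))[near]
    j = v @ (m * kernel) @ v.T
    j = j / d[:, np.newaxis] * d[np.newaxis, :]
    np.clip(j, 0.0, None, out=j)
    return j


def _class_messages(data: lk.PhyloData, decomp, lengths, pi):
    """Below partials L, upward messages U and outside messages O per node.

    No numerical rescaling is applied: per-site likelihoods stay well inside
    double range for the cluster sizes this pipeline handles (tens of
    leaves). Ratios of expectations to site likelihoods are therefore exact.
    """
    idx = data.index
    npat = data.n_patterns
    below: dict[int, np.ndarray] = {}
    up: dict[int, np.ndarray] = {}
    pmats: dict[int, np.ndarray] = {}
    for i in idx.postorder:
        if idx.is_leaf(i):
            obs = data.obs[i]
            partial = np.zeros((gc.N_CODONS, npat))
            ok = obs >= 0
            partial[:, ~ok] = 1.0
            partial[obs[ok], np.flatnonzero(ok)] = 1.0
            below[i] = partial
        else:
            partial = np.ones((gc.N_CODONS, npat))
            for child in idx.children[i]:
                partial = partial * up[child]
            below[i] = partial
        if i != idx.root:
            p = gy94.transition_matrix(decomp, lengths[i])
            pmats[i] = p
            up[i] = p @ below[i]
    outside: dict[int, np.ndarray] = {idx.root: np.tile(pi[:, np.newaxis], (1, npat))}
    for i in idx.postorder[::-1]:
        if idx.is_leaf(i):
            continue
        for child in idx.children[i]:
            o = outside[i].copy()
            for sib in idx.children[i]:
                if sib != child:
                    o = o * up[sib]
            outside[child] = o
    site_lik = (pi[:, np.newaxis] * below[idx.root]).sum(axis=0)
    return below, outside, pmats, site_lik


def map_substitutions(
    alignment: CodonAlignment, tree, fit: SiteModelFit
) -> pd.DataFrame:
    """Expected nbNS/nbS per branch under the fitted site-class mixture.

    Counts are computed per site class, weighted by the per-site posterior
    class probabilities implied by the fit, and summed over sites.
    """
    data = lk.PhyloData(alignment, tree)
    idx = data.index
    spec = fit.spec
    pi = fit.pi
    lengths = idx.length * fit.scale
    qs = gy94.mixture_generators(fit.kappa, spec.omegas, spec.weights, pi)

    edges = [int(i) for i in idx.edge_nodes()]
    nb = {lab: {e: np.zeros(data.n_patterns) for e in edges} for lab in ("NS", "S")}
    class_site_lik = np.zeros((len(qs), data.n_patterns))
    ratios = {
        lab: np.zeros((len(qs), len(edges), data.n_patterns)) for lab in ("NS", "S")
    }
    zero_warned = False
    for c, q in enumerate(qs):
        decomp = gy94.spectral(q, pi)
        below, outside, _, site_lik = _class_messages(data, decomp, lengths, pi)
        class_site_lik[c] = site_lik
        safe = np.where(site_lik > 0, site_lik, 1.0)
        for ei, e in enumerate(edges):
            t = lengths[e]
            if t <= 0:
                if not zero_warned and data.n_patterns:
                    zero_warned = True
                continue
            for lab, mask in (("S", gc.SYNONYMOUS), ("NS", gc.NONSYNONYMOUS)):
                j = _labelled_count_integral(decomp, q, mask, t)
                expect = np.einsum(
                    "ip,ij,jp->p", outside[e], j, below[e], optimize=True
                )
                ratios[lab][c, ei] = expect / safe

    weights = spec.weights
    mix = weights[:, np.newaxis] * class_site_lik
    total = mix.sum(axis=0)
    post = mix / np.where(total > 0, total, 1.0)
    rows = []
    for ei, e in enumerate(edges):
        child = idx.node_refs[e]
        child_label = (
            child.taxon.label if child.is_leaf() else f"node{e}"
        )
        parent = idx.parent[e]
        parent_label = "root" if parent == idx.root else f"node{parent}"
        per_site_ns = (post * ratios["NS"][:, ei]).sum(axis=0)
        per_site_s = (post * ratios["S"][:, ei]).sum(axis=0)
        rows.append(
            {
                "branch_id": e,
                "parent_label": parent_label,
                "child_label": child_label,
                "is_internal": not child.is_leaf(),
                "nbNS": float(per_site_ns @ data.pattern_weights),
                "nbS": float(per_site_s @ data.pattern_weights),
            }
        )
    return pd.DataFrame(rows)


def compute_branch_omega(nbNS: float, nbS: float, counts: SiteCounts) -> float:
    """omega = (nbNS / NSsites) / (nbS / Ssites); undefined when nbS = 0."""
    if counts.ns_sites <= 0 or counts.s_sites <= 0:
        raise ValueError("site opportunities must be positive")
    if nbS <= 0:
        raise ValueError("branch omega undefined with nbS = 0")
    return (nbNS / counts.ns_sites) / (nbS / counts.s_sites)


def classify_omega(
    omega: float,
    gt1: float = OMEGA_GT1_THRESHOLD,
    strong: float = OMEGA_STRONG_THRESHOLD,
) -> str:
    """Finest class label: lt1 (omega <= 1), gt1 (1 < omega <= 1.2), gt1_2."""
    if omega > strong:
        return "gt1_2"
    if omega > gt1:
        return "gt1"
    return "lt1"


def branch_table(
    cluster_id: str,
    mapped: pd.DataFrame,
    counts: SiteCounts,
) -> pd.DataFrame:
    """Attach omega, dS and selection class to a mapped branch table."""
    df = mapped.copy()
    df.insert(0, "cluster_id", cluster_id)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (df["nbNS"] / counts.ns_sites) / (df["nbS"] / counts.s_sites)
    df["omega"] = np.where(df["nbS"] > 0, omega, np.nan)
    df["dS"] = df["nbS"] / counts.s_sites
    df["selection_class"] = [
        classify_omega(o) if np.isfinite(o) else "" for o in df["omega"]
    ]
    return df


def filter_and_classify_branches(
    tables: dict[str, pd.DataFrame],
    min_cluster_subs: float = 1.0,
    zero_branch_eps: float = 1e-9,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply the cluster- and branch-level substitution filters.

    Clusters without at least one expected synonymous AND one expected
    nonsynonymous substitution overall are dropped entirely; within kept
    clusters, branches carrying no substitutions, or with undefined omega
    (nbS = 0), are removed. Returns the concatenated kept records and a
    cluster -> reason map for the drops.
    """
    kept = []
    dropped: dict[str, str] = {}
    for cluster_id, df in tables.items():
        tot_ns = df["nbNS"].sum()
        tot_s = df["nbS"].sum()
        if tot_s < min_cluster_subs or tot_ns < min_cluster_subs:
            dropped[cluster_id] = (
                f"cluster-wide substitutions below threshold "
                f"(nbNS={tot_ns:.3g}, nbS={tot_s:.3g})"
            )
            continue
        sub = df[(df["nbNS"] + df["nbS"]) > zero_branch_eps]
        sub = sub[sub["nbS"] > 0]
        kept.append(sub)
    if kept:
        return pd.concat(kept, ignore_index=True), dropped
    cols = ["cluster_id", "branch_id", "parent_label", "child_label",
            "is_internal", "nbNS", "nbS", "omega", "dS", "selection_class"]
    return pd.DataFrame(columns=cols), dropped


def map_cluster(
    cluster_id: str,
    alignment: CodonAlignment,
    tree,
    fit: SiteModelFit,
) -> pd.DataFrame:
    """Convenience wrapper: mapping + site counts + omega/dS/class columns."""
    counts = count_syn_nonsyn_sites(alignment, fit.kappa)
    mapped = map_substitutions(alignment, tree, fit)
    return branch_table(cluster_id, mapped, counts)
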