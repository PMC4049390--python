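"""Felsenstein pruning over the 61 sense-codon states with class mixtures.

The engine binds one alignment to one rooted tree (:class:`PhyloData`),
compresses codon columns into unique site patterns, and evaluates
log-likelihoods for arbitrary (kappa, scale, site-class mixture) settings.
Gaps and N codons are missing data (all-ones partial likelihoods).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from . import gy94
from .qc import CodonAlignment
from .trees import TreeIndex, index_tree


class PhyloData:
    """Alignment/tree binding with site-pattern compression."""

    def __init__(self, alignment: CodonAlignment, tree):
        self.alignment = alignment
        self.index: TreeIndex = index_tree(tree)
        tree_leaves = set(self.index.leaf_index)
        if tree_leaves != set(alignment.ids):
            missing = tree_leaves.symmetric_difference(alignment.ids)
            raise ValueError(f"tree/alignment leaf mismatch: {sorted(missing)}")
        mat = alignment.codon_matrix()
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_of_site = inverse.ravel()
        self.pattern_weights = counts.astype(float)
        self.n_sites = mat.shape[1]
        self.n_patterns = patterns.shape[1]
        # per-node observation rows (leaves only)
        self.obs: dict[int, np.ndarray] = {}
        for row, name in enumerate(alignment.ids):
            self.obs[self.index.leaf_index[name]] = patterns[row]

    def f3x4(self) -> np.ndarray:
        return gy94.f3x4_frequencies(self.alignment.codon_matrix())

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector back onto alignment sites."""
        return per_pattern[..., self.pattern_of_site]


def _leaf_message(p: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """P[:, obs] with missing data (-1) giving all-ones columns."""
    u = p[:, np.where(obs >= 0, obs, 0)]
    if (obs < 0).any():
        u = u.copy()
        u[:, obs < 0] = 1.0
    return u


def _prune_class(
    data: PhyloData, decomp, lengths: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Per-pattern log site likelihood for one site class."""
    idx = data.index
    pending: dict[int, np.ndarray] = {}
    logscale = np.zeros(data.n_patterns)
    root_partial = None
    for i in idx.postorder:
        if idx.is_leaf(i):
            p = gy94.transition_matrix(decomp, lengths[i])
            pending[i] = _leaf_message(p, data.obs[i])
            continue
        partial = pending.pop(idx.children[i][0])
        for child in idx.children[i][1:]:
            partial = partial * pending.pop(child)
        scale = partial.max(axis=0)
        scale[scale == 0.0] = 1.0
        partial = partial / scale
        logscale += np.log(scale)
        if i == idx.root:
            root_partial = partial
        else:
            p = gy94.transition_matrix(decomp, lengths[i])
            pending[i] = p @ partial
    site_lik = pi @ root_partial
    return np.log(site_lik) + logscale


def class_pattern_loglikes(
    data: PhyloData,
    kappa: float,
    scale: float,
    omegas: np.ndarray,
    weights: np.ndarray,
    pi: np.ndarray,
) -> np.ndarray:
    """(n_classes, n_patterns) log site likelihoods, one row per class."""
    qs = gy94.mixture_generators(kappa, omegas, weights, pi)
    lengths = data.index.length * scale
    out = np.empty((len(qs), data.n_patterns))
    for c, q in enumerate(qs):
        decomp = gy94.spectral(q, pi)
        out[c] = _prune_class(data, decomp, lengths, pi)
    return out


def mixture_pattern_loglikes(
    class_loglikes: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    return logsumexp(
        class_loglikes[keep] + np.log(w[keep])[:, np.newaxis], axis=0
    )


def log_likelihood(
    data: PhyloData,
    kappa: float,
    scale: float,
    spec,
    pi: np.ndarray,
) -> float:
    """Total alignment log-likelihood under a site-class mixture."""
    cls = class_pattern_loglikes(data, kappa, scale, spec.omegas, spec.weights, pi)
    mix = mixture_pattern_loglikes(cls, spec.weights)
    return float(np.dot(data.pattern_weights, mix))


def class_posteriors(
    class_loglikes: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """(n_classes, n_patterns) posterior class membership; columns sum to 1."""
    w = np.asarray(weights, dtype=float)
    logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    joint = class_loglikes + logw[:, np.newaxis]
    return np.exp(joint - logsumexp(joint, axis=0))
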