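"""Goldman-Yang codon substitution model (61 sense-codon states).

Rate matrices are parameterised by the transition/transversion ratio kappa,
the nonsynonymous/synonymous rate ratio omega and the stationary codon
frequencies pi. Stop codons are excluded from the state space entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geneticcode as gc


@dataclass
class Gy94Params:
    """GY94 parameters; pi defaults to uniform over the 61 sense codons."""

    kappa: float = 2.0
    omega: float = 1.0
    pi: np.ndarray = field(
        default_factory=lambda: np.full(gc.N_CODONS, 1.0 / gc.N_CODONS)
    )

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.pi.shape != (gc.N_CODONS,):
            raise ValueError("pi must have 61 entries")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be a probability vector")


def _raw_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalised GY94 generator: q_ij = pi_j * kappa^ts * omega^nonsyn."""
    q = np.where(gc.TRANSITION, kappa, 1.0) * np.where(
        gc.NONSYNONYMOUS, omega, 1.0
    )
    q = np.where(gc.SINGLE_NT, q, 0.0) * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per site per unit time at stationarity."""
    return float(-np.dot(pi, np.diag(q)))


def build_generator(
    kappa: float, omega: float, pi: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """61x61 GY94 rate matrix, normalised to mean rate 1 at stationarity."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("pi must be strictly positive over the 61 codons")
    q = _raw_generator(kappa, omega, pi)
    if normalize:
        q = q / stationary_rate(q, pi)
    return q


def mixture_generators(
    kappa: float,
    omegas: Sequence[float],
    weights: Sequence[float],
    pi: np.ndarray,
) -> list[np.ndarray]:
    """One generator per site class, jointly normalised.

    A single scale factor is applied to all classes so the weight-averaged
    stationary rate equals 1; relative rates between classes are preserved
    (high-omega classes evolve faster per unit branch length).
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("pi must be strictly positive over the 61 codons")
    weights = np.asarray(weights, dtype=float)
    qs = [_raw_generator(kappa, w, pi) for w in omegas]
    mu = sum(wt * stationary_rate(q, pi) for wt, q in zip(weights, qs))
    return [q / mu for q in qs]


def spectral(q: np.ndarray, pi: np.ndarray):
    """Symmetric eigendecomposition of a reversible generator.

    Returns (eigenvalues, V, sqrt_pi) with
    P(t) = diag(1/sqrt_pi) @ V @ diag(exp(w t)) @ V.T @ diag(sqrt_pi).
    """
    d = np.sqrt(pi)
    b = q * d[:, np.newaxis] / d[np.newaxis, :]
    b = 0.5 * (b + b.T)  # symmetrise away rounding noise
    w, v = np.linalg.eigh(b)
    return w, v, d


def transition_matrix(spec, t: float) -> np.ndarray:
    """P(t) from a :func:`spectral` decomposition; rows sum to 1."""
    w, v, d = spec
    p = (v * np.exp(w * t)) @ v.T
    p = p / d[:, np.newaxis] * d[np.newaxis, :]
    np.clip(p, 0.0, None, out=p)
    return p


def f3x4_frequencies(codon_columns: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies from observed codon indices.

    `codon_columns` is an integer array of sense-codon indices (missing data
    as -1). Nucleotide frequencies are tallied per codon position with a
    small pseudocount so no sense codon gets zero frequency; stop codons are
    excluded and the result renormalised.
    """
    obs = codon_columns[codon_columns >= 0]
    counts = np.full((3, 4), pseudocount)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for idx in obs.ravel():
        codon = gc.CODONS[idx]
        for pos in range(3):
            counts[pos, order[codon[pos]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(gc.N_CODONS)
    for i, codon in enumerate(gc.CODONS):
        pi[i] = np.prod([freqs[pos, order[codon[pos]]] for pos in range(3)])
    return pi / pi.sum()
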