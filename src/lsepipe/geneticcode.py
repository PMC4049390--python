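"""Standard genetic code tables for the 61 sense codons.

Everything downstream (rate matrices, site counting, substitution labelling,
simulation) indexes codons by their position in :data:`CODONS`, which lists
the sense codons of the standard nuclear code in lexicographic order
(stop codons TAA, TAG, TGA excluded).
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "TCAG"

_CODON_TABLE_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

ALL_CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
CODON_TO_AA = dict(zip(ALL_CODONS, _CODON_TABLE_AA))
STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")

#: the 61 sense codons, sorted alphabetically (A < C < G < T)
CODONS = sorted(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

AMINO_ACIDS = np.array([CODON_TO_AA[c] for c in CODONS])

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def _build_pair_tables():
    """Boolean 61x61 tables for single-nucleotide codon pairs."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    synonymous = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return single, transition, synonymous


SINGLE_NT, TRANSITION, SYNONYMOUS = _build_pair_tables()
NONSYNONYMOUS = SINGLE_NT & ~SYNONYMOUS


def _build_mutation_tables():
    """Per-codon enumeration of the 9 single-nucleotide mutations.

    Returns (targets, syn, ts) of shape (61, 9); targets is the sense-codon
    index of the mutated codon or -1 when the mutation creates a stop.
    """
    targets = np.full((N_CODONS, 9), -1, dtype=np.int64)
    syn = np.zeros((N_CODONS, 9), dtype=bool)
    ts = np.zeros((N_CODONS, 9), dtype=bool)
    for i, codon in enumerate(CODONS):
        m = 0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1:]
                ts[i, m] = is_transition(codon[pos], nt)
                if mutant not in STOP_CODONS:
                    j = CODON_INDEX[mutant]
                    targets[i, m] = j
                    syn[i, m] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
                m += 1
    return targets, syn, ts


MUTATION_TARGETS, MUTATION_SYN, MUTATION_TS = _build_mutation_tables()


def encode_codon(codon: str) -> int:
    """Sense-codon index, or -1 for codons containing gaps/N (missing data).

    Raises ValueError for stop codons and for characters outside {A,C,G,T,N,-}.
    """
    codon = codon.upper()
    if any(ch in "N-" for ch in codon):
        return -1
    if any(ch not in "ACGT" for ch in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} in alignment")
    return CODON_INDEX[codon]
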