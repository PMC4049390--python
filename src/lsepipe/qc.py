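"""CDS validity checks and alignment cleaning.

Implements the pre-model filters: whole-cluster rejection on internal stop
codons or lengths not divisible by three, codon-column cleaning from an
external per-column reliability mask (or a built-in gap-fraction fallback),
and the post-cleaning minimum-sequence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import geneticcode as gc

_VALID_CHARS = frozenset("ACGTN-")


@dataclass
class CodonAlignment:
    """A codon-aware nucleotide alignment over {A,C,G,T,N,-}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("sequences are not all the same length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_codons(self) -> int:
        if self.n_cols % 3:
            raise ValueError("alignment length not divisible by 3")
        return self.n_cols // 3

    def codon_matrix(self) -> np.ndarray:
        """(n_seqs, n_codons) sense-codon indices; -1 marks missing data."""
        mat = np.empty((self.n_seqs, self.n_codons), dtype=np.int64)
        for i, seq in enumerate(self.seqs):
            for j in range(self.n_codons):
                mat[i, j] = gc.encode_codon(seq[3 * j: 3 * j + 3])
        return mat

    def take_codon_columns(self, keep: np.ndarray) -> "CodonAlignment":
        keep = np.asarray(keep)
        new = []
        for seq in self.seqs:
            codons = [seq[3 * j: 3 * j + 3] for j in range(self.n_codons)]
            new.append("".join(codons[j] for j in np.flatnonzero(keep)))
        return CodonAlignment(ids=list(self.ids), seqs=new)

    def subset(self, ids: list[str]) -> "CodonAlignment":
        pos = {s: i for i, s in enumerate(self.ids)}
        return CodonAlignment(
            ids=list(ids), seqs=[self.seqs[pos[s]] for s in ids]
        )


@dataclass
class CleaningConfig:
    column_cutoff: float = 0.97      # applied to external mask scores only
    gap_fraction_cutoff: float = 0.5  # built-in fallback filter
    min_sequences: int = 4

    def __post_init__(self):
        for v in (self.column_cutoff, self.gap_fraction_cutoff):
            if not 0.0 <= v <= 1.0:
                raise ValueError("cutoffs must lie in [0, 1]")


@dataclass
class ValidationResult:
    ok: bool
    reasons: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def _internal_stop(seq: str) -> bool:
    return any(
        seq[i: i + 3] in gc.STOP_CODONS for i in range(0, len(seq) - 3, 3)
    )


def validate_cds_cluster(sequences: dict[str, str]) -> ValidationResult:
    """Accept or reject a whole cluster of (unaligned) CDS sequences.

    Rejection reasons: length not divisible by three, internal stop codon,
    characters outside {A,C,G,T,N}. Terminal stop codons are stripped and
    are not fatal. The cluster is rejected if any one sequence fails.
    """
    if not sequences:
        raise ValueError("empty cluster")
    reasons = []
    cleaned = {}
    for name, seq in sequences.items():
        seq = seq.upper()
        bad = set(seq) - frozenset("ACGTN")
        if bad:
            reasons.append(f"{name}: non-nucleotide characters {sorted(bad)}")
            continue
        if len(seq) % 3:
            reasons.append(f"{name}: length not divisible by three")
            continue
        if _internal_stop(seq):
            reasons.append(f"{name}: internal stop codon")
            continue
        if seq[-3:] in gc.STOP_CODONS:
            seq = seq[:-3]
        cleaned[name] = seq
    if reasons:
        return ValidationResult(ok=False, reasons=reasons)
    return ValidationResult(ok=True, sequences=cleaned)


def _codon_scores_from_mask(mask: np.ndarray, n_codons: int) -> np.ndarray:
    """Per-codon reliability: accepts one score per codon or per nt column."""
    mask = np.asarray(mask, dtype=float)
    if mask.shape == (n_codons,):
        return mask
    if mask.shape == (3 * n_codons,):
        return mask.reshape(n_codons, 3).min(axis=1)
    raise ValueError(
        f"mask length {mask.size} matches neither {n_codons} codon columns "
        f"nor {3 * n_codons} nucleotide columns"
    )


def clean_alignment(
    alignment: CodonAlignment,
    mask: np.ndarray | None = None,
    config: CleaningConfig | None = None,
) -> CodonAlignment:
    """Drop unreliable codon columns.

    With an external mask, codon columns scoring below ``column_cutoff`` are
    removed. Without one, the fallback drops codon columns whose gap
    fraction exceeds ``gap_fraction_cutoff``. Columns are always removed in
    whole codons; sequences are never edited otherwise.
    """
    config = config or CleaningConfig()
    n = alignment.n_codons
    if mask is not None:
        scores = _codon_scores_from_mask(mask, n)
        keep = scores >= config.column_cutoff
    else:
        gap_frac = np.empty(n)
        for j in range(n):
            codons = [s[3 * j: 3 * j + 3] for s in alignment.seqs]
            gap_frac[j] = sum("-" in c for c in codons) / max(len(codons), 1)
        keep = gap_frac <= config.gap_fraction_cutoff
    if keep.all():
        return alignment
    return alignment.take_codon_columns(keep)


def apply_min_size(alignment: CodonAlignment, min_sequences: int = 4) -> bool:
    """True when the cluster keeps at least ``min_sequences`` sequences."""
    return alignment.n_seqs >= min_sequences


def read_column_mask(path) -> np.ndarray:
    """Whitespace-separated per-column reliability scores."""
    with open(path) as fh:
        return np.array([float(tok) for tok in fh.read().split()])
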