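"""Goldman-Yang codon substitution machinery (61 sense codons).

The instantaneous rate between codons differing at exactly one nucleotide is
``pi_j * kappa^[transition] * omega^[nonsynonymous]``; codons differing at
more than one position do not exchange directly.  The generator is scaled so
the mean substitution rate at stationarity is 1, making branch lengths
expected substitutions per codon.  Codon frequencies may be equal, F1x4
(from nucleotide frequencies) or F3x4 (position-specific nucleotide
frequencies), estimated from the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "CodonAlignment",
    "CodonModelParams",
    "codon_Q",
    "codon_frequencies",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard code
_NUC = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _NUC
    for b in _NUC
    for c in _NUC
    if a + b + c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def _single_diff_tables():
    n = len(CODONS)
    ii, jj, ts, ns = [], [], [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [k for k in range(3) if CODONS[i][k] != CODONS[j][k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            a, b = CODONS[i][k], CODONS[j][k]
            ii.append(i)
            jj.append(j)
            ts.append((a in _PURINES) == (b in _PURINES))
            ns.append(AMINO_ACIDS[i] != AMINO_ACIDS[j])
    return (
        np.array(ii), np.array(jj),
        np.array(ts, dtype=bool), np.array(ns, dtype=bool),
    )


_I, _J, _IS_TS, _IS_NONSYN = _single_diff_tables()


def codon_Q(kappa: float, omega: float, freqs: np.ndarray, scale: bool = True) -> np.ndarray:
    """61x61 generator: ``q_ij = pi_j * kappa^[ts] * omega^[nonsyn]``.

    Rows sum to zero; with ``scale`` the mean rate at stationarity is 1 so
    that branch lengths are substitutions per codon.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (61,) or abs(freqs.sum() - 1.0) > 1e-8 or np.any(freqs < 0):
        raise ValueError("freqs must be a 61-codon probability vector")
    Q = np.zeros((61, 61))
    rates = freqs[_J] * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    Q[_I, _J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -float(freqs @ np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def substitution_flows(kappa: float, omega: float, freqs: np.ndarray) -> tuple[float, float]:
    """(nonsynonymous, synonymous) shares of the substitution flow at
    stationarity for an unscaled generator with these parameters."""
    freqs = np.asarray(freqs, dtype=float)
    rates = freqs[_I] * freqs[_J] * np.where(_IS_TS, kappa, 1.0)
    rates = rates * np.where(_IS_NONSYN, omega, 1.0)
    nonsyn = float(rates[_IS_NONSYN].sum())
    syn = float(rates[~_IS_NONSYN].sum())
    return nonsyn, syn


def codon_frequencies(model: str, seqs: list[str]) -> np.ndarray:
    """Stationary codon frequencies under 'equal', 'F1x4' or 'F3x4'.

    F1x4 uses overall nucleotide frequencies, F3x4 codon-position-specific
    ones; stop codons are excised and the vector renormalized.  Gap
    characters are ignored.
    """
    if model == "equal":
        return np.full(61, 1.0 / 61)
    counts = np.zeros((3, 4))
    for seq in seqs:
        for pos in range(0, len(seq) - 2, 3):
            codon = seq[pos : pos + 3].upper()
            for k, ch in enumerate(codon):
                if ch in _NUC:
                    counts[k, _NUC.index(ch)] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides for frequency estimation")
    if model == "F1x4":
        nt = counts.sum(axis=0)
        nt = nt / nt.sum()
        pos_freq = np.tile(nt, (3, 1))
    elif model == "F3x4":
        pos_freq = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown frequency model {model!r}")
    freqs = np.array(
        [
            pos_freq[0, _NUC.index(c[0])]
            * pos_freq[1, _NUC.index(c[1])]
            * pos_freq[2, _NUC.index(c[2])]
            for c in CODONS
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("degenerate codon frequencies")
    return freqs / total


@dataclass(frozen=True)
class CodonModelParams:
    """Parameters of a branch-class codon model.

    ``omega`` maps a branch-class label to its dN/dS ratio; ``branch_classes``
    maps a branch (identified by its child node) to a class label.  ``freqs``
    is the 61-codon stationary distribution.
    """

    kappa: float
    omega: dict[str, float]
    freqs: np.ndarray
    freq_model: str = "F3x4"
    branch_classes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for label, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega[{label!r}] must be >= 0")


class CodonAlignment:
    """In-frame aligned coding sequences over {A,C,G,T,-}.

    Validates equal lengths, length divisible by 3, and the absence of
    internal stop codons in ungapped codons.
    """

    def __init__(self, sequences: dict[str, str]):
        if len(sequences) < 2:
            raise ValueError("need at least two sequences")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned to equal length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.length = length
        for name, seq in self.sequences.items():
            n_codons = length // 3
            for pos in range(n_codons):
                codon = seq[3 * pos : 3 * pos + 3]
                if codon in STOP_CODONS and pos < n_codons - 1:
                    raise ValueError(
                        f"internal stop codon {codon} at codon {pos} in {name}"
                    )

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")

    def encode(self, species_order: list[str]) -> tuple[np.ndarray, list[int]]:
        """Codon-index matrix (n_species, n_used_codons) plus dropped columns.

        Columns containing a gap or ambiguous codon in any sequence are
        dropped alignment-wide (the dropped column indices are returned);
        terminal stop codons are likewise excluded.
        """
        n = self.n_codons
        mat = np.full((len(species_order), n), -1, dtype=int)
        for r, sp in enumerate(species_order):
            seq = self.sequences[sp]
            for c in range(n):
                codon = seq[3 * c : 3 * c + 3]
                mat[r, c] = CODON_INDEX.get(codon, -1)
        good = np.all(mat >= 0, axis=0)
        dropped = [int(c) for c in np.nonzero(~good)[0]]
        return mat[:, good], dropped
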