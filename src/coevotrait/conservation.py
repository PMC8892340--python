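"""Residue conservation scoring by Jensen-Shannon divergence.

Each alignment column's amino-acid distribution is compared against a
background distribution (by default the one implied by the BLOSUM62
substitution matrix) with the base-2 Jensen-Shannon divergence, which is
symmetric and bounded in [0, 1].  Columns with more than a gap-fraction
cutoff (30%) are ignored and scored exactly 0; otherwise the divergence is
down-weighted by the gap fraction.  A sliding window then mixes each
position's score with the mean of its scored neighbours so runs of
conserved residues reinforce one another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ConservationConfig",
    "ProteinAlignment",
    "blosum62_background",
    "js_divergence",
    "column_score",
    "profile",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")


def blosum62_background() -> np.ndarray:
    """The 20-residue background distribution shipped with the package."""
    with resources.files("coevotrait.data").joinpath(
        "blosum62_background.json"
    ).open() as fh:
        data = json.load(fh)
    freqs = np.array([data["frequencies"][a] for a in AMINO_ACIDS])
    return freqs / freqs.sum()


@dataclass
class ConservationConfig:
    """Scoring knobs.

    window_radius counts positions to each side (default 3); window_weight
    is the mixing weight lambda_w of the neighbourhood mean (default 0.5);
    gap_cutoff is the gap fraction above which a column is ignored (0.30);
    pseudocount avoids log(0) in sparse columns.
    """

    background: np.ndarray = field(default_factory=blosum62_background)
    window_radius: int = 3
    window_weight: float = 0.5
    gap_cutoff: float = 0.30
    pseudocount: float = 1e-7

    def __post_init__(self):
        b = np.asarray(self.background, dtype=float)
        if b.shape != (20,) or abs(b.sum() - 1.0) > 1e-8:
            raise ValueError("background must be a 20-residue distribution")
        if not 0 < self.gap_cutoff < 1:
            raise ValueError("gap_cutoff must be in (0, 1)")
        if not 0 <= self.window_weight <= 1:
            raise ValueError("window_weight must be in [0, 1]")


class ProteinAlignment:
    """Equal-length aligned amino-acid sequences (gaps allowed)."""

    def __init__(self, sequences: dict[str, str]):
        if len(sequences) < 2:
            raise ValueError("need at least two sequences")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal aligned length")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        (self.length,) = lengths

    @classmethod
    def from_file(cls, path: str | Path, fmt: str = "fasta") -> "ProteinAlignment":
        if fmt == "clustal":
            aln = AlignIO.read(str(path), "clustal")
            return cls({rec.id: str(rec.seq) for rec in aln})
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), fmt)})

    def columns(self) -> list[str]:
        seqs = list(self.sequences.values())
        return ["".join(s[i] for s in seqs) for i in range(self.length)]


def js_divergence(p, q) -> float:
    """Base-2 Jensen-Shannon divergence between two distributions in [0, 1].

    JS(p, q) = KL(p || m)/2 + KL(q || m)/2 with m = (p + q)/2 and logs base
    2, so identical distributions score 0 and disjoint ones score 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a normalized distribution")
    m = (p + q) / 2.0
    def kl(a):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))
    return 0.5 * kl(p) + 0.5 * kl(q)


def _column_distribution(column: str, pseudocount: float) -> tuple[np.ndarray, float]:
    counts = np.zeros(20)
    gaps = 0
    for ch in column:
        if ch in GAP_CHARS:
            gaps += 1
        elif ch in _AA_INDEX:
            counts[_AA_INDEX[ch]] += 1
        else:  # unknown residue (X etc.): ignored like a gap but not counted
            gaps += 1
    gap_fraction = gaps / len(column)
    total = counts.sum()
    if total == 0:
        return np.full(20, 1.0 / 20), gap_fraction
    dist = (counts + pseudocount) / (total + 20 * pseudocount)
    return dist, gap_fraction


def _base_and_mask(column: str, config: ConservationConfig) -> tuple[float, bool]:
    dist, gap_fraction = _column_distribution(column, config.pseudocount)
    if gap_fraction > config.gap_cutoff:
        return 0.0, True
    return (1.0 - gap_fraction) * js_divergence(dist, config.background), False


def column_score(column: str, config: ConservationConfig | None = None) -> float:
    """Gap-weighted JS divergence of one column against the background.

    Columns whose gap fraction exceeds the cutoff score exactly 0;
    otherwise the score is ``(1 - gap_fraction) * JS(column, background)``.
    """
    config = config or ConservationConfig()
    return _base_and_mask(column, config)[0]


def profile(
    alignment: ProteinAlignment, config: ConservationConfig | None = None
) -> np.ndarray:
    """Windowed conservation score per alignment position.

    score_i = (1 - lambda_w) * base_i + lambda_w * mean(base_j, j in window),
    where the window spans ``window_radius`` positions each side of i
    (excluding i itself) and only positions with base score > 0 contribute
    to the mean.  Positions zeroed by the gap rule stay exactly 0 and never
    contribute to a neighbour's window mean.
    """
    config = config or ConservationConfig()
    scored = [_base_and_mask(col, config) for col in alignment.columns()]
    base = np.array([s for s, _ in scored])
    gap_masked = np.array([m for _, m in scored])
    lam = config.window_weight
    if lam == 0 or config.window_radius == 0:
        return base
    out = np.zeros_like(base)
    n = len(base)
    r = config.window_radius
    for i in range(n):
        if gap_masked[i]:
            continue
        lo, hi = max(0, i - r), min(n, i + r + 1)
        neighbours = [
            base[j]
            for j in range(lo, hi)
            if j != i and not gap_masked[j] and base[j] > 0
        ]
        window_mean = float(np.mean(neighbours)) if neighbours else base[i]
        out[i] = (1.0 - lam) * base[i] + lam * window_mean
    return out


def profile_table(alignment: ProteinAlignment, config: ConservationConfig | None = None):
    """Per-position TSV-ready table: position, gap fraction, base, windowed."""
    import pandas as pd

    config = config or ConservationConfig()
    cols = alignment.columns()
    base = np.array([column_score(c, config) for c in cols])
    windowed = profile(alignment, config)
    gaps = [
        sum(1 for ch in c if ch in GAP_CHARS or ch not in _AA_INDEX) / len(c)
        for c in cols
    ]
    return pd.DataFrame(
        {
            "position": np.arange(1, len(cols) + 1),
            "gap_fraction": gaps,
            "base_score": base,
            "windowed_score": windowed,
        }
    )
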