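"""Amino-acid alphabet, substitution scoring and shared numeric constants.

The 20-letter alphabet is kept in a fixed alphabetical order so that every
matrix in the package indexes residues identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP = "-"

# Robinson & Robinson amino-acid background frequencies (the BLAST default),
# normalised to sum to 1 in AA order.
_ROBINSON = {
    "A": 78.05, "C": 19.25, "D": 53.64, "E": 62.95, "F": 38.56,
    "G": 73.77, "H": 21.99, "I": 51.42, "K": 57.44, "L": 90.19,
    "M": 22.43, "N": 44.87, "P": 52.03, "Q": 42.64, "R": 51.29,
    "S": 71.20, "T": 58.41, "V": 64.41, "W": 13.30, "Y": 32.16,
}


def background_frequencies() -> np.ndarray:
    """Background residue frequencies in AA order (sum to 1)."""
    v = np.array([_ROBINSON[a] for a in AA], dtype=float)
    return v / v.sum()


@dataclass(frozen=True)
class ScoringMatrix:
    """20x20 integer substitution scores with affine gap penalties.

    A gap of length ``k`` costs ``gap_open + (k - 1) * gap_extend``.
    Unknown residues ('X') score 0 against everything.
    """

    scores: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    name: str = "custom"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (20, 20):
            raise ValueError("scores must be 20x20")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        object.__setattr__(self, "scores", s.astype(np.int64))

    def score(self, a: str, b: str) -> int:
        ia = AA_INDEX.get(a)
        ib = AA_INDEX.get(b)
        if ia is None or ib is None:
            return 0
        return int(self.scores[ia, ib])

    def encode(self, seq: str) -> np.ndarray:
        """Integer-encode a sequence; unknown residues map to -1."""
        return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)

    def score_profile(self, seq: str) -> np.ndarray:
        """(len(seq), 20) score rows; unknown residues give all-zero rows."""
        idx = self.encode(seq)
        rows = np.zeros((len(seq), 20), dtype=np.int64)
        known = idx >= 0
        rows[known] = self.scores[idx[known]]
        return rows


def blosum62(gap_open: int = 11, gap_extend: int = 1) -> ScoringMatrix:
    """The standard BLOSUM62 matrix restricted to the 20 canonical residues."""
    m = substitution_matrices.load("BLOSUM62")
    s = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            s[i, j] = int(m[a, b])
    return ScoringMatrix(s, gap_open=gap_open, gap_extend=gap_extend, name="BLOSUM62")


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component generator derived from (seed, label)."""
    return np.random.default_rng([seed & 0xFFFFFFFF, zlib.crc32(label.encode())])
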