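"""Column conservation scoring (single- and two-group) and the AIM/sAIM
motif grammar: scanning, point mutation and sAIM-to-cAIM conversion.

Motif grammar: the canonical ATG8-interacting motif (cAIM) is the 4-mer
[WFY]xx[LIV]; the shuffled AIM (sAIM) is I[DS]W[GD]. Overlapping hits are
all reported.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alphabet import AA, AA_INDEX, GAP, ScoringMatrix, blosum62
from .msa_processing import GroupedMSA, henikoff_weights

CAIM_REGEX = re.compile(r"(?=([WFY]..[LIV]))")
SAIM_REGEX = re.compile(r"(?=(I[DS]W[GD]))")


@dataclass
class MotifHit:
    """A motif occurrence with 1-based inclusive coordinates."""

    pattern: str          # "cAIM" | "sAIM"
    seq_id: str
    start: int
    end: int
    matched: str


@dataclass
class ColumnScoreTrack:
    """Per-column scores over the retained alignment columns (1-based)."""

    columns: List[int]
    scores: List[float]
    flags: List[bool]                      # True = flagged-missing
    bins: Optional[List[int]] = None       # 1..9, 9 = most conserved
    group_sizes: Tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        data = {"column": self.columns, "score": self.scores, "flag": self.flags}
        if self.bins is not None:
            data["bin"] = self.bins
        return pd.DataFrame(data)


def _weighted_column_freqs(msa: GroupedMSA, c: int,
                           weights: np.ndarray) -> Tuple[np.ndarray, float]:
    """Weighted residue frequencies of column c (gaps excluded).

    Returns (20-vector summing to 1 or all-zero, non-gap weight fraction).
    """
    f = np.zeros(20)
    total = 0.0
    for row, w in zip(msa.rows, weights):
        ch = row[c]
        if ch == GAP:
            continue
        k = AA_INDEX.get(ch)
        if k is not None:
            f[k] += w
            total += w
    if total > 0:
        f = f / total
    return f, total


def twogroup_score(msa: GroupedMSA, matrix: Optional[ScoringMatrix] = None,
                   group_a: Optional[str] = None, group_b: Optional[str] = None,
                   ) -> ColumnScoreTrack:
    """Expected between-group substitution score per column.

    TC(c) = sum_{a,b} fA(a) fB(b) S(a,b) over Henikoff-weighted, gap-excluded
    residue frequencies of the two groups. Columns where either group is
    all-gap are flagged. Negative values mark columns where the two groups
    have diverged onto dissimilar residues.
    """
    if matrix is None:
        matrix = blosum62()
    if not msa.groups:
        raise ValueError("alignment has no group labels")
    labels = sorted(set(msa.groups.values()))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError("need exactly two groups (or pass group_a/group_b)")
        group_a, group_b = labels
    sub_a = henikoff_weights(msa.group_rows(group_a))
    sub_b = henikoff_weights(msa.group_rows(group_b))
    if sub_a.n_rows == 0 or sub_b.n_rows == 0:
        raise ValueError("both groups must be non-empty")
    S = matrix.scores.astype(float)
    columns, scores, flags = [], [], []
    for c in range(msa.n_columns):
        fa, occ_a = _weighted_column_freqs(sub_a, c, sub_a.weights)
        fb, occ_b = _weighted_column_freqs(sub_b, c, sub_b.weights)
        columns.append(c + 1)
        if occ_a == 0.0 or occ_b == 0.0:
            scores.append(math.nan)
            flags.append(True)
        else:
            scores.append(float(fa @ S @ fb))
            flags.append(False)
    return ColumnScoreTrack(columns=columns, scores=scores, flags=flags,
                            group_sizes=(sub_a.n_rows, sub_b.n_rows))


def column_conservation(msa: GroupedMSA, matrix: Optional[ScoringMatrix] = None,
                        n_bins: int = 9) -> ColumnScoreTrack:
    """Single-group expected pair score per column, with 1-9 rank bins.

    Bins are an equal-frequency partition of the retained columns by score
    rank (ties broken by column index; 9 = most conserved). This is a
    simplified stand-in for phylogenetic rate-based conservation scales.
    """
    if matrix is None:
        matrix = blosum62()
    if msa.n_rows < 2:
        raise ValueError("need at least two rows")
    w = henikoff_weights(msa)
    S = matrix.scores.astype(float)
    columns, scores, flags = [], [], []
    for c in range(msa.n_columns):
        f, occ = _weighted_column_freqs(w, c, w.weights)
        columns.append(c + 1)
        if occ == 0.0:
            scores.append(math.nan)
            flags.append(True)
        else:
            scores.append(float(f @ S @ f))
            flags.append(False)
    scored = [(s, c) for s, c, fl in zip(scores, columns, flags) if not fl]
    order = sorted(range(len(scored)), key=lambda k: (scored[k][0], scored[k][1]))
    n = len(scored)
    bin_of: Dict[int, int] = {}
    for rank, k in enumerate(order):
        bin_of[scored[k][1]] = 1 + min(n_bins - 1, rank * n_bins // max(n, 1))
    bins = [bin_of.get(c, 0) for c in columns]
    return ColumnScoreTrack(columns=columns, scores=scores, flags=flags,
                            bins=bins, group_sizes=(msa.n_rows,))


def logo_counts(msa: GroupedMSA) -> pd.DataFrame:
    """Henikoff-weighted per-column frequencies with information content.

    IC(c) = log2(20) - H(c), H the Shannon entropy of the weighted residue
    frequencies; gaps are excluded from frequencies and reported as
    occupancy. All-gap columns have NaN IC.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    w = henikoff_weights(msa)
    records = []
    for c in range(msa.n_columns):
        f, occ = _weighted_column_freqs(w, c, w.weights)
        if occ == 0.0:
            ic = math.nan
        else:
            nz = f[f > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
            ic = math.log2(20) - entropy
        rec = {"column": c + 1, "occupancy": occ, "ic": ic}
        rec.update({AA[k]: f[k] for k in range(20)})
        records.append(rec)
    return pd.DataFrame(records)


def _scan(seq: str, seq_id: str, regex: re.Pattern, pattern: str) -> List[MotifHit]:
    hits = []
    for m in regex.finditer(seq):
        start = m.start() + 1
        hits.append(MotifHit(pattern=pattern, seq_id=seq_id, start=start,
                             end=start + 3, matched=m.group(1)))
    return hits


def scan_caim(seq: str, seq_id: str = "seq") -> List[MotifHit]:
    """All (possibly overlapping) canonical AIM 4-mers [WFY]xx[LIV]."""
    return _scan(seq, seq_id, CAIM_REGEX, "cAIM")


def scan_saim(seq: str, seq_id: str = "seq") -> List[MotifHit]:
    """All shuffled-AIM 4-mers I[DS]W[GD]."""
    return _scan(seq, seq_id, SAIM_REGEX, "sAIM")


def saim_to_caim(seq: str, site_start: int) -> str:
    """Reorder the sAIM at ``site_start`` (1-based) into a canonical AIM.

    x1 x2 x3 x4 -> x3 x2 x4 x1, i.e. IDWD -> WDDI and IDWG -> WDGI.
    """
    i = site_start - 1
    if i < 0 or i + 4 > len(seq):
        raise ValueError("site out of range")
    site = seq[i: i + 4]
    if not re.fullmatch(r"I[DS]W[GD]", site):
        raise ValueError(f"4-mer {site!r} at {site_start} is not a sAIM")
    x1, x2, x3, x4 = site
    return seq[:i] + x3 + x2 + x4 + x1 + seq[i + 4:]


def mutate_motif(seq: str, position: int, to: str) -> str:
    """Single-residue substitution at a 1-based position."""
    if not 1 <= position <= len(seq):
        raise ValueError("position out of range")
    if len(to) != 1 or to not in AA:
        raise ValueError("replacement must be a single canonical residue")
    return seq[: position - 1] + to + seq[position:]


def apply_mutations(seq: str, mutations: Sequence[Tuple[int, str]]) -> str:
    """Apply several point mutations, e.g. the multi-Trp inactivation sets."""
    for position, to in mutations:
        seq = mutate_motif(seq, position, to)
    return seq


def motif_hits_to_bed(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """BED-like frame: 0-based half-open start, 1-based end."""
    return pd.DataFrame(
        [{"seq_id": h.seq_id, "start": h.start - 1, "end": h.end,
          "pattern": h.pattern, "matched": h.matched} for h in hits],
        columns=["seq_id", "start", "end", "pattern", "matched"])
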