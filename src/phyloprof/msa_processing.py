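"""Multiple alignment construction and the trimming / filtering rules.

Alignments are built progressively: a neighbor-joining guide tree from
pairwise global-alignment distances, then profile-profile global alignment
up the guide tree. Column trimming retains columns whose non-gap fraction
meets the gap threshold (the trimAl -gt convention), and the fragment
filter drops rows with too little data over the retained columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alphabet import AA, AA_INDEX, GAP, ScoringMatrix, blosum62


@dataclass
class GroupedMSA:
    """A multiple alignment with optional per-row group labels and weights."""

    ids: List[str]
    rows: List[str]
    groups: Optional[Dict[str, str]] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be positive and sum to 1")
            self.weights = w

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    def row_non_gap_fraction(self, i: int) -> float:
        row = self.rows[i]
        return 1.0 - row.count(GAP) / len(row) if row else 0.0

    def column_non_gap_fraction(self, c: int) -> float:
        col = self.column(c)
        return 1.0 - col.count(GAP) / len(col)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def subset(self, ids: Sequence[str]) -> "GroupedMSA":
        keep = set(ids)
        new_ids, new_rows = [], []
        for sid, row in zip(self.ids, self.rows):
            if sid in keep:
                new_ids.append(sid)
                new_rows.append(row)
        groups = {k: v for k, v in (self.groups or {}).items() if k in keep} or None
        return GroupedMSA(new_ids, new_rows, groups=groups)

    def group_rows(self, label: str) -> "GroupedMSA":
        if not self.groups:
            raise ValueError("alignment has no group labels")
        ids = [i for i in self.ids if self.groups.get(i) == label]
        return self.subset(ids)


# ---------------------------------------------------------------------------
# Progressive alignment

def _column_freqs(rows: List[str]) -> np.ndarray:
    """(L, 21) per-column frequency vectors; index 20 is the gap fraction."""
    L = len(rows[0])
    f = np.zeros((L, 21), dtype=float)
    for row in rows:
        for c, ch in enumerate(row):
            f[c, AA_INDEX.get(ch, 20)] += 1.0
    return f / len(rows)


def _profile_pair_scores(fa: np.ndarray, fb: np.ndarray, scoring: ScoringMatrix) -> np.ndarray:
    """Expected substitution score between every column pair (gaps score 0)."""
    return fa[:, :20] @ scoring.scores.astype(float) @ fb[:, :20].T


def _align_profiles(rows_a: List[str], rows_b: List[str],
                    scoring: ScoringMatrix) -> Tuple[List[str], List[str]]:
    """Global affine-gap alignment of two alignments (Gotoh, deterministic).

    Tie-break order in traceback: diagonal > up > left.
    """
    fa = _column_freqs(rows_a)
    fb = _column_freqs(rows_b)
    sub = _profile_pair_scores(fa, fb, scoring)
    m, n = sub.shape
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in A (consumes B columns)
    Y = np.full((m + 1, n + 1), NEG)  # gap in B (consumes A columns)
    M[0, 0] = 0.0
    for j in range(1, n + 1):
        X[0, j] = -go - (j - 1) * ge
    for i in range(1, m + 1):
        Y[i, 0] = -go - (i - 1) * ge
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - ge, Y[i, j - 1] - go)
            Y[i, j] = max(M[i - 1, j] - go, Y[i - 1, j] - ge, X[i - 1, j] - go)
    i, j = m, n
    states = {"M": M, "X": X, "Y": Y}
    final = max(states, key=lambda s: states[s][m, n])
    out_a: List[str] = ["" for _ in rows_a]
    out_b: List[str] = ["" for _ in rows_b]

    def emit(da: int, db: int) -> None:
        nonlocal i, j
        for k, row in enumerate(rows_a):
            out_a[k] += row[i - 1] if da else GAP
        for k, row in enumerate(rows_b):
            out_b[k] += row[j - 1] if db else GAP
        i -= da
        j -= db

    state = final
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                state = "X" if i == 0 else "Y"
                continue
            emit(1, 1)
            vals = {"M": M[i, j], "Y": Y[i, j], "X": X[i, j]}
            best = max(vals.values())
            state = next(s for s in ("M", "Y", "X") if vals[s] == best)
        elif state == "Y":  # consumed a column of A
            if i == 0:
                state = "X"
                continue
            came_m = M[i - 1, j] - go
            came_y = Y[i - 1, j] - ge
            came_x = X[i - 1, j] - go
            emit(1, 0)
            best = max(came_m, came_y, came_x)
            state = "M" if came_m == best else ("Y" if came_y == best else "X")
        else:  # "X": consumed a column of B
            if j == 0:
                state = "Y"
                continue
            came_m = M[i, j - 1] - go
            came_x = X[i, j - 1] - ge
            came_y = Y[i, j - 1] - go
            emit(0, 1)
            best = max(came_m, came_x, came_y)
            state = "M" if came_m == best else ("X" if came_x == best else "Y")
    return [s[::-1] for s in out_a], [s[::-1] for s in out_b]


def _pairwise_identity_distance(a: str, b: str, scoring: ScoringMatrix) -> float:
    """1 - identity over the global alignment length (gaps count as differences)."""
    ra, rb = _align_profiles([a], [b], scoring)
    matches = sum(1 for x, y in zip(ra[0], rb[0]) if x == y and x != GAP)
    if not ra[0]:
        return 1.0
    return 1.0 - matches / len(ra[0])


def progressive_align(seqs: Dict[str, str],
                      scoring: Optional[ScoringMatrix] = None) -> GroupedMSA:
    """Align sequences progressively along an NJ guide tree."""
    if scoring is None:
        scoring = blosum62()
    ids = list(seqs)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return GroupedMSA(ids, [seqs[ids[0]]])
    if len(ids) == 2:
        ra, rb = _align_profiles([seqs[ids[0]]], [seqs[ids[1]]], scoring)
        return GroupedMSA(ids, [ra[0], rb[0]])

    from .phylo import DistanceMatrix, neighbor_joining

    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_identity_distance(seqs[ids[i]], seqs[ids[j]], scoring)
    guide = neighbor_joining(DistanceMatrix(ids=ids, matrix=d))

    def merge(node) -> Tuple[List[str], List[str]]:
        if node.is_leaf():
            name = node.taxon.label
            return [name], [seqs[name]]
        children = node.child_nodes()
        ids_a, rows_a = merge(children[0])
        for child in children[1:]:
            ids_b, rows_b = merge(child)
            rows_a, rows_b = _align_profiles(rows_a, rows_b, scoring)
            ids_a = ids_a + ids_b
            rows_a = rows_a + rows_b
        return ids_a, rows_a

    merged_ids, merged_rows = merge(guide.seed_node)
    order = {name: k for k, name in enumerate(ids)}
    pairs = sorted(zip(merged_ids, merged_rows), key=lambda p: order[p[0]])
    return GroupedMSA([p[0] for p in pairs], [p[1] for p in pairs])


# ---------------------------------------------------------------------------
# Trimming and filtering

def trim_columns(msa: GroupedMSA, gap_threshold: float = 0.3) -> GroupedMSA:
    """Retain columns whose non-gap fraction is >= gap_threshold."""
    if not 0.0 <= gap_threshold <= 1.0:
        raise ValueError("gap_threshold must be in [0, 1]")
    keep = [c for c in range(msa.n_columns)
            if msa.column_non_gap_fraction(c) >= gap_threshold]
    rows = ["".join(row[c] for c in keep) for row in msa.rows]
    return GroupedMSA(list(msa.ids), rows, groups=msa.groups)


def filter_fragments(msa: GroupedMSA, min_data: float = 0.5) -> GroupedMSA:
    """Drop rows with non-gap fraction < min_data over the current columns."""
    if not 0.0 <= min_data <= 1.0:
        raise ValueError("min_data must be in [0, 1]")
    keep = [i for i in range(msa.n_rows) if msa.row_non_gap_fraction(i) >= min_data]
    ids = [msa.ids[i] for i in keep]
    rows = [msa.rows[i] for i in keep]
    groups = {k: v for k, v in (msa.groups or {}).items() if k in set(ids)} or None
    return GroupedMSA(ids, rows, groups=groups)


def henikoff_weights(msa: GroupedMSA) -> GroupedMSA:
    """Attach position-based sequence weights, normalised to sum to 1.

    In each column a row's contribution is 1/(r*s), with r the number of
    distinct non-gap residues in the column and s the multiplicity of the
    row's residue; gap cells contribute nothing.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    raw = np.zeros(msa.n_rows)
    for c in range(msa.n_columns):
        col = msa.column(c)
        residues = [ch for ch in col if ch != GAP]
        if not residues:
            continue
        r = len(set(residues))
        counts = {ch: residues.count(ch) for ch in set(residues)}
        for i, ch in enumerate(col):
            if ch != GAP:
                raw[i] += 1.0 / (r * counts[ch])
    if raw.sum() == 0:
        raw[:] = 1.0
    weights = raw / raw.sum()
    return GroupedMSA(list(msa.ids), list(msa.rows), groups=msa.groups, weights=weights)


def realign_range(msa: GroupedMSA, start_col: int, end_col: int,
                  scoring: Optional[ScoringMatrix] = None) -> GroupedMSA:
    """Re-align one column block (1-based, inclusive) and splice it back.

    A curation utility; rows with no residues in the block keep all-gap rows.
    """
    if not (1 <= start_col <= end_col <= msa.n_columns):
        raise ValueError("column range out of bounds")
    a, b = start_col - 1, end_col
    block = {sid: row[a:b].replace(GAP, "")
             for sid, row in zip(msa.ids, msa.rows)}
    non_empty = {k: v for k, v in block.items() if v}
    if len(non_empty) >= 2:
        sub = progressive_align(non_empty, scoring)
        width = sub.n_columns
        aligned = dict(zip(sub.ids, sub.rows))
    else:
        width = max((len(v) for v in block.values()), default=0)
        aligned = {k: v.ljust(width, GAP) for k, v in non_empty.items()}
    rows = []
    for sid, row in zip(msa.ids, msa.rows):
        mid = aligned.get(sid, GAP * width)
        rows.append(row[:a] + mid + row[b:])
    return GroupedMSA(list(msa.ids), rows, groups=msa.groups)
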