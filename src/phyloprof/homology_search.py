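"""Family detection by local alignment and iterative profile search.

Stage 1 scans every proteome with per-family query sequences using
Smith-Waterman local alignment under Karlin-Altschul E-value statistics.
Stage 2 builds a position-specific log-odds profile (PSSM) from the aligned
stage-1 orthologs and re-searches the proteomes with a calibrated E-value,
which recovers diverged family members the pairwise stage misses. A final
rescue stage six-frame-translates nucleotide genomes and runs the profile
over the resulting ORFs to catch unannotated orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .alphabet import AA, AA_INDEX, ScoringMatrix, background_frequencies, blosum62, rng_for
from .containers import ProteomeSet

# Published gapped BLOSUM62(11,1) Karlin-Altschul parameters.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_EVALUE = 1e-5


@dataclass
class AlignmentHit:
    """One local alignment, with 1-based inclusive spans."""

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_span: Tuple[int, int]
    target_span: Tuple[int, int]
    aligned_query: str = ""
    aligned_target: str = ""


@dataclass
class SearchHit:
    """A family hit in one taxon, from any search stage."""

    family: str
    taxon: str
    target_id: str
    raw_score: float
    bit_score: float
    evalue: float
    stage: str
    query_span: Tuple[int, int] = (0, 0)
    target_span: Tuple[int, int] = (0, 0)


def evalue(raw_score: float, m: int, n: int, lambda_: float = DEFAULT_LAMBDA,
           K: float = DEFAULT_K) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return float(K * m * n * math.exp(-lambda_ * raw_score))


def bit_score(raw_score: float, lambda_: float = DEFAULT_LAMBDA,
              K: float = DEFAULT_K) -> float:
    return float((lambda_ * raw_score - math.log(K)) / math.log(2.0))


def _substitution_grid(query: str, target: str, scoring: ScoringMatrix) -> np.ndarray:
    qrows = scoring.score_profile(query)  # (m, 20), zero rows for X
    tcode = scoring.encode(target)
    grid = np.zeros((len(query), len(target)), dtype=np.int64)
    known = tcode >= 0
    if known.any():
        grid[:, known] = qrows[:, tcode[known]]
    return grid


def sw_score(query: str, target: str, scoring: ScoringMatrix) -> int:
    """Score-only affine-gap Smith-Waterman, vectorised over anti-diagonals."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    m, n = len(query), len(target)
    sub = _substitution_grid(query, target, scoring)
    go, ge = scoring.gap_open, scoring.gap_extend
    neg = np.int64(-(1 << 40))
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), neg, dtype=np.int64)
    F = np.full((m + 1, n + 1), neg, dtype=np.int64)
    best = 0
    for k in range(2, m + n + 1):
        lo = max(1, k - n)
        hi = min(m, k - 1)
        if lo > hi:
            continue
        ii = np.arange(lo, hi + 1)
        jj = k - ii
        e = np.maximum(H[ii, jj - 1] - go, E[ii, jj - 1] - ge)
        f = np.maximum(H[ii - 1, jj] - go, F[ii - 1, jj] - ge)
        h = np.maximum(H[ii - 1, jj - 1] + sub[ii - 1, jj - 1], 0)
        h = np.maximum(h, np.maximum(e, f))
        E[ii, jj] = e
        F[ii, jj] = f
        H[ii, jj] = h
        hmax = int(h.max())
        if hmax > best:
            best = hmax
    return best


def smith_waterman(query: str, target: str, scoring: Optional[ScoringMatrix] = None,
                   query_id: str = "query", target_id: str = "target",
                   m_space: Optional[int] = None, n_space: Optional[int] = None,
                   lambda_: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> AlignmentHit:
    """Optimal affine-gap local alignment with deterministic traceback.

    Tie-break order during traceback is diagonal > up (gap in target) >
    left (gap in query). A score of zero yields an empty span.
    """
    if scoring is None:
        scoring = blosum62()
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    m, n = len(query), len(target)
    sub = _substitution_grid(query, target, scoring)
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = -(1 << 40)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fi1 = F[i], F[i - 1]
        subrow = sub[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            f = max(Hi1[j] - go, Fi1[j] - ge)
            h = Hi1[j - 1] + subrow[j - 1]
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    msp = m_space if m_space is not None else m
    nsp = n_space if n_space is not None else n
    ev = evalue(best, msp, nsp, lambda_, K)
    bits = bit_score(best, lambda_, K)
    if best == 0:
        return AlignmentHit(query_id, target_id, 0, bits, ev, (0, 0), (0, 0), "", "")
    # Traceback from the best cell; priority diagonal > up > left.
    aq, at = [], []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if h == H[i - 1][j - 1] + sub[i - 1][j - 1]:
                aq.append(query[i - 1])
                at.append(target[j - 1])
                i -= 1
                j -= 1
            elif h == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in target, consume query
            aq.append(query[i - 1])
            at.append("-")
            if F[i][j] == H[i - 1][j] - go:
                state = "H"
            i -= 1
        else:  # state == "E": gap in query, consume target
            aq.append("-")
            at.append(target[j - 1])
            if E[i][j] == H[i][j - 1] - go:
                state = "H"
            j -= 1
    return AlignmentHit(
        query_id, target_id, int(best), bits, ev,
        (i + 1, bi), (j + 1, bj),
        "".join(reversed(aq)), "".join(reversed(at)),
    )


def search_round1(queries: Mapping[str, str], proteomes: ProteomeSet,
                  threshold: float = DEFAULT_EVALUE,
                  scoring: Optional[ScoringMatrix] = None,
                  lambda_: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> List[SearchHit]:
    """Pairwise search of every proteome with one query per family.

    E-values use the query length and the total residue count of the
    searched proteome set as the search space; the best hit per target is
    retained and hits with E >= ``threshold`` are discarded.
    """
    if scoring is None:
        scoring = blosum62()
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not proteomes.proteomes:
        raise ValueError("empty proteome set")
    db_size = proteomes.total_residues()
    hits: List[SearchHit] = []
    for family, query in queries.items():
        for taxon in proteomes.taxa():
            for target_id, target in proteomes.proteomes[taxon].items():
                raw = sw_score(query, target, scoring)
                ev = evalue(raw, len(query), db_size, lambda_, K)
                if ev < threshold:
                    aln = smith_waterman(query, target, scoring,
                                         query_id=family, target_id=target_id,
                                         m_space=len(query), n_space=db_size,
                                         lambda_=lambda_, K=K)
                    hits.append(SearchHit(
                        family=family, taxon=taxon, target_id=target_id,
                        raw_score=aln.raw_score, bit_score=aln.bit_score,
                        evalue=aln.evalue, stage="round1",
                        query_span=aln.query_span, target_span=aln.target_span))
    return hits


@dataclass
class ProfileModel:
    """Position-specific log-odds model (base 2) of a trimmed alignment."""

    log_odds: np.ndarray            # (L, 20)
    background: np.ndarray          # (20,) sums to 1
    counts: Optional[np.ndarray] = None  # (L, 20) weighted counts
    calibration: Optional[Tuple[float, float]] = None  # Gumbel (loc, scale)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 20:
            raise ValueError("log_odds must be (L, 20)")

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def lambda_hat(self) -> Optional[float]:
        if self.calibration is None:
            return None
        return 1.0 / self.calibration[1]

    def consensus(self) -> str:
        return "".join(AA[int(i)] for i in np.argmax(self.log_odds, axis=1))

    def score_sequence(self, seq: str, local: bool = True) -> float:
        """Best ungapped placement score over all full-length windows.

        With ``local`` (default) the score of a placement is its best
        contiguous column segment (max-subarray), the PSSM analogue of a
        local profile alignment; otherwise the full-window log-odds sum.
        Returns -inf when the sequence is shorter than the profile.
        """
        L = self.length
        n = len(seq)
        if n < L:
            return float("-inf")
        code = np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(code, L)  # (n-L+1, L)
        cols = np.arange(L)
        contrib = np.where(win >= 0, self.log_odds[cols[None, :], np.maximum(win, 0)], 0.0)
        if not local:
            return float(contrib.sum(axis=1).max())
        best = np.zeros(contrib.shape[0])
        run = np.zeros(contrib.shape[0])
        for k in range(L):
            run = np.maximum(run + contrib[:, k], 0.0)
            best = np.maximum(best, run)
        return float(best.max())


def build_profile(msa, pseudocount_weight: float = 1.0,
                  background: Optional[np.ndarray] = None) -> ProfileModel:
    """Build a PSSM from a (trimmed) alignment using Henikoff weights.

    Per column c and residue a:
        log_odds[c, a] = log2(((w_count + pc * bg_a) / (total + pc)) / bg_a)
    where w_count sums Henikoff sequence weights of rows showing residue a
    and total sums weights of non-gap rows in the column.
    """
    from .msa_processing import henikoff_weights

    if msa.n_columns == 0:
        raise ValueError("alignment has zero retained columns")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount weight must be non-negative")
    if background is None:
        background = background_frequencies()
    weights = msa.weights if msa.weights is not None else henikoff_weights(msa).weights
    L = msa.n_columns
    counts = np.zeros((L, 20), dtype=float)
    totals = np.zeros(L, dtype=float)
    for row, w in zip(msa.rows, weights):
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            k = AA.find(ch)
            if k >= 0:
                counts[c, k] += w
                totals[c] += w
    pc = pseudocount_weight
    freqs = (counts + pc * background[None, :]) / (totals + pc)[:, None]
    log_odds = np.log2(freqs / background[None, :])
    return ProfileModel(log_odds=log_odds, background=background, counts=counts)


def calibrate_profile(profile: ProfileModel, proteomes: ProteomeSet,
                      n_shuffles: int = 200, seed: int = 0) -> ProfileModel:
    """Fit a Gumbel null to profile scores of composition-matched decoys.

    Random sequences are drawn from the pooled residue composition of the
    searched set, at the median target length (at least profile length + 20);
    scipy's extreme-value MLE supplies (loc, scale), and E-values follow as
    n_targets * exp(-(S - loc)/scale).
    """
    rng = rng_for(seed, "profile-calibration")
    pool = "".join("".join(p.values()) for p in proteomes.proteomes.values())
    if not pool:
        raise ValueError("empty proteome set")
    comp = np.zeros(20)
    for ch in pool:
        k = AA.find(ch)
        if k >= 0:
            comp[k] += 1
    comp = comp / comp.sum()
    lengths = [len(s) for p in proteomes.proteomes.values() for s in p.values()]
    length = max(int(np.median(lengths)), profile.length + 20)
    scores = np.empty(n_shuffles)
    aa = np.array(list(AA))
    for i in range(n_shuffles):
        seq = "".join(rng.choice(aa, size=length, p=comp))
        scores[i] = profile.score_sequence(seq)
    loc, scale = stats.gumbel_r.fit(scores)
    profile.calibration = (float(loc), float(scale))
    return profile


def profile_evalue(profile: ProfileModel, score: float, n_targets: int) -> float:
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    loc, scale = profile.calibration
    z = (score - loc) / scale
    # Exact Gumbel upper tail; the exponential form is its large-z limit.
    p = float(-np.expm1(-np.exp(-min(z, 700.0))))
    return n_targets * p


def profile_search(profile: ProfileModel, proteomes: ProteomeSet,
                   threshold: float = DEFAULT_EVALUE, family: str = "profile",
                   n_shuffles: int = 200, seed: int = 0) -> List[SearchHit]:
    """Ungapped sliding-placement profile search with calibrated E-values."""
    if not proteomes.proteomes:
        raise ValueError("empty proteome set")
    if profile.calibration is None:
        calibrate_profile(profile, proteomes, n_shuffles=n_shuffles, seed=seed)
    n_targets = sum(len(p) for p in proteomes.proteomes.values())
    hits: List[SearchHit] = []
    for taxon in proteomes.taxa():
        for target_id, target in proteomes.proteomes[taxon].items():
            score = profile.score_sequence(target)
            if not np.isfinite(score):
                continue  # target shorter than profile: no placement, no hit
            ev = profile_evalue(profile, score, n_targets)
            if ev < threshold:
                hits.append(SearchHit(
                    family=family, taxon=taxon, target_id=target_id,
                    raw_score=float(score),
                    bit_score=float(score),  # profile scores are already bits
                    evalue=float(ev), stage="profile"))
    return hits


@dataclass
class PredictedProtein:
    """An ORF called from a six-frame translation (1-based forward coords)."""

    orf_id: str
    sequence: str
    strand: str          # '+' or '-'
    frame: int           # 1..3 on the given strand
    start: int           # 1-based inclusive, forward strand
    end: int


def six_frame_orfs(genome: str, min_orf: int = 30) -> List[PredictedProtein]:
    """All-stop-free ORFs of length >= min_orf from all six reading frames."""
    genome = genome.upper()
    if any(c not in "ACGTN" for c in genome):
        raise ValueError("genome contains non-ACGTN characters")
    if min_orf < 10:
        raise ValueError("min_orf must be >= 10")
    L = len(genome)
    orfs: List[PredictedProtein] = []
    for strand in ("+", "-"):
        nt = genome if strand == "+" else str(Seq(genome).reverse_complement())
        for frame in range(3):
            usable = (len(nt) - frame) // 3 * 3
            if usable < 3:
                continue
            prot = str(Seq(nt[frame:frame + usable]).translate())
            start_aa = 0
            for chunk in prot.split("*"):
                if len(chunk) >= min_orf and chunk.count("X") <= 0.2 * len(chunk):
                    a, b = start_aa, start_aa + len(chunk)  # aa half-open on strand
                    s_nt, e_nt = frame + 3 * a, frame + 3 * b  # strand coords, half-open
                    if strand == "+":
                        start, end = s_nt + 1, e_nt
                    else:
                        start, end = L - e_nt + 1, L - s_nt
                    orf_id = f"orf_{strand}{frame + 1}_{start}_{end}"
                    orfs.append(PredictedProtein(orf_id, chunk, strand, frame + 1, start, end))
                start_aa += len(chunk) + 1
    return orfs


def six_frame_rescue(profile: ProfileModel, genome: str, taxon: str = "genome",
                     min_orf: int = 30, threshold: float = DEFAULT_EVALUE,
                     family: str = "profile", n_shuffles: int = 200,
                     seed: int = 0) -> Tuple[List[PredictedProtein], List[SearchHit]]:
    """Translate a genome in six frames and profile-search the ORFs."""
    orfs = six_frame_orfs(genome, min_orf=min_orf)
    if not orfs:
        return [], []
    orf_set = ProteomeSet(proteomes={taxon: {o.orf_id: o.sequence for o in orfs}})
    prof = ProfileModel(log_odds=profile.log_odds, background=profile.background,
                        counts=profile.counts, calibration=profile.calibration)
    hits = profile_search(prof, orf_set, threshold=threshold, family=family,
                          n_shuffles=n_shuffles, seed=seed)
    for h in hits:
        h.stage = "genome-rescue"
    return orfs, hits
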