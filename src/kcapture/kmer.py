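"""K-mer decomposition, physicochemical k-mer similarity, best matches.

Each sequence is cut into overlapping length-k windows; unique k-mers of
two sequences are compared all-vs-all by the mean of their position-wise
residue similarities, and each k-mer is paired with its single most
similar k-mer in the other sequence. Ties on similarity are broken by
the lowest LD value computed from the two k-mers' occurrence
frequencies, then lexicographically, so results are fully deterministic.
Reciprocal best matches — pairs where the choice agrees in both
directions — are the unit of conservation evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .physchem import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20 canonical residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence '{self.id}' is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class KmerTable:
    """Unique k-mers of one sequence with counts and 1-based start positions.

    K-mers are kept in lexicographic order so every downstream structure
    is independent of scan order.
    """

    sequence_id: str
    k: int
    kmers: list[str]
    counts: np.ndarray  # int, aligned with kmers
    positions: dict[str, list[int]]
    encoded: np.ndarray = field(repr=False, default=None)  # (n, k) residue idx

    @property
    def n_unique(self) -> int:
        return len(self.kmers)

    def frequency(self, kmer: str) -> int:
        return len(self.positions.get(kmer, ()))


def decompose(
    seq: SequenceRecord, k: int, sm: SimilarityMatrix | None = None
) -> KmerTable:
    """Sliding-window decomposition into all L-k+1 overlapping k-mers.

    A k longer than the sequence yields an empty table (the sequence is
    skipped for this k) with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = seq.residues
    if k > len(s):
        logger.warning(
            "sequence '%s' (length %d) shorter than k=%d; skipped",
            seq.id, len(s), k,
        )
        return KmerTable(seq.id, k, [], np.zeros(0, dtype=int), {})
    positions: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        positions.setdefault(s[i : i + k], []).append(i + 1)
    kmers = sorted(positions)
    counts = np.array([len(positions[x]) for x in kmers], dtype=int)
    encoded = None
    if sm is not None:
        encoded = _encode(kmers, k, sm)
    return KmerTable(seq.id, k, kmers, counts, positions, encoded)


def _encode(kmers: list[str], k: int, sm: SimilarityMatrix) -> np.ndarray:
    enc = np.empty((len(kmers), k), dtype=np.intp)
    for i, kmer in enumerate(kmers):
        for p, aa in enumerate(kmer):
            enc[i, p] = sm.index_of(aa)
    return enc


def kmer_similarity(x: str, y: str, sm: SimilarityMatrix) -> float:
    """Mean position-wise residue similarity of two equal-length k-mers."""
    if len(x) != len(y):
        raise ValueError(
            f"k-mer lengths differ: {len(x)} vs {len(y)}; similarity is "
            "defined only within one k"
        )
    return sum(sm.lookup(a, b) for a, b in zip(x, y)) / len(x)


def ld_tiebreak(q: int, t: int) -> float:
    """LD(q, t) = 2(q^2 + t^2)/(q + t), from the occurrence frequencies.

    Used to break similarity ties in best-match selection: the candidate
    with the lowest LD wins. The formula is isolated here so an
    alternative transcription can be swapped in one place; any remaining
    tie falls through to lexicographic order, keeping outputs
    reproducible under either reading.
    """
    return 2.0 * (q * q + t * t) / (q + t)


@dataclass
class PairSimilarityMatrix:
    """All-vs-all similarity of the unique k-mers of two sequences."""

    seq_a_id: str
    seq_b_id: str
    k: int
    row_kmers: list[str]
    col_kmers: list[str]
    values: np.ndarray  # (rows, cols) of w in [0, 1]


def pair_similarity_matrix(
    ta: KmerTable, tb: KmerTable, sm: SimilarityMatrix
) -> PairSimilarityMatrix:
    """Complete |unique(a)| x |unique(b)| matrix of k-mer similarities."""
    if ta.k != tb.k:
        raise ValueError("k-mer tables have different k")
    k = ta.k
    if ta.n_unique == 0 or tb.n_unique == 0:
        logger.info(
            "empty k-mer table for pair (%s, %s) at k=%d",
            ta.sequence_id, tb.sequence_id, k,
        )
        return PairSimilarityMatrix(
            ta.sequence_id, tb.sequence_id, k, ta.kmers, tb.kmers,
            np.zeros((ta.n_unique, tb.n_unique)),
        )
    ea = ta.encoded if ta.encoded is not None else _encode(ta.kmers, k, sm)
    eb = tb.encoded if tb.encoded is not None else _encode(tb.kmers, k, sm)
    values = np.zeros((ta.n_unique, tb.n_unique))
    s = sm.values
    for p in range(k):
        values += s[np.ix_(ea[:, p], eb[:, p])]
    values /= k
    return PairSimilarityMatrix(
        ta.sequence_id, tb.sequence_id, k, ta.kmers, tb.kmers, values
    )


@dataclass(frozen=True)
class BestMatchRecord:
    source_kmer: str
    target_kmer: str
    w: float
    ld: float
    reciprocal: bool = False


def _best_per_row(
    values: np.ndarray,
    col_counts: np.ndarray,
    row_counts: np.ndarray,
) -> list[int]:
    """Index of the best column per row with LD then lexicographic tie-break.

    Column k-mers are lexicographically sorted, so among equal (w, LD)
    candidates the smallest index is the smallest k-mer string.
    """
    best = np.argmax(values, axis=1)
    row_max = values[np.arange(values.shape[0]), best]
    n_at_max = (values == row_max[:, None]).sum(axis=1)
    for i in np.nonzero(n_at_max > 1)[0]:
        tied = np.nonzero(values[i] == row_max[i])[0]
        q = int(row_counts[i])
        lds = [ld_tiebreak(q, int(col_counts[j])) for j in tied]
        best[i] = tied[int(np.argmin(lds))]
    return best.tolist()


def best_matches(
    m: PairSimilarityMatrix, ta: KmerTable, tb: KmerTable
) -> tuple[list[BestMatchRecord], list[BestMatchRecord]]:
    """Best match per k-mer in both directions (a->b rows, b->a columns)."""
    fwd_idx = _best_per_row(m.values, tb.counts, ta.counts)
    rev_idx = _best_per_row(m.values.T, ta.counts, tb.counts)
    recip = {
        (i, j) for i, j in enumerate(fwd_idx) if rev_idx[j] == i
    }
    fwd = [
        BestMatchRecord(
            m.row_kmers[i], m.col_kmers[j], float(m.values[i, j]),
            ld_tiebreak(int(ta.counts[i]), int(tb.counts[j])),
            reciprocal=(i, j) in recip,
        )
        for i, j in enumerate(fwd_idx)
    ]
    rev = [
        BestMatchRecord(
            m.col_kmers[j], m.row_kmers[i], float(m.values[i, j]),
            ld_tiebreak(int(tb.counts[j]), int(ta.counts[i])),
            reciprocal=(i, j) in recip,
        )
        for j, i in enumerate(rev_idx)
    ]
    return fwd, rev


@dataclass
class ReciprocalMatchSet:
    """Reciprocal best matches of one sequence pair at one k."""

    seq_a_id: str
    seq_b_id: str
    k: int
    pairs: list[tuple[str, str, float]]  # (kmer_a, kmer_b, w)


def reciprocal_best_matches(
    fwd: list[BestMatchRecord],
    rev: list[BestMatchRecord],
    m: PairSimilarityMatrix,
) -> ReciprocalMatchSet:
    """Pairs (x, y) with best(x) = y and best(y) = x."""
    rev_best = {r.source_kmer: r.target_kmer for r in rev}
    pairs = [
        (f.source_kmer, f.target_kmer, f.w)
        for f in fwd
        if rev_best.get(f.target_kmer) == f.source_kmer
    ]
    return ReciprocalMatchSet(m.seq_a_id, m.seq_b_id, m.k, pairs)


def reciprocal_matches_for_pair(
    ta: KmerTable, tb: KmerTable, sm: SimilarityMatrix
) -> ReciprocalMatchSet:
    """Convenience chain: similarity matrix -> best matches -> reciprocal."""
    m = pair_similarity_matrix(ta, tb, sm)
    if ta.n_unique == 0 or tb.n_unique == 0:
        return ReciprocalMatchSet(ta.sequence_id, tb.sequence_id, ta.k, [])
    fwd, rev = best_matches(m, ta, tb)
    return reciprocal_best_matches(fwd, rev, m)
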