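"""Consensus k-mer scoring across all sequence pairs and all k.

For n input sequences, all n(n+1)/2 unordered pairs (self-pairs
included) are compared at every k in [k_min, k_max]. A k-mer's raw
score is the number of reciprocal-best-match events it takes part in
across all pairs. Because longer k-mers live in a larger search space
and are therefore less likely to find reciprocal partners, raw scores
are multiplied by a weighting factor f(S_k) that grows with the number
S_k of unique k-mers of that length pooled over the whole input set
(default f = S_k/2, variant f = S_k^2), giving the capture score that
is comparable across k. Consensus k-mers are ranked by this score and
mapped back onto each sequence via their most frequent reciprocal
partner in that sequence.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .kmer import (
    KmerTable,
    ReciprocalMatchSet,
    SequenceRecord,
    decompose,
    reciprocal_matches_for_pair,
)
from .physchem import (
    SimilarityMatrix,
    distance_to_similarity,
    load_distance_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class CaptureConfig:
    """Run parameters for consensus k-mer detection."""

    k_min: int = 3
    k_max: int = 10
    top_n: int = 10
    matrix: str = "grantham"
    weighting: str = "half"       # "half": S_k/2; "squared": S_k^2
    score_mode: str = "count"     # "count": events; "weighted": sum of w
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("require 1 <= k_min <= k_max")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.weighting not in ("half", "squared"):
            raise ValueError(f"unknown weighting variant '{self.weighting}'")
        if self.score_mode not in ("count", "weighted"):
            raise ValueError(f"unknown score mode '{self.score_mode}'")


@dataclass(frozen=True)
class ConsensusKmer:
    """A candidate motif: a k-mer ranked by its weighted reciprocal count."""

    kmer: str
    k: int
    raw_score: float
    search_space: int
    score: float
    rank: int


@dataclass(frozen=True)
class MotifMapping:
    """A consensus k-mer located in one sequence (1-based inclusive)."""

    consensus: str
    sequence_id: str
    mapped_kmer: str
    start: int
    end: int
    support: int


@dataclass
class ProbabilityMatrix:
    """k x 20 residue probability matrix summarizing mapped k-mers."""

    consensus: str
    labels: tuple[str, ...]
    values: np.ndarray  # (k, 20), rows sum to 1


def enumerate_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered index pairs including self-pairs: n(n+1)/2 of them."""
    if n < 1:
        raise ValueError("empty input set")
    return [(i, j) for i in range(n) for j in range(i, n)]


def accumulate_raw_scores(
    recip_sets: list[ReciprocalMatchSet], k: int, score_mode: str = "count"
) -> dict[str, float]:
    """Raw score per k-mer: reciprocal events it appears in, on either side.

    One event contributes 1 to each distinct k-mer string involved
    (a self-match x<->x contributes 1 to x). The "weighted" mode sums
    the event similarities w instead of counting.
    """
    raw: Counter[str] = Counter()
    for rs in recip_sets:
        if rs.k != k:
            continue
        for ka, kb, w in rs.pairs:
            inc = w if score_mode == "weighted" else 1.0
            raw[ka] += inc
            if kb != ka:
                raw[kb] += inc
    return dict(raw)


def weight_score(raw: float, s_k: int, variant: str = "half") -> float:
    """Capture score: raw reciprocal count times the search-space factor."""
    if s_k < 1:
        raise ValueError("search space S_k must be >= 1")
    if variant == "half":
        return raw * s_k / 2.0
    if variant == "squared":
        return raw * float(s_k) ** 2
    raise ValueError(f"unknown weighting variant '{variant}'")


def rank_consensus(
    raw_by_k: dict[int, dict[str, float]],
    s_k: dict[int, int],
    config: CaptureConfig,
) -> list[ConsensusKmer]:
    """Rank all scored k-mers across k by descending capture score.

    Ties are broken toward larger k (longer exact conservation is
    rarer), then lexicographically. Ranks are dense from 1. The full
    list is returned; callers truncate to top_n for reporting.
    """
    entries = []
    for k, raw in raw_by_k.items():
        for kmer, r in raw.items():
            entries.append(
                (kmer, k, r, s_k[k], weight_score(r, s_k[k], config.weighting))
            )
    entries.sort(key=lambda e: (-e[4], -e[1], e[0]))
    ranked = [
        ConsensusKmer(kmer, k, r, sk, score, rank)
        for rank, (kmer, k, r, sk, score) in enumerate(entries, start=1)
    ]
    if not ranked:
        logger.warning("no conserved k-mers found")
    return ranked


@dataclass
class CaptureResult:
    """Everything a run produced, sufficient for map-back and extension."""

    records: list[SequenceRecord]
    config: CaptureConfig
    s_k: dict[int, int]
    raw_by_k: dict[int, dict[str, float]]
    consensus: list[ConsensusKmer]          # full ranked list
    reciprocal: dict[tuple[str, str, int], list[tuple[str, str, float]]]
    tables: dict[int, dict[str, KmerTable]] = field(repr=False, default=None)

    @property
    def top(self) -> list[ConsensusKmer]:
        return self.consensus[: self.config.top_n]

    def record(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)


def _pair_events(task):
    ta, tb, sm = task
    rs = reciprocal_matches_for_pair(ta, tb, sm)
    return (rs.seq_a_id, rs.seq_b_id, rs.k), rs.pairs


def run_capture(
    records: list[SequenceRecord],
    config: CaptureConfig | None = None,
    similarity: SimilarityMatrix | None = None,
    processes: int = 1,
) -> CaptureResult:
    """Full pipeline: decompose, compare all pairs at all k, score, rank."""
    config = config or CaptureConfig()
    if not records:
        raise ValueError("empty input set")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")
    sm = similarity
    if sm is None:
        sm = distance_to_similarity(load_distance_matrix(config.matrix))

    # Pair identity is by sequence id, so input order never matters.
    order = sorted(range(len(records)), key=lambda i: records[i].id)
    pair_ids = [
        (order[i], order[j]) for i, j in enumerate_pairs(len(records))
    ]

    tables: dict[int, dict[str, KmerTable]] = {}
    s_k: dict[int, int] = {}
    for k in range(config.k_min, config.k_max + 1):
        tables[k] = {r.id: decompose(r, k, sm) for r in records}
        pooled = set()
        for t in tables[k].values():
            pooled.update(t.kmers)
        s_k[k] = len(pooled)

    tasks = []
    for k in range(config.k_min, config.k_max + 1):
        if s_k[k] == 0:
            continue
        for i, j in pair_ids:
            ta = tables[k][records[i].id]
            tb = tables[k][records[j].id]
            if ta.n_unique == 0 or tb.n_unique == 0:
                continue
            tasks.append((ta, tb, sm))

    if processes > 1:
        from multiprocessing import get_context

        with get_context("fork").Pool(processes) as pool:
            results = pool.map(_pair_events, tasks, chunksize=8)
    else:
        results = [_pair_events(t) for t in tasks]

    reciprocal = {key: pairs for key, pairs in results}

    raw_by_k = {}
    for k in range(config.k_min, config.k_max + 1):
        sets = [
            ReciprocalMatchSet(a, b, kk, pairs)
            for (a, b, kk), pairs in reciprocal.items()
            if kk == k
        ]
        raw = accumulate_raw_scores(sets, k, config.score_mode)
        if raw:
            raw_by_k[k] = raw
        logger.info(
            "k=%d: S_k=%d, %d scored k-mers over %d pairs",
            k, s_k[k], len(raw), len(pair_ids),
        )

    consensus = rank_consensus(raw_by_k, s_k, config)
    return CaptureResult(
        records=list(records),
        config=config,
        s_k=s_k,
        raw_by_k=raw_by_k,
        consensus=consensus,
        reciprocal=reciprocal,
        tables=tables,
    )


def map_back(
    consensus: ConsensusKmer | str,
    seq: SequenceRecord,
    result: CaptureResult,
) -> list[MotifMapping]:
    """Locate a consensus k-mer in one sequence.

    Among all reciprocal events pairing the consensus k-mer with a k-mer
    of this sequence, the partner string with the most events wins (ties:
    higher mean w to the consensus, then lexicographic). All occurrence
    positions of the winning partner are returned; an empty list means
    the sequence shares no reciprocal event with the consensus.
    """
    ck = consensus.kmer if isinstance(consensus, ConsensusKmer) else consensus
    k = len(ck)
    partner_events: dict[str, int] = defaultdict(int)
    partner_wsum: dict[str, float] = defaultdict(float)
    for (a, b, kk), pairs in result.reciprocal.items():
        if kk != k or (a != seq.id and b != seq.id):
            continue
        for ka, kb, w in pairs:
            if a == seq.id and kb == ck:
                partner_events[ka] += 1
                partner_wsum[ka] += w
            if b == seq.id and ka == ck and not (a == b and kb == ck):
                partner_events[kb] += 1
                partner_wsum[kb] += w
    if not partner_events:
        return []
    best = min(
        partner_events,
        key=lambda p: (
            -partner_events[p],
            -partner_wsum[p] / partner_events[p],
            p,
        ),
    )
    table = result.tables[k][seq.id]
    return [
        MotifMapping(
            consensus=ck,
            sequence_id=seq.id,
            mapped_kmer=best,
            start=pos,
            end=pos + k - 1,
            support=partner_events[best],
        )
        for pos in table.positions.get(best, [])
    ]


def map_back_all(
    result: CaptureResult, consensus: ConsensusKmer | str
) -> list[MotifMapping]:
    """Map a consensus k-mer onto every sequence, sorted for determinism."""
    mappings: list[MotifMapping] = []
    for rec in sorted(result.records, key=lambda r: r.id):
        mappings.extend(map_back(consensus, rec, result))
    return mappings


def probability_matrix(
    mappings: list[MotifMapping],
    labels: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY"),
) -> ProbabilityMatrix:
    """Empirical residue probabilities per position over mapped k-mers."""
    if not mappings:
        raise ValueError("nothing to summarize: empty mapping list")
    k = len(mappings[0].mapped_kmer)
    if any(len(m.mapped_kmer) != k for m in mappings):
        raise ValueError("mapped k-mers have unequal lengths")
    index = {aa: i for i, aa in enumerate(labels)}
    values = np.zeros((k, len(labels)))
    for m in mappings:
        for p, aa in enumerate(m.mapped_kmer):
            values[p, index[aa]] += 1
    values /= values.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(mappings[0].consensus, labels, values)
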