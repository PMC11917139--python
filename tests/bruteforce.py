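"""Independent brute-force reference for the capture pipeline.

Pure-Python nested loops over dictionaries — no similarity matrices, no
numpy — so it shares no code path with the package implementation. Only
the raw Grantham pair table is reused as input data.
"""

from __future__ import annotations

from kcapture._grantham import GRANTHAM_PAIRS

_DIST = {}
for (a, b), d in GRANTHAM_PAIRS.items():
    _DIST[(a, b)] = d
    _DIST[(b, a)] = d
_MAX = max(_DIST.values())


def residue_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    return 1.0 - _DIST[(a, b)] / _MAX


def kmer_w(x: str, y: str) -> float:
    total = 0.0
    for p in range(len(x)):
        total += residue_similarity(x[p], y[p])
    return total / len(x)


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i + 1)
    return pos


def ld(q: int, t: int) -> float:
    return 2.0 * (q * q + t * t) / (q + t)


def best_match(
    source: str, q: int, targets: dict[str, list[int]]
) -> tuple[str, float]:
    """Best target k-mer by (max w, min LD, lexicographic)."""
    choice = None
    for cand in sorted(targets):
        w = kmer_w(source, cand)
        key = (-w, ld(q, len(targets[cand])), cand)
        if choice is None or key < choice[0]:
            choice = (key, cand, w)
    return choice[1], choice[2]


def reciprocal_pairs(
    pa: dict[str, list[int]], pb: dict[str, list[int]]
) -> list[tuple[str, str, float]]:
    fwd = {x: best_match(x, len(pa[x]), pb) for x in pa}
    rev = {y: best_match(y, len(pb[y]), pa) for y in pb}
    out = []
    for x in sorted(pa):
        y, w = fwd[x]
        if rev[y][0] == x:
            out.append((x, y, w))
    return out


def brute_capture(seqs: list[tuple[str, str]], k_min: int = 3, k_max: int = 10):
    """Full reference pipeline on (id, sequence) pairs.

    Returns a dict with s_k, raw scores per k, the ranked consensus list
    of (kmer, k, raw, s_k, score) tuples (score = raw * S_k / 2, ties
    toward larger k then lexicographic), and per-pair reciprocal events.
    """
    n = len(seqs)
    events: dict[tuple[str, str, int], list[tuple[str, str, float]]] = {}
    s_k: dict[int, int] = {}
    raw_by_k: dict[int, dict[str, float]] = {}
    ordered = sorted(seqs, key=lambda s: s[0])
    for k in range(k_min, k_max + 1):
        pooled = set()
        for _, seq in seqs:
            pooled.update(kmer_positions(seq, k))
        s_k[k] = len(pooled)
        raw: dict[str, float] = {}
        for i in range(n):
            for j in range(i, n):
                ida, sa = ordered[i]
                idb, sb = ordered[j]
                pa = kmer_positions(sa, k)
                pb = kmer_positions(sb, k)
                if not pa or not pb:
                    continue
                pairs = reciprocal_pairs(pa, pb)
                events[(ida, idb, k)] = pairs
                for x, y, _w in pairs:
                    raw[x] = raw.get(x, 0) + 1
                    if y != x:
                        raw[y] = raw.get(y, 0) + 1
        if raw:
            raw_by_k[k] = raw
    ranked = []
    for k, raw in raw_by_k.items():
        for kmer, r in raw.items():
            ranked.append((kmer, k, r, s_k[k], r * s_k[k] / 2.0))
    ranked.sort(key=lambda e: (-e[4], -e[1], e[0]))
    return {
        "s_k": s_k,
        "raw_by_k": raw_by_k,
        "ranked": ranked,
        "events": events,
    }


def brute_map_back(
    consensus: str,
    seq_id: str,
    seq: str,
    events: dict[tuple[str, str, int], list[tuple[str, str, float]]],
) -> list[tuple[str, int, int]]:
    """Reference map-back: (mapped_kmer, start, end) per occurrence."""
    k = len(consensus)
    count: dict[str, int] = {}
    wsum: dict[str, float] = {}
    for (a, b, kk), pairs in events.items():
        if kk != k:
            continue
        for x, y, w in pairs:
            if a == seq_id and y == consensus:
                count[x] = count.get(x, 0) + 1
                wsum[x] = wsum.get(x, 0.0) + w
            if b == seq_id and x == consensus and not (a == b and y == consensus):
                count[y] = count.get(y, 0) + 1
                wsum[y] = wsum.get(y, 0.0) + w
    if not count:
        return []
    best = min(
        count, key=lambda p: (-count[p], -wsum[p] / count[p], p)
    )
    return [
        (best, pos, pos + k - 1)
        for pos in kmer_positions(seq, k).get(best, [])
    ]
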