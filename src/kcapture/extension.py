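"""Extension post-processing: grow the top-ranked mapped region.

Per sequence, the top-ranked consensus k-mer's mapped interval is
extended with mapped regions of other high-ranking consensus k-mers
that (1) overlap it by at least one residue and (2) score strictly
above a fraction (default 0.9) of the top capture score C. The merged
interval may exceed k_max. By default absorption iterates to a fixed
point, so newly absorbed intervals can recruit further overlapping
candidates; a single-pass mode applies the criterion once against the
seed interval only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import CaptureResult, MotifMapping, map_back


@dataclass
class ExtensionConfig:
    threshold_fraction: float = 0.9
    candidate_pool: int = 10
    iterate_to_fixpoint: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")


@dataclass
class ExtendedRegion:
    sequence_id: str
    start: int
    end: int
    merged_from: list[tuple[str, float]] = field(default_factory=list)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def extend(
    top_mapping: MotifMapping,
    candidates: list[tuple[MotifMapping, float]],
    top_score: float,
    cfg: ExtensionConfig | None = None,
) -> ExtendedRegion:
    """Grow one top-ranked mapped interval by overlap + score criterion.

    ``candidates`` are (mapping, capture score) pairs of the same
    sequence, drawn from the top ``candidate_pool`` consensus k-mers.
    Only candidates with score > threshold_fraction * top_score (strict)
    and >= 1 residue of overlap are absorbed. The result is independent
    of candidate ordering.
    """
    cfg = cfg or ExtensionConfig()
    start, end = top_mapping.start, top_mapping.end
    merged = [(top_mapping.consensus, top_score)]
    eligible = [
        (m, s)
        for m, s in candidates
        if s > cfg.threshold_fraction * top_score
        and m.sequence_id == top_mapping.sequence_id
        and not (m.start == top_mapping.start and m.end == top_mapping.end
                 and m.consensus == top_mapping.consensus)
    ]
    # Deterministic scan order; set semantics guaranteed by iterating
    # until no eligible candidate overlaps the current interval.
    eligible.sort(key=lambda e: (e[0].start, e[0].end, e[0].consensus))
    if not cfg.iterate_to_fixpoint:
        # Strict single pass: overlap is judged against the seed only.
        for m, s in eligible:
            if _overlaps(top_mapping.start, top_mapping.end, m.start, m.end):
                start = min(start, m.start)
                end = max(end, m.end)
                merged.append((m.consensus, s))
        return ExtendedRegion(top_mapping.sequence_id, start, end, merged)
    absorbed = [False] * len(eligible)
    changed = True
    while changed:
        changed = False
        for i, (m, s) in enumerate(eligible):
            if absorbed[i]:
                continue
            if _overlaps(start, end, m.start, m.end):
                start = min(start, m.start)
                end = max(end, m.end)
                merged.append((m.consensus, s))
                absorbed[i] = True
                changed = True
    return ExtendedRegion(top_mapping.sequence_id, start, end, merged)


def extend_run(
    result: CaptureResult, cfg: ExtensionConfig | None = None
) -> list[ExtendedRegion]:
    """Extended region per sequence, seeded by the rank-1 consensus k-mer.

    Only the first (top-ranked) consensus k-mer seeds extension and only
    mappings of the top ``candidate_pool`` consensus k-mers are
    candidates. Sequences in which the top consensus has no reciprocal
    match produce no region. When the seed maps to several equal
    positions, the first (lowest start) seeds and the others remain
    candidates.
    """
    cfg = cfg or ExtensionConfig()
    if not result.consensus:
        return []
    top = result.consensus[0]
    pool = result.consensus[: cfg.candidate_pool]
    regions: list[ExtendedRegion] = []
    for rec in sorted(result.records, key=lambda r: r.id):
        seed_mappings = map_back(top, rec, result)
        if not seed_mappings:
            continue
        seed = min(seed_mappings, key=lambda m: m.start)
        candidates: list[tuple[MotifMapping, float]] = []
        for ck in pool:
            for m in map_back(ck, rec, result):
                candidates.append((m, ck.score))
        regions.append(extend(seed, candidates, top.score, cfg))
    return regions
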