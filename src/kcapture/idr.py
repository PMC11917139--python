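"""pLDDT-based disorder segmentation and proteome-scale motif filters.

Sustained low per-residue structure-prediction confidence (pLDDT) is a
practical proxy for intrinsic disorder. Tracks are smoothed with a
centered 15-residue moving average (the window shrinks at the termini),
residues with smoothed pLDDT <= 65 are called disordered, small
segments (<= 10 residues) flanked on both sides by the opposite label
are reassigned (ordered islands first), and maximal disordered runs of
>= 30 residues become IDRs. Proteome-scale motif calls are then kept
only when they lie fully inside an IDR, more than 2 residues away from
any ordered segment, and within a per-protein budget of two motifs per
100 IDR residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlddtTrack:
    protein_id: str
    values: np.ndarray  # per-residue pLDDT in [0, 100]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0:
            raise ValueError(f"empty pLDDT track for '{self.protein_id}'")
        if values.min() < 0 or values.max() > 100:
            raise ValueError("pLDDT values must lie in [0, 100]")
        self.values = values


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based inclusive
    end: int
    label: str  # "ordered" | "disordered"

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class DisorderSegmentation:
    protein_id: str
    segments: list[Segment]  # tiles the protein, no gaps/overlaps
    idrs: list[Segment]      # disordered segments of length >= min_idr_len


def smooth_plddt(values: np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average; the window shrinks at the termini."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty pLDDT track")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def call_disorder(smoothed: np.ndarray, threshold: float = 65.0) -> np.ndarray:
    """Boolean disorder mask: smoothed pLDDT <= threshold (inclusive)."""
    return np.asarray(smoothed) <= threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs as (start0, end0, value) with 0-based ends."""
    runs = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            runs.append((start, i - 1, bool(mask[start])))
            start = i
    return runs


def reassign_small_segments(
    mask: np.ndarray, max_len: int = 10, order_first: bool = True
) -> np.ndarray:
    """Flip small (<= max_len) islands flanked on both sides by the
    opposite label; ordered islands are reassigned first by default.
    Terminal segments have only one flank and are never flipped.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    passes = (False, True) if order_first else (True, False)
    for island_label in passes:  # False = ordered island, True = disordered
        runs = _runs(mask)
        for ri, (s, e, val) in enumerate(runs):
            if val != island_label:
                continue
            if e - s + 1 > max_len:
                continue
            if ri == 0 or ri == len(runs) - 1:
                continue
            mask[s : e + 1] = not island_label
    return mask


def extract_idrs(
    mask: np.ndarray, protein_id: str = "", min_len: int = 30
) -> DisorderSegmentation:
    """Tile the protein into labeled segments; disordered runs >= min_len
    are IDRs."""
    segments = [
        Segment(s + 1, e + 1, "disordered" if v else "ordered")
        for s, e, v in _runs(np.asarray(mask, dtype=bool))
    ]
    idrs = [
        seg for seg in segments
        if seg.label == "disordered" and len(seg) >= min_len
    ]
    return DisorderSegmentation(protein_id, segments, idrs)


def segment_protein(
    track: PlddtTrack,
    window: int = 15,
    threshold: float = 65.0,
    max_island: int = 10,
    min_idr_len: int = 30,
    order_first: bool = True,
) -> DisorderSegmentation:
    """Full chain: smooth -> threshold -> reassign islands -> IDRs."""
    smoothed = smooth_plddt(track.values, window)
    mask = call_disorder(smoothed, threshold)
    mask = reassign_small_segments(mask, max_island, order_first)
    return extract_idrs(mask, track.protein_id, min_idr_len)


@dataclass(frozen=True)
class ProteomeMotif:
    """A mapped motif instance on a proteome reference sequence."""

    protein_id: str
    kmer: str
    start: int  # 1-based inclusive
    end: int
    score: float


def filter_proteome_motifs(
    motifs: list[ProteomeMotif],
    segmentation: DisorderSegmentation,
    min_gap: int = 2,
    motifs_per_100: float = 2.0,
) -> list[ProteomeMotif]:
    """Keep motifs inside IDRs, clear of structure, under the length cap.

    A motif passes when it lies fully inside an IDR and more than
    ``min_gap`` residues separate it from every ordered segment. The
    per-protein budget is max(2, floor(motifs_per_100 * L_IDR / 100))
    distinct k-mers by descending score, where L_IDR is the protein's
    summed IDR length; equal-scoring positions of one k-mer all pass
    and count once against the budget.
    """
    if not segmentation.idrs:
        return []
    ordered = [s for s in segmentation.segments if s.label == "ordered"]
    passed: list[ProteomeMotif] = []
    for m in motifs:
        if m.protein_id != segmentation.protein_id:
            continue
        if not any(
            idr.start <= m.start and m.end <= idr.end
            for idr in segmentation.idrs
        ):
            continue
        gap_ok = True
        for seg in ordered:
            if seg.end < m.start:
                gap = m.start - seg.end - 1
            elif m.end < seg.start:
                gap = seg.start - m.end - 1
            else:
                gap = -1
            if gap <= min_gap:
                gap_ok = False
                break
        if gap_ok:
            passed.append(m)
    if not passed:
        return []
    l_idr = sum(len(idr) for idr in segmentation.idrs)
    cap = max(2, int(motifs_per_100 * l_idr // 100))
    # Rank distinct k-mers by their best score; all positions of a kept
    # k-mer are reported but consume one budget unit.
    by_kmer: dict[str, list[ProteomeMotif]] = {}
    for m in passed:
        by_kmer.setdefault(m.kmer, []).append(m)
    ranked = sorted(
        by_kmer.items(),
        key=lambda kv: (-max(m.score for m in kv[1]), kv[0]),
    )
    kept: list[ProteomeMotif] = []
    for kmer, group in ranked[:cap]:
        kept.extend(sorted(group, key=lambda m: m.start))
    return kept


@dataclass(frozen=True)
class ControlKmer:
    protein_id: str
    source_kmer: str
    control_kmer: str
    start: int
    end: int
    replicate: int


def random_control(
    motifs: list[ProteomeMotif],
    sequences: dict[str, str],
    seed: int,
    n_replicates: int = 5,
) -> list[ControlKmer]:
    """Length-matched random windows from the same protein, 5 per motif."""
    rng = np.random.default_rng(seed)
    controls: list[ControlKmer] = []
    for m in motifs:
        seq = sequences.get(m.protein_id)
        if seq is None:
            continue
        k = m.end - m.start + 1
        if len(seq) < k:
            continue
        for rep in range(n_replicates):
            start0 = int(rng.integers(0, len(seq) - k + 1))
            controls.append(
                ControlKmer(
                    m.protein_id,
                    m.kmer,
                    seq[start0 : start0 + k],
                    start0 + 1,
                    start0 + k,
                    rep + 1,
                )
            )
    return controls
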