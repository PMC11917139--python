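"""Site- and residue-level precision/recall/F1 for motif predictions.

Predictions and annotations are 1-based inclusive intervals on named
sequences, grouped into classes (sets of sequences sharing one motif
type). A predicted site is a true positive when it shares at least one
residue with an annotated site; one prediction overlapping m annotated
sites contributes m true positives. At the residue level only unique
residues count (overlapping annotations are deduplicated) and the four
confusion counts are summed over all sequences of a class before
precision/recall/F1 are computed. Class summaries are combined as
unweighted means, so large classes do not dominate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .engine import CaptureResult, map_back_all
from .kmer import SequenceRecord
from .physchem import check_canonical


@dataclass(frozen=True)
class AnnotatedSite:
    class_id: str
    sequence_id: str
    start: int
    end: int
    motif_string: str | None = None
    regex: str | None = None


@dataclass(frozen=True)
class PredictedSite:
    sequence_id: str
    start: int
    end: int
    rank: int = 1


@dataclass
class ClassMetrics:
    class_id: str
    site_tp: int
    site_fp: int
    site_fn: int
    residue_tp: int
    residue_fp: int
    residue_fn: int
    residue_tn: int
    site_precision: float
    site_recall: float
    site_f1: float
    residue_precision: float
    residue_recall: float
    residue_f1: float


def _prf(tp: int, fp: int, fn: int, recall_mode: str) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    if recall_mode == "as_printed":
        recall = tp / (fp + fn) if fp + fn > 0 else 0.0
    else:
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    # A prediction may overlap several annotations (and vice versa), so
    # the ratios are clamped to honor the [0, 1] contract.
    precision = min(precision, 1.0)
    recall = min(recall, 1.0)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def site_metrics(
    pred: list[PredictedSite], annot: list[AnnotatedSite]
) -> tuple[int, int, int]:
    """(TP, FP, FN) at site level.

    TP: overlapping (prediction, annotation) pairs sharing >= 1 residue.
    FN: annotated sites touched by no prediction. FP: predicted sites
    touching no annotation. True negatives are not defined at this level.
    """
    tp = 0
    matched_annot = [False] * len(annot)
    for p in pred:
        hit = False
        for ai, a in enumerate(annot):
            if a.sequence_id == p.sequence_id and a.start <= p.end and p.start <= a.end:
                tp += 1
                matched_annot[ai] = True
                hit = True
        _ = hit
    fp = sum(
        1
        for p in pred
        if not any(
            a.sequence_id == p.sequence_id and a.start <= p.end and p.start <= a.end
            for a in annot
        )
    )
    fn = matched_annot.count(False)
    return tp, fp, fn


def residue_metrics(
    pred: list[PredictedSite],
    annot: list[AnnotatedSite],
    sequence_lengths: Mapping[str, int],
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over unique residues, summed over sequences."""
    tp = fp = fn = tn = 0
    for seq_id, length in sequence_lengths.items():
        pred_res = set()
        for p in pred:
            if p.sequence_id == seq_id:
                pred_res.update(range(p.start, p.end + 1))
        annot_res = set()
        for a in annot:
            if a.sequence_id == seq_id:
                annot_res.update(range(a.start, a.end + 1))
        tp += len(pred_res & annot_res)
        fp += len(pred_res - annot_res)
        fn += len(annot_res - pred_res)
        tn += length - len(pred_res | annot_res)
    return tp, fp, fn, tn


def evaluate_class(
    class_id: str,
    pred: list[PredictedSite],
    annot: list[AnnotatedSite],
    sequence_lengths: Mapping[str, int],
    recall_mode: str = "standard",
) -> ClassMetrics:
    s_tp, s_fp, s_fn = site_metrics(pred, annot)
    r_tp, r_fp, r_fn, r_tn = residue_metrics(pred, annot, sequence_lengths)
    sp, sr, sf = _prf(s_tp, s_fp, s_fn, recall_mode)
    rp, rr, rf = _prf(r_tp, r_fp, r_fn, recall_mode)
    return ClassMetrics(
        class_id, s_tp, s_fp, s_fn, r_tp, r_fp, r_fn, r_tn,
        sp, sr, sf, rp, rr, rf,
    )


def aggregate(metrics: Iterable[ClassMetrics]) -> dict[str, float]:
    """Unweighted means across classes (each class counts once)."""
    metrics = list(metrics)
    if not metrics:
        raise ValueError("no evaluable classes")
    n = len(metrics)
    fields = (
        "site_precision", "site_recall", "site_f1",
        "residue_precision", "residue_recall", "residue_f1",
    )
    out = {f: sum(getattr(m, f) for m in metrics) / n for f in fields}
    out["n_classes"] = float(n)
    return out


def curate_classes(
    annotations: list[AnnotatedSite],
    sequences: list[SequenceRecord],
    min_sequences: int = 3,
    min_length: int = 10,
) -> dict[str, list[AnnotatedSite]]:
    """Apply the benchmark curation rules and group annotations by class.

    Drops: sites whose motif string contains non-canonical residues,
    sites whose motif string fails the supplied regex (when both are
    given), annotations on sequences shorter than ``min_length``, and
    classes left with fewer than ``min_sequences`` unique sequences.
    """
    lengths = {rec.id: len(rec) for rec in sequences}
    kept: dict[str, list[AnnotatedSite]] = {}
    for a in annotations:
        if a.sequence_id not in lengths:
            continue
        if lengths[a.sequence_id] < min_length:
            continue
        motif = a.motif_string
        if motif is None:
            rec = next(r for r in sequences if r.id == a.sequence_id)
            motif = rec.residues[a.start - 1 : a.end]
        if check_canonical(motif) is not None:
            continue
        if a.regex is not None and not re.search(a.regex, motif):
            continue
        kept.setdefault(a.class_id, []).append(a)
    curated = {
        cid: sites
        for cid, sites in kept.items()
        if len({s.sequence_id for s in sites}) >= min_sequences
    }
    if not curated:
        raise ValueError("no evaluable classes after curation")
    return curated


def combine_top_k(result: CaptureResult, max_rank: int = 10) -> list[PredictedSite]:
    """Union of mapped sites of the top <= max_rank consensus k-mers.

    Overlapping mapped intervals within one sequence are merged so the
    predicted site set is disjoint (sensitivity-mode evaluation).
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for rank, ck in enumerate(result.consensus[:max_rank], start=1):
        for m in map_back_all(result, ck):
            intervals.setdefault(m.sequence_id, []).append((m.start, m.end))
    preds: list[PredictedSite] = []
    for seq_id in sorted(intervals):
        merged: list[list[int]] = []
        for start, end in sorted(intervals[seq_id]):
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        preds.extend(PredictedSite(seq_id, s, e) for s, e in merged)
    return preds


def top1_predictions(result: CaptureResult) -> list[PredictedSite]:
    """Default stringent mode: the rank-1 consensus, first mapped instance."""
    if not result.consensus:
        return []
    preds = []
    top = result.consensus[0]
    all_mappings = map_back_all(result, top)
    for rec in sorted(result.records, key=lambda r: r.id):
        mappings = sorted(
            (m for m in all_mappings if m.sequence_id == rec.id),
            key=lambda m: m.start,
        )
        if mappings:
            m = mappings[0]
            preds.append(PredictedSite(m.sequence_id, m.start, m.end, rank=1))
    return preds
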