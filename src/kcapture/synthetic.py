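"""Synthetic ortholog-like sequence sets with planted motifs.

The generator emulates a group of related disordered sequences sharing
one or more short motifs: random background residues (uniform or biased
toward the disorder-promoting set P,R,G,Q,S,K,A,E), motifs planted at
random non-overlapping positions, per-position substitutions that are
conservative (low Grantham distance), radical (high distance) or
uniform, optional indels inside the motif, and optional shuffling of
multi-motif order across sequences (a multivalent-motif stress case).
Ground-truth intervals are emitted alongside, so benchmark metrics can
be computed with no external data. Synthetic pLDDT tracks (high-
confidence background with low-confidence blocks) exercise the IDR
module. No phylogeny or rate heterogeneity is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._grantham import GRANTHAM_PAIRS
from .idr import PlddtTrack
from .kmer import SequenceRecord
from .physchem import CANONICAL_RESIDUES

IDR_BIASED_RESIDUES = "PRGQSKAE"


@dataclass
class PlantSpec:
    """Recipe for one ortholog-like set with planted motifs."""

    motifs: list[str]
    n_sequences: int = 10
    seq_length: int = 150
    background: str = "uniform"          # "uniform" | "idr"
    substitution_rate: float = 0.0       # per motif position
    substitution_mode: str = "uniform"   # "conservative" | "radical" | "uniform"
    indel_rate: float = 0.0              # per motif position
    shuffle_motif_order: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.motifs, str):
            self.motifs = [self.motifs]
        if not self.motifs:
            raise ValueError("at least one motif required")
        for m in self.motifs:
            if not m or any(aa not in CANONICAL_RESIDUES for aa in m):
                raise ValueError(f"motif '{m}' is not canonical")
        if sum(len(m) + 1 for m in self.motifs) > self.seq_length:
            raise ValueError("motifs do not fit in seq_length")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.substitution_mode not in ("conservative", "radical", "uniform"):
            raise ValueError(
                f"unknown substitution mode '{self.substitution_mode}'"
            )
        if self.n_sequences < 1 or self.seq_length < 1:
            raise ValueError("n_sequences and seq_length must be >= 1")


def _grantham_neighbors() -> dict[str, list[str]]:
    """Residues ranked by ascending Grantham distance from each residue."""
    dist: dict[str, dict[str, int]] = {aa: {} for aa in CANONICAL_RESIDUES}
    for (a, b), d in GRANTHAM_PAIRS.items():
        dist[a][b] = d
        dist[b][a] = d
    return {
        aa: sorted(dist[aa], key=lambda x: (dist[aa][x], x))
        for aa in CANONICAL_RESIDUES
    }


_NEIGHBORS = _grantham_neighbors()
_N_POOL = 3  # substitutions drawn from the 3 nearest/farthest residues


def _substitute(aa: str, mode: str, rng: np.random.Generator) -> str:
    ranked = _NEIGHBORS[aa]
    if mode == "conservative":
        pool = ranked[:_N_POOL]
    elif mode == "radical":
        pool = ranked[-_N_POOL:]
    else:
        pool = ranked
    return pool[int(rng.integers(0, len(pool)))]


def _mutate_motif(
    motif: str, spec: PlantSpec, rng: np.random.Generator
) -> str:
    out = []
    for aa in motif:
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(CANONICAL_RESIDUES[int(rng.integers(0, 20))])
        if spec.substitution_rate > 0 and rng.random() < spec.substitution_rate:
            out.append(_substitute(aa, spec.substitution_mode, rng))
        else:
            out.append(aa)
    return "".join(out) or motif[0]


def _background(length: int, kind: str, rng: np.random.Generator) -> str:
    if kind == "idr":
        # 80% mass on the disorder-promoting residues, 20% on the rest.
        probs = np.full(20, 0.2 / 12)
        for aa in IDR_BIASED_RESIDUES:
            probs[CANONICAL_RESIDUES.index(aa)] = 0.8 / 8
    elif kind == "uniform":
        probs = np.full(20, 1 / 20)
    else:
        raise ValueError(f"unknown background '{kind}'")
    idx = rng.choice(20, size=length, p=probs)
    return "".join(CANONICAL_RESIDUES[i] for i in idx)


def generate_set(spec: PlantSpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate sequences plus a ground-truth interval table.

    The truth table has columns sequence_id, motif (the original planted
    string), planted (the possibly mutated copy), start, end (1-based
    inclusive). Fully reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth_rows = []
    for si in range(spec.n_sequences):
        order = list(range(len(spec.motifs)))
        if spec.shuffle_motif_order:
            rng.shuffle(order)
        planted = [
            (spec.motifs[mi], _mutate_motif(spec.motifs[mi], spec, rng))
            for mi in order
        ]
        total_motif = sum(len(p) for _, p in planted)
        n_background = spec.seq_length - total_motif
        # Split background into len(planted)+1 chunks at sorted cut points.
        cuts = sorted(
            int(c) for c in rng.integers(0, n_background + 1, len(planted))
        )
        bg = _background(n_background, spec.background, rng)
        chunks = []
        prev = 0
        for c in cuts:
            chunks.append(bg[prev:c])
            prev = c
        chunks.append(bg[prev:])
        seq_id = f"seq{si + 1:03d}"
        parts = []
        pos = 0
        for chunk, (original, copy) in zip(chunks, planted):
            parts.append(chunk)
            pos += len(chunk)
            parts.append(copy)
            truth_rows.append(
                {
                    "sequence_id": seq_id,
                    "motif": original,
                    "planted": copy,
                    "start": pos + 1,
                    "end": pos + len(copy),
                }
            )
            pos += len(copy)
        parts.append(chunks[-1])
        records.append(SequenceRecord(seq_id, "".join(parts)))
    truth = pd.DataFrame(
        truth_rows, columns=["sequence_id", "motif", "planted", "start", "end"]
    )
    return records, truth


def generate_plddt(
    protein_length: int,
    idr_blocks: list[tuple[int, int]],
    protein_id: str = "synthetic",
    ordered_level: float = 90.0,
    disordered_level: float = 45.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlddtTrack:
    """High-confidence background with low-confidence blocks (1-based)."""
    blocks = sorted(idr_blocks)
    for i, (s, e) in enumerate(blocks):
        if not 1 <= s <= e <= protein_length:
            raise ValueError(f"block ({s},{e}) out of bounds")
        if i > 0 and s <= blocks[i - 1][1]:
            raise ValueError("overlapping IDR blocks")
    values = np.full(protein_length, ordered_level)
    for s, e in blocks:
        values[s - 1 : e] = disordered_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0, noise_sd, protein_length)
    return PlddtTrack(protein_id, np.clip(values, 0.0, 100.0))
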