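"""FASTA/TSV/JSON input-output, run manifests, output round-trips.

All tabular outputs are tab-delimited with a header row and 1-based
inclusive coordinates, and every writer has a matching reader so run
directories can be post-processed (extension, benchmarking, proteome
filters) without re-running the engine.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .engine import (
    CaptureResult,
    map_back_all,
    probability_matrix,
)
from .extension import ExtendedRegion
from .idr import DisorderSegmentation, PlddtTrack
from .kmer import SequenceRecord
from .physchem import check_canonical

logger = logging.getLogger(__name__)


@dataclass
class FastaPolicy:
    """How to handle awkward records: non-canonical residues and length."""

    noncanonical: str = "error"  # "error" | "skip"
    min_length: int = 10


def read_fasta(path: str | Path, policy: FastaPolicy | None = None) -> list[SequenceRecord]:
    """Read protein FASTA into validated records with unique ids."""
    policy = policy or FastaPolicy()
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id '{rec.id}' in {path}")
        seen.add(rec.id)
        bad = check_canonical(seq)
        if bad is not None:
            if policy.noncanonical == "skip":
                logger.warning(
                    "skipping '%s': non-canonical residue '%s'", rec.id, bad
                )
                continue
            raise ValueError(
                f"sequence '{rec.id}' contains non-canonical residue '{bad}' "
                "(use policy noncanonical='skip' to drop such records)"
            )
        if len(seq) < policy.min_length:
            logger.warning(
                "skipping '%s': length %d < minimum %d",
                rec.id, len(seq), policy.min_length,
            )
            continue
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no usable records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_plddt_tsv(path: str | Path) -> dict[str, PlddtTrack]:
    """TSV with columns protein_id, position, plddt (positions 1..L)."""
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for pid, group in df.groupby("protein_id"):
        group = group.sort_values("position")
        if list(group["position"]) != list(range(1, len(group) + 1)):
            raise ValueError(f"positions of '{pid}' are not contiguous from 1")
        tracks[str(pid)] = PlddtTrack(str(pid), group["plddt"].to_numpy())
    return tracks


def read_plddt_json(path: str | Path) -> dict[str, PlddtTrack]:
    """JSON object mapping protein id -> list of per-residue pLDDT."""
    data = json.loads(Path(path).read_text())
    return {
        str(pid): PlddtTrack(str(pid), np.asarray(values, dtype=float))
        for pid, values in data.items()
    }


def write_plddt_tsv(tracks: list[PlddtTrack], path: str | Path) -> None:
    rows = [
        {"protein_id": t.protein_id, "position": i + 1, "plddt": v}
        for t in tracks
        for i, v in enumerate(t.values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path, config: dict, inputs: list[Path] | None = None
) -> None:
    manifest = {
        "tool": "kcapture",
        "version": __version__,
        "config": config,
        "inputs": {
            str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
        "written": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def write_run_outputs(
    result: CaptureResult,
    out_dir: str | Path,
    inputs: list[Path] | None = None,
) -> Path:
    """Write consensus table, per-consensus mappings and probability
    matrices, plus a manifest. TSVs are byte-deterministic for a given
    input set and configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "mappings").mkdir(exist_ok=True)
    (out / "pssm").mkdir(exist_ok=True)

    cons_rows = [
        {
            "rank": ck.rank,
            "kmer": ck.kmer,
            "k": ck.k,
            "raw_score": ck.raw_score,
            "S_k": ck.search_space,
            "score": ck.score,
        }
        for ck in result.top
    ]
    header = f"# weighting={result.config.weighting}\n"
    cons_path = out / "consensus.tsv"
    with open(cons_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(
            cons_rows,
            columns=["rank", "kmer", "k", "raw_score", "S_k", "score"],
        ).to_csv(fh, sep="\t", index=False)

    for ck in result.top:
        mappings = map_back_all(result, ck)
        pd.DataFrame(
            [
                {
                    "sequence_id": m.sequence_id,
                    "mapped_kmer": m.mapped_kmer,
                    "start": m.start,
                    "end": m.end,
                    "support": m.support,
                }
                for m in mappings
            ],
            columns=["sequence_id", "mapped_kmer", "start", "end", "support"],
        ).to_csv(out / "mappings" / f"{ck.rank}_{ck.kmer}.tsv", sep="\t", index=False)
        if mappings:
            pm = probability_matrix(mappings)
            pd.DataFrame(
                pm.values, columns=list(pm.labels),
                index=pd.Index(range(1, pm.values.shape[0] + 1), name="position"),
            ).to_csv(out / "pssm" / f"{ck.rank}_{ck.kmer}.tsv", sep="\t")

    write_manifest(
        out,
        {
            "k_min": result.config.k_min,
            "k_max": result.config.k_max,
            "top_n": result.config.top_n,
            "matrix": result.config.matrix,
            "weighting": result.config.weighting,
            "score_mode": result.config.score_mode,
            "seed": result.config.seed,
        },
        inputs,
    )
    return out


def read_consensus(run_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "consensus.tsv", sep="\t", comment="#")


def read_mappings(run_dir: str | Path) -> dict[int, pd.DataFrame]:
    """Mapping tables keyed by consensus rank."""
    out = {}
    for path in sorted((Path(run_dir) / "mappings").glob("*.tsv")):
        rank = int(path.stem.split("_", 1)[0])
        out[rank] = pd.read_csv(path, sep="\t")
    return out


def write_extended(regions: list[ExtendedRegion], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "start": r.start,
                "end": r.end,
                "contributors": ";".join(
                    f"{kmer}:{score:g}" for kmer, score in r.merged_from
                ),
            }
            for r in regions
        ],
        columns=["sequence_id", "start", "end", "contributors"],
    ).to_csv(path, sep="\t", index=False)


def write_idrs(segmentations: list[DisorderSegmentation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"protein_id": seg.protein_id, "start": idr.start, "end": idr.end}
            for seg in segmentations
            for idr in seg.idrs
        ],
        columns=["protein_id", "start", "end"],
    ).to_csv(path, sep="\t", index=False)
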