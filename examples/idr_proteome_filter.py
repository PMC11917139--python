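"""Disorder segmentation and proteome-style motif filtering.

Builds a synthetic pLDDT confidence track (high-confidence structure
with one low-confidence block), segments it into ordered/disordered
regions, keeps only motif calls that sit inside the IDR and away from
structure, and draws length-matched random control k-mers.
"""

import numpy as np

from kcapture import (
    ProteomeMotif,
    filter_proteome_motifs,
    generate_plddt,
    random_control,
    segment_protein,
)
from kcapture.physchem import CANONICAL_RESIDUES

track = generate_plddt(300, [(100, 220)], noise_sd=2.0, seed=5)
seg = segment_protein(track)
print("segments:")
for s in seg.segments:
    print(f"  [{s.start:>3}, {s.end:>3}] {s.label}")
print(f"IDRs (disordered runs >= 30): {[(i.start, i.end) for i in seg.idrs]}")

# Candidate motifs: two inside the IDR, one hugging the boundary, one
# in the structured region.
motifs = [
    ProteomeMotif("synthetic", "QSPR", 130, 133, 40.0),
    ProteomeMotif("synthetic", "GRGK", 170, 173, 35.0),
    ProteomeMotif("synthetic", "AEAE", 108, 111, 30.0),  # near boundary
    ProteomeMotif("synthetic", "LVLM", 40, 43, 50.0),    # structured
]
kept = filter_proteome_motifs(motifs, seg)
print("\nkept after IDR containment, >2-residue gap and per-length cap:")
for m in kept:
    print(f"  {m.kmer} [{m.start}, {m.end}] score {m.score}")
# The structured-region motif and anything within 2 residues of an
# ordered segment are discarded; the cap allows two motifs per 100 IDR
# residues (minimum two).

rng = np.random.default_rng(5)
seq = "".join(CANONICAL_RESIDUES[i] for i in rng.integers(0, 20, 300))
controls = random_control(kept, {"synthetic": seq}, seed=5)
print(f"\n{len(controls)} random controls (5 per kept motif), e.g.:")
for c in controls[:5]:
    print(f"  {c.source_kmer} -> {c.control_kmer} [{c.start}, {c.end}]")
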