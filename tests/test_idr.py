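"""Disorder segmentation from pLDDT and proteome motif filters."""

import numpy as np
import pytest

from kcapture import (
    DisorderSegmentation,
    PlddtTrack,
    ProteomeMotif,
    Segment,
    call_disorder,
    extract_idrs,
    filter_proteome_motifs,
    random_control,
    reassign_small_segments,
    segment_protein,
    smooth_plddt,
)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        values = np.full(50, 70.0)
        assert np.allclose(smooth_plddt(values), 70.0)

    def test_terminal_window_shrinks_to_real_data(self):
        values = np.full(60, 90.0)
        smoothed = smooth_plddt(values)
        assert smoothed[0] == 90.0
        assert smoothed[-1] == 90.0

    def test_spike_spread_conserves_interior_mass(self):
        values = np.full(101, 50.0)
        values[50] = 65.0
        smoothed = smooth_plddt(values)
        # Direct convolution oracle for the interior.
        kernel = np.full(15, 1 / 15)
        expected = np.convolve(values, kernel, mode="valid")
        assert np.allclose(smoothed[7:-7], expected)
        affected = np.nonzero(smoothed != 50.0)[0]
        assert len(affected) <= 15
        assert smoothed.sum() == pytest.approx(values.sum())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_plddt(np.full(30, 50.0), window=14)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            smooth_plddt(np.array([]))


class TestDisorderCall:
    def test_threshold_is_inclusive(self):
        mask = call_disorder(np.array([65.0, 65.01, 64.99, 80.0]))
        assert mask.tolist() == [True, False, True, False]

    def test_constant_low_track_fully_disordered(self):
        assert call_disorder(np.full(40, 50.0)).all()

    def test_raising_threshold_never_shrinks_disorder(self, rng):
        values = rng.uniform(30, 100, 200)
        lower = call_disorder(values, 55.0)
        higher = call_disorder(values, 75.0)
        assert (higher | lower).tolist() == higher.tolist()


class TestReassignment:
    def test_small_ordered_island_flipped(self):
        mask = np.array([True] * 20 + [False] * 8 + [True] * 20)
        assert reassign_small_segments(mask).all()

    def test_island_longer_than_ten_unchanged(self):
        mask = np.array([True] * 20 + [False] * 11 + [True] * 20)
        assert reassign_small_segments(mask).tolist() == mask.tolist()

    def test_small_disordered_island_flipped_second(self):
        mask = np.array([False] * 20 + [True] * 8 + [False] * 20)
        assert not reassign_small_segments(mask).any()

    def test_terminal_segments_never_flipped(self):
        mask = np.array([False] * 5 + [True] * 40)
        out = reassign_small_segments(mask)
        assert not out[:5].any()
        assert out[5:].all()

    def test_alternating_islands_hand_worked(self):
        # D7 O4 D6 O12 D3: pass 1 flips both short ordered islands
        # (each flanked by disorder), merging everything left of the
        # long ordered block; pass 2 then finds the trailing D3 flanked
        # only on one side (terminal), so it stays.
        mask = np.array(
            [True] * 7 + [False] * 4 + [True] * 6 + [False] * 12 + [True] * 3
        )
        out = reassign_small_segments(mask)
        assert out.tolist() == [True] * 17 + [False] * 12 + [True] * 3

    def test_order_first_flag_changes_contested_case(self):
        # O12 D8 O4 D8 O12: ordered-first flips the O4 into one long
        # D20 (too long to re-flip); disorder-first removes both D8s.
        mask = np.array(
            [False] * 12 + [True] * 8 + [False] * 4 + [True] * 8 + [False] * 12
        )
        ordered_first = reassign_small_segments(mask, order_first=True)
        assert ordered_first.tolist() == [False] * 12 + [True] * 20 + [False] * 12
        disorder_first = reassign_small_segments(mask, order_first=False)
        assert not disorder_first.any()


class TestIdrExtraction:
    def test_run_of_29_dropped(self):
        mask = np.array([False] * 10 + [True] * 29 + [False] * 10)
        seg = extract_idrs(mask, "p")
        assert seg.idrs == []

    def test_run_of_30_kept(self):
        mask = np.array([False] * 10 + [True] * 30 + [False] * 10)
        seg = extract_idrs(mask, "p")
        assert seg.idrs == [Segment(11, 40, "disordered")]

    def test_fully_ordered_protein(self):
        seg = extract_idrs(np.zeros(80, dtype=bool), "p")
        assert seg.idrs == []

    def test_segments_tile_protein_exactly(self, rng):
        mask = rng.random(300) < 0.4
        seg = extract_idrs(mask, "p")
        covered = []
        for s in seg.segments:
            covered.extend(range(s.start, s.end + 1))
        assert covered == list(range(1, 301))
        for a, b in zip(seg.segments, seg.segments[1:]):
            assert a.label != b.label

    def test_full_chain_on_synthetic_track(self):
        from kcapture import generate_plddt

        track = generate_plddt(200, [(50, 120)])
        seg = segment_protein(track)
        assert len(seg.idrs) == 1
        idr = seg.idrs[0]
        # Window-edge smearing may shift boundaries by up to half a window.
        assert abs(idr.start - 50) <= 7
        assert abs(idr.end - 120) <= 7

    def test_constant_high_track_has_no_idr(self):
        seg = segment_protein(PlddtTrack("p", np.full(100, 90.0)))
        assert seg.idrs == []

    def test_constant_low_short_protein_is_one_idr(self):
        seg = segment_protein(PlddtTrack("p", np.full(40, 50.0)))
        assert seg.idrs == [Segment(1, 40, "disordered")]


def _segmentation():
    # Protein of 200: ordered 1-50, IDR 51-170, ordered 171-200.
    segments = [
        Segment(1, 50, "ordered"),
        Segment(51, 170, "disordered"),
        Segment(171, 200, "ordered"),
    ]
    return DisorderSegmentation("p", segments, [segments[1]])


def motif(start, end, kmer="QQQQ", score=10.0):
    return ProteomeMotif("p", kmer, start, end, score)


class TestProteomeFilters:
    def test_motif_two_residues_from_structure_rejected(self):
        seg = _segmentation()
        # Starts at 53: exactly 2 residues (51, 52) separate it from the
        # ordered segment ending at 50 — "more than 2" is strict.
        assert filter_proteome_motifs([motif(53, 56)], seg) == []
        kept = filter_proteome_motifs([motif(54, 57)], seg)
        assert len(kept) == 1

    def test_motif_outside_idr_rejected(self):
        seg = _segmentation()
        assert filter_proteome_motifs([motif(10, 13)], seg) == []
        assert filter_proteome_motifs([motif(168, 172)], seg) == []

    def test_cap_scales_with_idr_length(self):
        seg = _segmentation()  # L_IDR = 120 -> cap max(2, 2) = 2
        motifs = [
            motif(60, 63, "AAAA", 5.0),
            motif(70, 73, "CCCC", 4.0),
            motif(80, 83, "DDDD", 3.0),
        ]
        kept = filter_proteome_motifs(motifs, seg)
        assert sorted({m.kmer for m in kept}) == ["AAAA", "CCCC"]

    def test_cap_arithmetic(self):
        # Budget is max(2, floor(2 * L_IDR / 100)).
        def cap_for(l_idr):
            segs = [Segment(1, l_idr, "disordered")]
            seg = DisorderSegmentation("p", segs, segs)
            motifs = [
                ProteomeMotif("p", f"K{i:03d}", 5 + 6 * i, 8 + 6 * i, 100 - i)
                for i in range(6)
            ]
            return len({m.kmer for m in filter_proteome_motifs(motifs, seg)})

        assert cap_for(100) == 2
        assert cap_for(150) == 3

    def test_equal_scoring_positions_count_once(self):
        seg = _segmentation()
        motifs = [
            motif(60, 63, "AAAA", 5.0),
            motif(90, 93, "AAAA", 5.0),
            motif(70, 73, "CCCC", 4.0),
            motif(100, 103, "DDDD", 3.0),
        ]
        kept = filter_proteome_motifs(motifs, seg)
        # Cap 2: AAAA (both positions) + CCCC.
        assert [(m.kmer, m.start) for m in kept] == [
            ("AAAA", 60), ("AAAA", 90), ("CCCC", 70)
        ]

    def test_output_is_subset_of_input(self, rng):
        seg = _segmentation()
        motifs = [
            motif(int(s), int(s) + 3, f"M{i}", float(rng.integers(1, 50)))
            for i, s in enumerate(rng.integers(1, 195, 30))
        ]
        kept = filter_proteome_motifs(motifs, seg)
        assert set(kept) <= set(motifs)

    def test_protein_without_idr_keeps_nothing(self):
        seg = DisorderSegmentation("p", [Segment(1, 100, "ordered")], [])
        assert filter_proteome_motifs([motif(10, 13)], seg) == []


class TestRandomControl:
    def test_five_controls_per_motif(self):
        motifs = [motif(60 + 5 * i, 63 + 5 * i, f"M{i}") for i in range(10)]
        sequences = {"p": "ACDEFGHIKLM" * 30}
        controls = random_control(motifs, sequences, seed=3)
        assert len(controls) == 50

    def test_control_lengths_match_sources(self):
        motifs = [motif(60, 63), motif(70, 75, "QQQQQQ")]
        sequences = {"p": "ACDEFGHIKLM" * 30}
        for c in random_control(motifs, sequences, seed=3):
            src = next(m for m in motifs if m.kmer == c.source_kmer)
            assert len(c.control_kmer) == src.end - src.start + 1
            assert c.end - c.start + 1 == len(c.control_kmer)

    def test_seed_reproducibility(self):
        motifs = [motif(60, 63)]
        sequences = {"p": "ACDEFGHIKLM" * 30}
        a = random_control(motifs, sequences, seed=7)
        b = random_control(motifs, sequences, seed=7)
        assert a == b
        c = random_control(motifs, sequences, seed=8)
        assert a != c

    def test_enrichment_of_real_motifs_over_controls(self):
        """Planted 'annotation' intervals inside the IDR are hit more
        often by real motifs than by length-matched random controls."""
        rng = np.random.default_rng(99)
        l_prot = 400
        segs = [Segment(1, l_prot, "disordered")]
        seg = DisorderSegmentation("p", segs, segs)
        annotation = [(40 * i + 5, 40 * i + 12) for i in range(10)]
        motifs = [
            ProteomeMotif("p", f"M{i}", s, s + 3, 50.0 - i)
            for i, (s, _) in enumerate(annotation)
        ]
        seq = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, l_prot)
        )
        controls = random_control(motifs, {"p": seq}, seed=11)

        def hit_fraction(intervals):
            hits = sum(
                1
                for s, e in intervals
                if any(a <= e and s <= b for a, b in annotation)
            )
            return hits / len(intervals)

        real = hit_fraction([(m.start, m.end) for m in motifs])
        ctrl = hit_fraction([(c.start, c.end) for c in controls])
        assert real == 1.0
        assert real > ctrl
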