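# Methods

This note documents the model, its parameters and defaults, the
numerical and design choices, what the synthetic generator does and
does not emulate, and known limitations.

## Residue similarity

Conservation is assessed in physicochemical space. A 20×20 symmetric,
zero-diagonal, non-negative distance matrix D′ is rescaled to a
similarity matrix by min-max normalization,

    D(a, b) = 1 − D′(a, b) / max(D′),

so identity maps to 1, the most dissimilar pair (Cys–Trp at 215 in the
bundled Grantham table) maps to 0, and the ranking of all 190 residue
pairs is exactly reversed. The normalization function is a pluggable
argument of `distance_to_similarity`, so a per-pair rescaling or any
other monotone map can be swapped in without touching downstream code.
Non-canonical residues (B, Z, X, U, O, J) are rejected at ingestion by
default; a `skip` policy drops the offending sequences instead, which
mirrors how curated motif datasets are usually cleaned.

## K-mer matching

K-mer similarity is the mean of position-wise residue similarities,
w(x, y) = (1/k) Σ D(x_p, y_p) ∈ [0, 1]. For each unordered sequence
pair — including self-pairs, so n sequences give n(n+1)/2 comparisons —
the unique k-mers are compared all-vs-all and each k-mer keeps its
single best partner in the other sequence. Ties on w are broken by the
lowest LD(q, t) = 2(q² + t²)/(q + t) computed from the two k-mers'
occurrence frequencies; any remaining tie falls to lexicographic order
on the k-mer string, so selection is fully deterministic. The LD
expression is isolated in one function (`ld_tiebreak`) because its
printed form is typographically ambiguous; for singleton sources
(q = 1, by far the dominant case in non-repetitive sequence) every
plausible reading prefers the less frequent candidate, and the
lexicographic fallback guarantees reproducible output under any
reading. Reciprocal best matches — pairs chosen in both directions —
are the unit of conservation evidence. In low-complexity sequence the
same k-mer can occur many times; occurrences are counted by simple
sliding windows and a reciprocal event still counts once per pair.

## Scoring and ranking

A k-mer's raw score is the number of reciprocal events it appears in
across all pairs (on either side; a self-match counts once). A variant
that sums the similarities w of those events instead is available via
`score_mode="weighted"` for experimentation; plain counting is the
default. Raw scores are comparable only within one k: longer k-mers
find reciprocal partners less often because they live in a larger
search space. S_k is the number of unique k-mers of length k pooled
over the whole input set (sequences shorter than k simply contribute
nothing at that k), and the capture score is

    score = raw × f(S_k),    f(S_k) = S_k / 2 by default.

The factor is deliberately linear in S_k: the baseline probability of
a reciprocal hit scales roughly as 1/S_k, so multiplying by S_k puts
different k on a comparable footing; the alternative f(S_k) = S_k² is
selectable (`weighting="squared"`) and the choice is recorded in every
output header. Ranking is by descending score with ties broken toward
larger k (longer exact conservation is rarer), then lexicographically;
ranks are dense from 1. A useful consequence of counting self-pairs: a
k-mer present in m sequences has a raw-score floor of m.

Map-back locates a consensus k-mer in a sequence through its most
frequent reciprocal partner there (ties: higher mean w to the
consensus, then lexicographic); all occurrence positions of the winning
partner are reported, and a sequence sharing no reciprocal event with
the consensus gets no site. Mapped sites feed a k×20 empirical residue
probability matrix (one vote per mapping, rows sum to 1).

## Extension

Per sequence, the rank-1 consensus k-mer's mapped interval (lowest
start if it occurs several times) is grown by absorbing candidate
intervals — mappings of the top 10 consensus k-mers in that sequence —
that overlap it by at least one residue and score strictly above
0.9 × the top score. Both thresholds are configurable. Absorption
iterates to a fixed point by default, so a newly absorbed interval can
recruit further overlapping candidates; a single-pass mode judges
overlap against the seed interval only, for a stricter reading of the
rule. The result is independent of candidate order, always contains
the seed, and may exceed k_max in length. Extended regions are not
re-scored.

## Benchmark metrics

Predictions and annotations are 1-based inclusive intervals grouped
into classes. Site level: a predicted site sharing ≥ 1 residue with an
annotated site is a true positive, and one prediction spanning m
annotated sites counts m TPs (sequences may carry several instances of
the same motif); annotations touched by no prediction are FNs,
predictions touching nothing are FPs, and true negatives are undefined
at this level. Residue level: per sequence, unique predicted and
annotated residue sets produce TP/FP/FN/TN that tile the sequence
exactly; counts are summed over a class's sequences before computing
precision, recall, and F1. Precision = TP/(TP+FP),
recall = TP/(TP+FN), both 0 when the denominator is 0 (in particular
when nothing is predicted), F1 = 2PR/(P+R) with 0 at P=R=0. A
compatibility flag `recall_mode="as_printed"` computes TP/(FP+FN)
instead, a form that appears in some published method descriptions;
the standard form is the default because the rest of the evaluation
logic assumes it. Because multi-overlap counting can in pathological
many-prediction inputs push a ratio above 1, both ratios are clamped
to 1.0 to keep the documented [0, 1] contract. Class summaries are
unweighted means across classes, so a class with 100 sequences counts
the same as a class with 3.

Curation before evaluation: annotations with non-canonical residues in
the motif are dropped, as are annotations on sequences shorter than 10
residues; when a regex column is present, instances not matching their
class regex are dropped; classes keeping fewer than 3 unique sequences
are excluded (motif detection from 2 sequences is considered
unreliable). Default evaluation uses only the top-ranked prediction
per sequence (first instance on ties); a sensitivity mode evaluates
the union of the top-10 consensus k-mers' mapped sites, with
overlapping intervals merged.

## IDR segmentation and proteome filters

Per-residue pLDDT tracks are smoothed with a centered 15-residue
moving average whose window shrinks at the termini (no padding —
terminal residues are classified from real data only). Smoothed values
≤ 65 (inclusive) are disordered. Small segments of ≤ 10 residues
flanked on both sides by the opposite label are reassigned — ordered
islands first, then disordered islands, with the opposite pass order
available by flag since either reading of "first" is defensible;
terminal segments have a single flank and are never flipped. Maximal
disordered runs of ≥ 30 residues are IDRs.

Proteome-mode filtering keeps a mapped motif when it lies fully inside
an IDR and more than 2 residues (strict) separate it from every
ordered segment of the reassigned mask. Each protein's budget is
max(2, floor(2 × L_IDR / 100)) distinct k-mers by descending score,
where L_IDR is the summed IDR length of the protein — floor keeps "two
per 100 residues" exact at multiples of 100, and the floor of two
avoids silencing short-IDR proteins. Equal-scoring positions of one
k-mer are all reported but consume one budget unit. Controls draw, per
kept motif, five uniformly placed windows of the same length from the
same protein with a seeded generator.

## Synthetic data

The generator emulates an ortholog-like family: i.i.d. background
residues (uniform by default, or 80% of mass on the disorder-promoting
set P, R, G, Q, S, K, A, E to stress low-complexity behavior), one or
more motifs planted at random non-overlapping positions, per-position
substitutions that are conservative (drawn from the 3 nearest residues
by Grantham distance), radical (3 farthest) or uniform, optional
indels inside the motif, and optional shuffling of multi-motif order
across sequences (a multivalency stress case). Ground-truth intervals
track the possibly mutated copies exactly, so benchmark metrics need
no external data. Synthetic pLDDT tracks are a two-level step function
(≈90 ordered, ≈45 disordered) plus optional Gaussian noise.

Deliberately not emulated: phylogenetic correlation between sequences,
site-rate heterogeneity, realistic indel processes, compositional
drift, and annotation noise. Tests passing on these fixtures therefore
show that the machinery is correct under its stated model, not that
recovery rates transfer to real ortholog groups, where shared ancestry
correlates the noise and motifs can be partially absent.

## Default study conditions and problem sizes

Recovery experiments use the package's reference condition: 10
sequences of length 150, uniform background, one planted 5-mer, with
k = 3..10 and 100 seeded replicates per condition; oracle
cross-validation uses 20 random sets of ≤ 5 sequences of length ≤ 30,
where exhaustive nested-loop reference computation is cheap. Under the
verbatim condition the planted 5-mer outranks its own sub-k-mers
because every shared sub-k-mer compresses the smaller-k search spaces
(S_4 < S_5 whenever the 4-mer windows collide more), a small but
systematic margin — this is why the linear weighting suffices.

## Determinism

All tie-breaks are total orders, pair identity is by sequence id, and
mapping tables are sorted by sequence id and position, so outputs are
byte-identical under input permutation, reruns, and any worker count
(`processes` parallelizes over sequence pairs and reduces in a fixed
order). The only seeded randomness is in the synthetic generator and
the control sampler.

## Known limitations

- No statistical significance is attached to capture scores; ranking
  is relative within a run.
- Gapped motifs and wildcard positions are out of scope; a motif with
  a variable-length insertion is recovered, at best, as two motifs.
- The per-pair comparison is O(u_a × u_b) in unique k-mers, so very
  long sequences at small k dominate runtime; the engine vectorizes
  the inner product but does not approximate it.
- pLDDT ingestion expects per-residue tracks (TSV/JSON); parsing
  coordinates out of structure files is intentionally not core.
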