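# Methods

This note documents the model implemented by `fragscan`, the choices
made where the design was genuinely open, what the synthetic data
emulate, and the known limitations.

## The gene model

A sequence is modelled as alternating non-coding stretches and genes.
Hidden states (49 in total, see `fragscan/states.py` for the counting
convention):

* **Non-coding** `R`, emitting P(base | previous base).
* **Match states** `M1..M6` per strand: inhomogeneous codon-cycle
  states over two successive codons. `Mp` emits
  P(base | two preceding bases) with a period-specific table — the
  codon-usage signal. Two codons (rather than one) let the trained
  tables capture dicodon preferences.
* **Insertion states** `I1..I6` per strand: a sequencing error added a
  base to the read. Emission is uniform; the codon period is held
  across the run, so the reading frame resumes correctly afterwards.
* **Deletion states** (implicit): the read lost a base. Realised as a
  transition `Mp -> Mp+2` that consumes a single base while advancing
  the codon cycle by two. They are genuine states of the model
  inventory but never occupy a dynamic-programming row, which is why
  the DP table has 37 rows for 49 states.
* **Boundary composites**: start and stop codons are 3-base atomic
  units. Entering one scores a positional weight matrix (PWM) over a
  window (default 9 positions, odd, centred on the middle base of the
  codon; windows truncated at sequence ends score their in-range part).
  Reverse-strand genes are read left-to-right on the forward strand, so
  their stop composite comes first and their start composite last.

Transition weights come from five condition-level rates:
`noncoding_to_gene` (per-base gene entry, either strand), `gene_to_stop`
(gene exit at a codon boundary), `match_to_insert` and `match_skip`
(per-base insertion/deletion error rates) and `insert_continue`
(insertion-run extension). Weights within a gene are shared between
strands so that mirrored genes score identically; a consequence is that
outgoing weights of a few reverse rows do not sum exactly to one, which
is irrelevant for Viterbi decoding (only relative path scores matter).

Partial genes are first-class: a path may begin or end in any match or
insertion state (equal prior over the 25 legal initial rows,
log 1/25). Boundary composites are excluded at *both* sequence edges:
a path cannot start inside one, and — dually — cannot end on one. The
dual treatment is what makes decoding exactly strand-symmetric (see
below); the practical cost is that a start/stop codon flush against a
read edge is absorbed into a partial gene instead of being recognised.

## Numerical and algorithmic choices

* All scores are natural-log probabilities. Probability zero maps to
  the finite sentinel −10⁹ (`model.LOG_ZERO`); sums of a few sentinels
  stay finite and can never beat a real path, so no NaN/inf arithmetic
  arises and "impossible" is testable (`< −10⁸`).
* The DP is position-outer/state-inner over a dense 37×37 transition
  matrix; ties between equal-scoring predecessors resolve to the
  lowest-numbered row in the fixed row order (non-coding first), making
  decoding fully deterministic. The brute-force oracle implements the
  same rule globally: among equal-scoring paths, the one whose row
  indices read from the *last* position backwards are lexicographically
  smallest — provably the path the per-step rule reconstructs.
* Emission edge rules: an ambiguous base (anything outside ACGT) emits
  1/4 under every table; a position whose left context is incomplete or
  ambiguous emits from the context-uniform marginal of its table. The
  marginal (not a bare 1/4) keeps context-free tables exactly
  context-free, which the strand-symmetry guarantee relies on.
* GC binning: integer percent of unambiguous bases, rounded, clamped
  into the trained bin range; a sequence with no unambiguous base uses
  50%. Hard lookup, no interpolation between bins.
* The per-gene score is the mean per-base log-odds of the decoded gene
  path against the all-non-coding path over the same span, printed to
  6 decimals. Compatibility with other tools' score columns is not
  claimed.
* The `pwm` training file is a parameterized boundary-adjustment hook:
  per boundary kind, `weight · logpdf_Normal(raw_window_score; mu,
  sigma)` is added to the raw PWM score. Packaged and fixture data set
  weight 0 (hook disabled); it exists so a calibrated re-weighting of
  candidate boundary placements can be dropped in without a topology
  change.
* Operation counting: `DecodedPath.op_count` is the number of
  (predecessor, state) relaxations the recurrence evaluates — the
  hardware-independent measure used to verify linear scaling in the
  sequence length at fixed state count.

## Strand symmetry

Decoding a sequence and its reverse complement are related by a
bijection on state paths (match period p ↔ 7−p on the other strand,
composites reversed). Total scores are preserved under this bijection
iff (a) the reverse emission tables are the reverse-complement
transform of the forward ones, (b) boundary PWMs are mirrored
likewise, (c) initial/final treatment is dual (uniform prior, the
composite edge exclusion above), and (d) the rates are self-dual:
strand reversal swaps gene entry with gene exit and insertion-run entry
with exit, so `noncoding_to_gene == gene_to_stop` and
`match_to_insert == 1 − insert_continue`. `generate_params(symmetric=True)`
constructs exactly this (with context-free emission tables, for which
the transform is exact), and the symmetry tests then assert equality to
1e-9; asymmetric conditions trained on real data need not satisfy (d)
and then symmetry holds for interior genes but not for every
edge-truncated path.

## Parallel pipeline

The trained model is loaded once; worker processes are forked and share
it read-only. Reads are dispatched one at a time (no upfront chunking);
a single writer in the parent emits results, in input order by default
(`imap`) or as completed with `-u` (`imap_unordered`). Products no sink
requests are never rendered. With one worker the pipeline runs inline,
and ordered output bytes are identical for any worker count.

## Synthetic data: what it emulates, and what not

The fixtures module samples reads from the generative model itself:
non-coding flanks (≥10 bases; shorter flanks make edge-partial
interpretations of the boundary genuinely ambiguous), one planted gene
per read with explicit ATG start and a sampled stop codon, interior
codons drawn from the model's own context-dependent tables, and indel
errors at the requested per-base rates placed only where the topology
can represent them (never in boundary codons, no two consecutive
deletions, never immediately before a boundary). `gene_strength` scales
emission sharpness; at 0, coding and non-coding emissions coincide
exactly. Codon-completing stop triplets are damped by exp(−2·strength)
in generated coding tables, as trained tables would show. The packaged
default training set is generated the same way (fixed seed, mild
strength 2.0, per-bin GC tilt) and is *synthetic*: it demonstrates and
tests the machinery but is not a substitute for tables trained on
annotated genomes.

Consequences for interpreting green tests: passing recovery and
self-consistency tests show the decoder, backtracker and renderers are
correct *for data generated by the model's own assumptions*. Real reads
violate those assumptions (non-uniform error profiles, overlapping
genes, leader sequences, GC-heterogeneous contigs), so test pass rates
are not field accuracy estimates.

Problem sizes used by the test suite and the acceptance script —
200 oracle pairs at ≤12 bases, 100–1000 simulated reads of 80–300 bp,
one ≥100 kb genome — were chosen as the package's own verification
budget; all scale linearly if enlarged.

## Known limitations

* Only Viterbi decoding; no posterior/forward-backward support.
* The packaged training data are synthetic (see above); byte-level
  compatibility with FragGeneScan's training-file releases is not
  implemented — the `-r` directory must follow the documented dialect.
* Whole-genome mode differs from short-read mode only in expectation
  (long sequences, `complete` condition); no genome-specific
  post-processing is applied.
* A start/stop codon touching a read edge is not recognised as a
  boundary (see the symmetry discussion).
* Insertion states emit uniformly rather than from trained tables.
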