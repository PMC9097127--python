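# Methods

## Model and procedure

`primercover` treats multiplexed primer/probe design as set coverage:
the universe is the set of input sequences, and every distinct k-mer
occurring in them is a candidate set, covering exactly the sequences
that contain it as an exact substring.  Minimum set cover is NP-hard;
instead of solving it, the pipeline builds the *full* coverage and then
reduces its redundancy in linear passes:

1. sliding-window enumeration of all k-mers, indexed by coverage set;
2. optional GC screens on the candidates;
3. merging of candidates with identical coverage into primer clusters
   (interchangeable for covering purposes — a laboratory picks any one
   member of a cluster);
4. removal of clusters below the two size cut-offs;
5. size-ranking plus rounded cumulative-coverage annotation;
6. collapse of clusters tied on rounded cumulative coverage, keeping
   the largest.

Step 6 is where near-optimality comes from: a cluster whose rounded
cumulative coverage equals its predecessor's contributed fewer than
n·10⁻ᵈ new sequences, so at coarse d the tail of near-redundant
clusters collapses aggressively, while d fine enough that
10⁻ᵈ < 1/n removes exactly the clusters with zero marginal
contribution and provably preserves the covered union.  The procedure
is not the classical greedy set-cover algorithm (it never re-evaluates
marginal gains after each pick), which is what makes it one-pass and
linear; on small instances where the exact optimum can be enumerated,
the retained cluster count is typically within a few percent of it
(the acceptance script reports the measured ratio).

## Assumptions

- Hybridisation is modelled as exact substring identity on the given
  strand; no mismatches, no reverse complement (a future flag could add
  reverse-complement candidates), no thermodynamics (melting
  temperature, dimers and specificity screening are outside the
  method's scope).
- Windows containing any non-A/C/G/T letter are skipped rather than
  expanded into degenerate matches; expansion would silently change
  coverage semantics.  A sequence whose every window is ambiguous is
  reported as excluded.
- Duplicate input sequences are kept (distinct ids); headers are never
  used as keys.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `primer_length` (k) | 20 nt | window size; 20 nt is the conventional primer length, and an adjacent-probe pair can be designed as one 20-mer split into two 10-mers |
| `min_primer_group_size` | 1 | drop clusters offering fewer interchangeable primers |
| `min_sequence_group_size` | 2 | drop clusters covering fewer sequences; set to 1 to let singleton-coverage clusters through (needed if every sequence must be covered) |
| `decimals` (d) | 4 | cumulative-coverage rounding; coarser ⇒ stronger redundancy collapse |
| `gc_min` / `gc_max` | unset | allowed GC fraction of a primer |
| `max_gc_half_diff` | unset | allowed \|GC(first half) − GC(second half)\|; for odd k the first half takes ⌈k/2⌉ bases (a fixed convention — "two halves" needs one) |

All defaults are echoed into `config_used.yaml` and `description.txt`
next to the outputs.

## Numerical and ordering conventions

- "Ordered by size" is implemented as sequence-group size descending,
  then primer-group size descending, then the lexicographically
  smallest member k-mer — sequence coverage is the quantity being
  maximised, and the final tie-break makes output order reproducible
  across runs and platforms.
- Cumulative coverage counts the union of sequence groups (each
  sequence once), never the sum of group sizes, so it cannot exceed 1.
- Rounding is half-away-from-zero (`Decimal` quantisation), not
  banker's rounding.
- Cumulative values are computed once on the pre-collapse walk and
  frozen; they describe that walk and are deliberately not recomputed
  after the collapse.
- Within a tie group all co-maximal clusters are retained, not an
  arbitrary single one.
- Degenerate inputs: filtering everything out is legal at every stage
  and yields an empty cluster table with every sequence excluded (with
  a reason); only an input in which no sequence reaches length k is an
  error at enumeration.

## Implementation notes

For k ≤ 31 each window is packed two bits per base into a 64-bit
integer (the packing preserves lexicographic order), candidate
grouping is one `lexsort` over (code, sequence-id) pairs, the GC
screens are evaluated directly on the packed codes, and
coverage-identical clusters are found by bucketing coverage slices on
(size, order-independent 64-bit hash sum) with exact verification of
each bucket — Python objects are materialised only per cluster, never
per window.  This keeps per-window cost flat into the multi-megabase
range; the string-keyed mapping view of the index is built lazily when
accessed.  For k > 31 a dictionary-accumulation fallback over string
windows handles the (unusual) long-oligo case; both paths are tested
against the same naive oracle.

The heatmap is a two-colour `imshow` of the boolean matrix: rows are
clusters in rank order, columns sequence ids ascending, dark = covered.
An all-false column is an excluded sequence.

## Synthetic data

The generator has two regimes, both reproducible from a seed:

- `uniform_random`: every base i.i.d. uniform on {A,C,G,T}.  Emulates
  the scaling benchmark inputs (files of hundreds of sequences and up
  to millions of bases).  Independent random 20-mers essentially never
  collide, so these files exercise throughput, not cluster structure.
- `family`: a few ancestor sequences, each emitted as copies with
  i.i.d. substitutions at a per-base rate (default regimes here use
  2–5 %).  This produces the shared motifs — and hence multi-sequence
  clusters — that real heterogeneous panels (gene families, viral
  quasi-species) contain.  Sequence lengths are equal within a file.

What the generator does **not** emulate: insertions/deletions,
recombination, composition bias, phylogenetic (non-star) relatedness,
and real header metadata.  Tests passing on these fixtures therefore
demonstrate algorithmic correctness (coverage semantics, ranking,
collapse, determinism, scaling), not wet-lab primer quality on real
genomes.

## Problem sizes used in the test and acceptance runs

Correctness properties are checked on ~100 seeded fixtures up to 10⁵
bases (enumeration vs oracle), a 100-sequence × 200 bp family fixture
(cluster soundness by brute-force substring search), and 50 instances
of ≤ 12 sequences for the comparison against the exhaustive minimum
set cover.  The scaling harness runs 300-sequence files at 300 kb and
3 Mb with two repeats per size, reporting the minimum wall time per
size (the standard way to damp scheduler noise) alongside the exact
window counts Σ(L − k + 1), whose ratio is the deterministic linearity
witness; the wall-time ratio between the two sizes is asserted only
loosely, since absolute timings are hardware-bound.

## Known limitations

- Exact-match coverage only; a single substitution in a target defeats
  a primer, which is why family-like redundancy in the input is what
  creates useful clusters.
- The collapse step can discard a cluster that was some sequence's only
  cover when d is coarse; such sequences are reported in
  `excluded_sequences.tsv` with reason `no_shared_candidate_surviving`.
- `exact_min_cover` is an exhaustive test oracle for tiny instances
  only; it is never the production path.
- Memory holds the packed window arrays (~16 bytes per window), so a
  1 Gb genome collection would need a chunked variant not implemented
  here.
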