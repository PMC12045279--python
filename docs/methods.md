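# Methods

## The incremental-search model

A similarity search reports, for each query–subject high-scoring pair, a raw
alignment score S normalized to a bit score S′ = (λS − ln K)/ln 2 and an
expected chance-hit count E = m·n·2^(−S′), where λ and K are the
Karlin–Altschul parameters of the scoring system, m is the query length and
n the database length in residues. The bit score, the alignment coordinates
and the identity counts depend only on the query and subject sequences; the
database enters E only through the linear factor n.

Incremental search exploits this: when the database grows from batches with
residue counts n_1 … n_k, each batch is searched on its own and a hit's
e-value is recalibrated to the union by E → E·(Σn_i)/n_j. The merged table
is then re-ranked strictly by recalibrated e-value. For any engine whose
e-values are exactly linear in n this reproduces, field for field, the
result of one search against the union.

**Assumptions and limitations.** An m8/m8e row carries only the e-value and
bit score, so linear length scaling is the only recalibration recoverable
from the data. Real engines apply finite-size ("edge effect") corrections
and, in some modes, composition-based statistics whose parameters are not in
the row; for them the linear rescaling is an approximation, which is why
merged results from real tools correlate highly with, but do not exactly
equal, full re-searches. Batches are assumed disjoint in content; merging
overlapping databases is handled mechanically by HSP-level deduplication
(key: query, subject, both coordinate ranges; lowest e-value survives, ties
to the highest bit score) but no statistical claim is made for that case.

## File format

m8e is the 12-column BLAST tabular format preceded by one line holding the
total residue count of the searched database. The header is a bare decimal
integer — the minimal unambiguous encoding — and the parser also tolerates
`#db_length:<int>`. Later `#` lines are skipped on input (tabular-with-
comments tolerance) and never written. Coordinates are stored and re-emitted
exactly as read (1-based inclusive). The writer emits shortest-exact numeric
representations (scientific for e-values, positional for identities and bit
scores, always with a decimal digit), so write→parse is lossless for every
representable table; fixed-precision formatting would break the round-trip
guarantee for arbitrary doubles.

## Thresholding and caps

Filtering at the homology threshold (default 1e-5, strict `<`) happens only
when a report is finalized, never on the persisted merged state: rescaling
only ever increases e-values, so early filtering would be safe in one
direction only, and keeping the full state makes merging order-independent
and preserves hits for ratio analyses. Per-query hit caps (the default
limits search tools impose) are off by default, since caps suppress hits
that an uncapped incremental run retains. The persisted state is exactly an
m8e file; a resumed run therefore restarts its batch counter at one
consolidated batch, which does not affect any finalized output.

## The synthetic verification substrate

The generator emulates a class-structured protein database: `n_classes`
top-level classes, each with `n_families_per_class` families of
`members_per_family` sequences. Each family has one uniformly random parent
of `parent_length` residues (20-letter alphabet, no ambiguity codes);
members substitute each position with probability `mutation_rate` to a
different residue. Identifiers `c<class>_f<family>_m<member>` carry the
ground-truth labels. The pinned study configuration — 4 classes × 5
families × 6 members, length 120, mutation rate 0.1, split into 10
class-stratified batches with batch 1 held out as the 12-sequence query set
— keeps the whole study under a few seconds on one CPU while leaving every
query with same-family homologs spread across all database batches. The
stratified partitioner shuffles within each class (seeded) and deals
round-robin, so every batch matches the global class proportions within one
record per class.

What the generator does **not** emulate: indels (members differ from parents
by substitutions only), domain architecture, low-complexity regions,
realistic length variation, or substitution-matrix scoring. Passing tests
therefore demonstrate the correctness of the merge algebra and statistics,
not the biological behavior of any real search engine on real data.

The toy engine computes full affine-gap Smith–Waterman (match 2, mismatch
−1, gap open −2, gap extend −1 by default; identity scoring keeps the
brute-force oracle trivial) for every query×subject pair, converts raw
scores with fixed λ = 0.267, K = 0.041 (typical ungapped-matrix-scale
constants; all verified properties are relative, so their exact values are
immaterial), and reports rows whose bit score reaches `min_bit_score`
(default 25). Filtering on bit score — a database-size-independent quantity
— guarantees that partitioning the database never changes which hits exist,
only their e-values; it also keeps desk-scale tables to tens–hundreds of
rows. Traceback tie-breaks are fixed (diagonal over up over left; earliest
end cell wins score ties), making output byte-reproducible. The dynamic-
programming kernel is numba-compiled for speed; the test suite checks it
against an independent pure-Python exhaustive recursion on short sequences.

## Concordance statistics

- **Pearson** correlates e-values of (query, subject) pairs present in both
  tables, one value per pair (best HSP = lowest e-value). Default transform
  is −log10(E) with exact zeros floored at 1e-300, numerically sane across
  hundreds of orders of magnitude; `raw` is available.
- **Kendall tau-b** is computed per query over shared hits, ranked by
  (e-value asc, bit score desc, subject id asc), and averaged uniformly over
  queries contributing ≥2 shared hits — rankings are only meaningful within
  a query. A pooled variant is available behind a flag.
- **Ranking keys quantize e-values to 9 significant digits.** Rescaling
  leaves last-ulp noise, so two genuinely tied hits (equal bit scores)
  arriving from different batches could otherwise swap ranks against a
  direct search and spuriously depress tau. Treating e-values within
  relative ~1e-9 as tied matches the package's own merge-equivalence
  tolerance and lets the deterministic tie-breaks decide.
- **DCG** per query over the top `depth` hits: Σ rel_i/log2(i+1); log DCG is
  ln(1+DCG); nDCG divides by the ideal ordering's DCG (0 when the ideal is
  0). The relevance function is pluggable; the default scores 1 when the
  subject's class label equals the query's.
- **Containment** is |pairs(a) ∩ pairs(b)|/|pairs(a)| over distinct
  (query, subject) pairs, vacuously 1 for an empty a (logged).
- **Ratios** (hit counts, arithmetic-mean e-values), **zero-hit
  proportions** and **average hits per query** are computed after
  thresholding, with hitless queries kept in denominators.
- **Top-hit F1** predicts each query's class from its lowest-e-value hit
  (no-hit queries count as wrong) and macro-averages F1 over the classes
  present among the queries, so rare classes weigh equally.

Statistics with no defined value (fewer than two shared pairs, zero
variance, empty denominators) raise `UndefinedResultError` rather than
returning a sentinel.

## Numerical choices

- Rescaling is done in double precision; results below 1e-300 are clamped to
  exact zero (a per-process counter and debug log record each clamp).
- Exact-zero e-values are preserved through parse/write and rescale.
- Deterministic global hit order: query id, e-value, −bit score, subject id,
  subject start, query start.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  (configuration, seed) reproduce byte-identical FASTA and m8e output.

## Verification study sizes

The equivalence study (incremental vs full search) uses the pinned 120-
sequence fixture: 12 queries × 108 subjects per full search plus nine
12×12-subject batch searches, ~60 reported pairs — small enough that the
complete suite runs in seconds while exercising every code path, and large
enough that every query has cross-batch homologs. The metric cross-checks
run each statistic against an independent brute-force implementation on 100
seeded random tables, and the aligner against exhaustive recursion on 200
random short pairs.
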