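# Methods

## Scope and data model

The toolkit evaluates insertion/deletion structural-variant (SV) callsets
against a reference set, with stratification by tandem-repeat regions
(TRRs). Every record is normalized to a single representation:

* `chrom` without `chr` prefix (GRCh37-style callsets and hg19-style
  annotation tables then interoperate);
* `pos`/`end` are 1-based breakpoints; an insertion has a single breakpoint
  (`end = pos`), a deletion spans `(pos, end]`;
* deletion size is the interval length `end − pos`. When a record carries
  both END and SVLEN, the VCF layer (htslib) reconciles them for symbolic
  alleles; for sequence-resolved alleles the allele span is taken as
  coordinate ground truth and a >10 % discrepant SVLEN is warned about and
  ignored. Negative SVLEN is read as its absolute value, and a deletion
  missing END gets `pos + |SVLEN|`.

Inclusion rules at ingest (the `FilterPolicy`): size ≥ 50 bp (inclusive),
types INS/DEL only (BND, DUP, INV are recognized and counted but excluded),
autosomes 1–22 plus X and Y, optional PASS-only selection for truth sets,
and — for the PBHoney "Spots" dialect — the szCount/coverage quality ratio:
records with ratio < 0.2 are removed (a ratio of exactly 0.2 is kept). The
per-reason exclusion counters satisfy
`records_in = kept + Σ excluded`, and filtering is idempotent.

## Regions and coordinates

Regions are 0-based half-open `[start, end)` as in BED and RepeatMasker
tables; TRRs are rows with repClass `Simple_repeat` (short-pattern tandem
repeats) or `Satellite` (medium/long-pattern). A 1-based breakpoint `p`
maps to the 0-based point `p − 1`. A record is inside a region set when
*any* of its breakpoints is inside some region; this is the literal reading
of a breakpoint-overlap requirement, and `all`/`start` combinators are
available for sensitivity analysis. Adjacent or overlapping regions are not
merged, so region counts in reports reflect the source annotation
(membership is unaffected). Queries use an interval tree (O(log n + k));
the test suite checks equivalence with a linear scan.

## Matching

Candidates are same-chromosome, same-type pairs satisfying the type's
criterion — insertion breakpoint distance ≤ 200 bp (inclusive), deletion
reciprocal overlap ≥ 50 % (inclusive), where reciprocal overlap is
`min(o/ℓ_a, o/ℓ_b)`, i.e. the overlap must cover the threshold fraction of
*both* spans. Insertion sequence similarity is deliberately not evaluated;
the criterion is positional.

The one-to-one assignment maximizes (1) the number of matched pairs and
(2) the total quality among maximum-cardinality assignments, with quality
`1 − d/201` for insertions and the overlap fraction for deletions.
A best-score-first greedy sweep was considered and rejected: in chained
configurations (calls at 80 and 100 vs. references at 100 and 290 with a
200 bp window) greedy pairs 100↔100 and strands two matchable records,
whereas the optimum pairs both calls. The implementation decomposes the
candidate graph into connected components and solves each with the
Jonker–Volgenant solver (`scipy.optimize.linear_sum_assignment`) on a
benefit matrix `M + quality + ε·rank`, where `M` exceeds any achievable
quality sum (cardinality dominates) and the ε term implements the
deterministic tie-break (reference chromosome, reference position, call
position; ε = 1e−9, far below any meaningful quality difference). The test
suite verifies equality with a brute-force enumeration oracle on hundreds
of random fixtures with ≤ 8 records per side.

Benchmark comparison restricts *both* callset and truth to the benchmark
regions first; records outside contribute to neither TP, FP nor FN.

## Metrics and stratification

Precision, recall and F1 follow the standard formulas; a metric whose
denominator is zero is reported as NA (None/null), never 0, so empty strata
cannot fake perfect or zero scores. Size bins are half-open —
[50, 100), [100, 300), [300, 1000), [1000, ∞) — so the four bins tile
[50, ∞); the 1,000 bp boundary is assigned to the ">1000" bin (the side is
a convention, fixed and tested on both sides along with every other
boundary).

Stratified tables are computed match-then-stratify: matching runs once,
globally, inside the benchmark regions, and the resulting TP/FP/FN records
are distributed to strata afterwards. This prevents a call from going
unmatched merely because its true partner lies 1 bp outside a stratum
boundary; the alternative order is available (`stratify_first=True`) for
sensitivity analysis. A matched pair is counted in its reference record's
stratum (the benchmark composition defines the strata); FP calls and FN
references use their own. Stratum sums are conserved by construction and
asserted in tests. Pooled per-TRR-status rows are emitted in both
aggregations — micro (pooled counts) and macro (unweighted mean of the
defined per-type metrics) — since a pooled headline F1 is ambiguous between
the two.

The IMPRECISE-subset precision matches globally, then computes precision
over the calls carrying the flag; recall is not meaningful for a call
subset and is reported NA.

## Concordance and trios

When two callsets of the same sample are compared, the larger one is the
reference (ties: first operand) and the shared count is the number of
matched pairs. The three-set Venn is assembled from the three pairwise
comparisons via per-record "matched in X" labels. A true simultaneous
three-way assignment is ill-defined under pairwise one-to-one criteria, so
Venn counts are kept per set — each set's four regions sum exactly to its
size — rather than forced into seven global numbers that could disagree
between perspectives. Overlap rates (fraction matched in ≥ 1 other set) are
invariant to the order of the other sets.

Concurrent detection labels each truth record inside the benchmark regions
with the number of callsets whose independent pairwise benchmark comparison
matched it; the histogram of proportions sums to 1.

The trio de novo rate uses the same matching criteria as benchmarking: a
son call is de novo iff unmatched against both parents, and the rate is
stratified by the son record's TRR status. No genotypes are used; the rate
is an upper bound on true de novo events (it absorbs the son's false
positives and the parents' false negatives), which is precisely the
quantity the evaluation is designed to expose.

## Synthetic data

The generator's purpose is parameter recovery as an *integer identity*, not
a statistical tolerance. Defaults define the study conditions:

* genome: 3 chromosomes × 10 Mb on a 10 kb slot grid; every planted record
  gets its own slot, so distinct records are always > 200 bp apart and
  deletions never overlap across records — no accidental matches, and
  one-to-one assignment is unambiguous;
* truth: 1,000 SVs, 57 % insertions (the insertion fraction of a typical
  germline truth set), size mix (0.50, 0.30, 0.15, 0.05) over the four bins
  (counts fall fast with size; sizes within a bin are uniform, capped at
  5 kb by the slot geometry);
* TRRs: the first 10 % of every slot, giving an exact, configurable genome
  fraction; per-SV TRR placement probability follows an enrichment factor
  (default 4.4), which puts about one third of SVs inside TRRs, as
  long-read callsets show against a ~10 % genome fraction;
* derived callsets: per-profile FN rate (optionally higher inside TRRs),
  FP rate (false records on fresh slots, guaranteed unmatchable), breakpoint
  jitter ~ N(0, sd) rounded and clamped to the recoverable range (±200 bp
  for insertions; deletion endpoint shifts ≤ L/8, keeping reciprocal
  overlap ≥ 0.75 and span ≥ 50 bp), and an IMPRECISE flag rate. An optional
  unrecoverable fraction relocates calls to fresh slots — by construction
  those are FP and their truth partners FN;
* trio: the son's records are inherited copies of parental plants (with
  recoverable jitter) plus a de novo pool on fresh slots; parents carry
  additional non-transmitted records so the transmitted fraction of each
  parent's callset equals the configured inheritance rate (default 0.5).
  De novo counts are planted as exact integers, so planted rates like 0.2
  at n = 1,000 are recovered exactly.

Because recoverability is planted per record rather than left to jitter
tails, expected TP/FP/FN (global and per stratum) are recomputable from the
provenance labels, and measured precision/recall equal them exactly — with
or without jitter. All arithmetic is integer coordinate arithmetic under
`numpy.random.default_rng`, hence reproducible across platforms.

What the generator does **not** emulate: read-level evidence and
aligner-induced breakpoint bias, realistic insertion sequence content,
overlapping/nested true deletions (a separate stress generator exists only
inside the matching oracle tests), partial benchmark-region coverage
(generated benchmark regions span the whole synthetic genome; restriction
semantics are exercised by dedicated fixtures), and correlated errors
between pipelines. Passing recovery tests therefore validates the
*bookkeeping* — matching, stratification, rate formulas — not any claim
about real-data caller accuracy.

## Problem sizes and numerics

Default test and analysis runs use 1,000 truth records, three derived
callsets and a 1,000-record trio; the oracle-equivalence property runs 500
random fixtures with ≤ 8 records per side against exhaustive enumeration.
These sizes are the package's chosen desk-scale study conditions; the
module APIs take arbitrary sizes. Degenerate inputs are defined behavior:
empty strata give NA metrics, an empty son callset an NA rate, an empty
region query False, and an empty BED or an rmsk table with no qualifying
rows a hard error (almost certainly a schema mismatch).

## Known limitations

Genotypes, phasing and Mendelian-consistency analysis are out of scope, as
are sequence-resolved allele comparison, symbolic types beyond INS/DEL, and
confidence intervals on P/R/F1. Headline real-data figures (F1 of specific
callers on deep-coverage human trios) require the corresponding sequencing
data and truth sets and are deliberately not targets of this package's
tests; the toolkit reproduces the *methodology* and validates it on
synthetic data.
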