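# Methods

## The problem and the model

A 3′-RACE library of a single transcript reads across the exact RNA 3′
terminus: each read is, 5′→3′, a templated suffix of the transcript,
possibly a short non-templated tail, the ligated constant linker, and
downstream adapter sequence including a randomized molecular barcode.
`racemap` recovers, per read, the coordinate of the last templated base
and the non-templated addition (NTNA), then aggregates reads into
per-sample end distributions and isoform-class fractions.

The default coordinate frame and classes describe human telomerase RNA:
1-based sense-strand positions with position 1 the transcription start;
mature end 451; assignment window 366–641; classes sub_mature
([366, 450]), mature ([451, 451]), exS ([452, 460]), exL ([461, 641]),
plus reporting sub-bins 452–453, 454–457 and 458–459 inside exS. All of
these are model parameters and can be overridden; the hTR sequence is
supplied by the user as FASTA and never shipped.

## End assignment

Parameters (defaults): anchor length 20 nt, at most 2 substitutions in
the anchor, the 2 most-3′ anchor bases required to match exactly,
unbounded tail trim (up to insert length − anchor length), window
366–641.

For tail trim t = 0, 1, 2, … the anchor is the 20 insert bases ending
t bases before the insert's 3′ end. The anchor is compared at every
reference placement (Hamming distance; substitutions only, no indels —
indel tolerance would shift end coordinates unpredictably). The search
stops at the smallest t with any valid placement anywhere on the
reference:

- if a valid placement ends inside the window, the read is `assigned`
  to the most 3′ such coordinate and the t trimmed bases are its NTNA;
- if all valid placements end outside the window, the read is
  `out_of_window` and excluded from distributions (this is how reads
  from species ending beyond the window ceiling are kept out of the
  bounded tally rather than force-trimmed back to the boundary).

Inserts shorter than the anchor are `short_match`; exhausting all trims
without a placement is `no_anchor`. Ties do not arise: trims are probed
in increasing order and coordinates compared by position.

Two deliberate consequences:

- **Tail absorption.** Tail bases that match the reference continuation
  past the true end are indistinguishable from templated sequence and
  are absorbed: the assigned coordinate is an upper bound on the true
  end, with equality whenever the first tail base differs from the next
  reference base. This is inherent to calling the *most 3′* compatible
  coordinate, and the mismatch tolerance can occasionally absorb past a
  single non-matching tail base. All expectation calculations in the
  tests reconcile truth-table ends through the naive oracle for exactly
  this reason.
- **Terminal-exactness reading.** "Up to two mismatches not counting
  the two most-3′ bases" is read as: those bases must match exactly.
  The opposite reading (terminal bases free and uncounted) is available
  as `terminal_free=True`.

`oracle_assign_end` implements the identical contract by exhaustive
enumeration of every (trim, coordinate) pair with direct base-by-base
comparison. It exists so the vectorized implementation and a maximally
naive one can check each other; the equivalence is exercised on >10⁴
randomized inserts in the test suite.

## Linker location, barcode, deduplication

The linker is located as the 5′-most exact occurrence of its first
10 nt (a mismatch-tolerant scan exists but is off by default — the
protocol threshold is a length, and exact matching is its simplest
reading). The insert is everything 5′ of that offset, so an early
spurious match yields the shorter, conservative insert. The 10-nt
barcode is taken immediately 3′ of the full constant linker; where the
real protocol places it is not derivable from the library description,
so the position is configurable and the simulator and extractor share
the same convention. Reads truncated before a complete barcode are kept
but never collapsed.

Duplicates are collapsed on the (barcode, insert) key, keeping the
first occurrence. Collapsing on the barcode alone would merge distinct
molecules that collide in a 4¹⁰ space; including the insert makes the
collapse conservative. Whether the original analysis collapsed on
barcode alone or barcode+sequence is unknown; this choice is the safer
one and is logged per read (family size) for audit.

## Tallying and comparison

Distributions count every assigned read at its end coordinate,
irrespective of NTNA presence. Class and sub-bin fractions use assigned
reads as the denominator, over the whole window — sub-mature ends are
counted in it, not excluded (failure categories are reported
separately). Comparisons
are signed fraction differences, treatment − control, per coordinate
and per class; they sum to ~0 by construction. No significance test is
attached by default (none is standard for this readout); a chi-square
option exists.

## Synthetic libraries

The simulator's defaults are the study conditions used throughout the
tests: end distribution 5% sub-mature / 55% mature / 25% exS / 15% exL
spread uniformly within each class interval; tails on 50% of molecules,
pure oligo-A, geometric length of mean 5 capped at 30; 10-nt barcode;
substitution error rate 0.001 per base; geometric PCR copy number of
mean 2; 250-nt single-end reads; templated segment length uniform in
[40, 120] (a stand-in for the fixed forward primer of the real
protocol, which is not modeled). Errors are applied per molecule before
copying, so duplicate families are exact and deduplication has
unambiguous ground truth; a post-copy error mode exists but is off by
default. Not modeled: indels, quality-dependent errors, ligation bias,
RT drop-off. Passing tests therefore demonstrate correctness of the
analysis logic under a clean error model, not robustness to every
artifact of real libraries.

Tail composition, tail probability and the end distribution are
configurable; the geometric mean-5 tail mirrors the +5A species that
dominates oligo-adenylated intermediates in this system.

## Densitometry

Input is a long-format TSV (species, time in minutes, replicate,
intensity); band quantification from images is out of scope. Each
species is normalized per replicate to the loading control and then to
t = 0, making the series exposure-invariant and exactly 1 at t = 0.
The 50%-decay time uses log-linear interpolation between the two
sampled points flanking 0.5 by default — it assumes nothing about the
kinetics; on exact exponentials its error is <2% for sampling intervals
up to one half-life. A single-exponential fit (`method="fit"`,
least squares on log signal through the origin) is provided since the
interpolation-versus-fit choice of the original quantification is not
stated. Non-monotone series use the first downward crossing; series
never reaching 0.5 return the last time point flagged `reached=False`.

Fold changes are mean ratios of control-normalized replicate values;
the standard error comes from per-replicate ratios against the
reference mean, and significance from a two-sided two-sample Student's
t-test (equal-variance by default — the classical reading of
"Student's t-test" — with Welch available). Zero variance in both
groups is handled
explicitly: p = 1 for equal means, p → 0 flagged `degenerate`
otherwise. No multiple-testing correction is applied.

## Problem sizes and numerical choices

Test and acceptance workloads use seeded 700–750-nt random references,
libraries of 2,000–10,000 molecules, and ≥10,000 inserts for the
oracle-equivalence sweep — large enough that class-fraction recovery is
tested against exact 3σ binomial bands, small enough to run on a
laptop. Probability sums are validated to 1e-9; fraction conservation
likewise. Reads are validated to the A/C/G/T alphabet (U is normalized
to T on input; other characters are rejected rather than guessed).

## Known limitations

- Single-gene, single-end design; no general read alignment, no
  multi-gene references, no splice awareness, no paired-end support.
- The (barcode, insert) dedup key may keep two copies of a molecule
  apart if a sequencing error survives into one copy's insert
  (with per-molecule errors this cannot happen; with post-copy errors
  it can).
- Tail absorption biases assigned ends 3′ of true ends whenever the
  genomic continuation matches the tail base; analyses of A-rich
  reference regions should interpret single-coordinate shifts with
  care.
- The simulator's uniform within-class end distribution is a modeling
  convenience; real end distributions concentrate on specific
  coordinates.
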