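# Methods

## Filter model

A `FilterSpec` is a conjunction of optional criteria; an absent criterion
never excludes a record, so the empty spec is the identity filter and
adding a criterion can only shrink the matched set (a property the test
suite asserts on randomized records).  Conventions that the underlying
formats leave open are fixed as follows:

* **Template length.**  SAM's TLEN is signed (leftmost mate positive,
  rightmost negative).  Both `tlen_min` and `tlen_max` apply to |TLEN| so
  both mates of a pair receive the same verdict.  Bounds are inclusive.
* **Regions.**  Intervals are 1-based inclusive.  A record belongs to a
  region iff its leftmost position lies inside it (start containment).
  This avoids CIGAR-length arithmetic, makes verdicts independent of
  alignment details, and matches streaming behaviour.  Chromosome names
  are compared verbatim — no `chr` normalization.
* **Sequence pattern.**  A plain substring over {A,C,G,T,N},
  case-insensitive — deliberately not a regex, since the use case is "the
  sequence must contain this motif".
* **CIGAR regex.**  Implicitly anchored at both ends (full match), so a
  pattern like `\d+M` means "nothing but one match segment".
* **Tag regex.**  Matched (re.search) against the optional tags serialized
  exactly as SAM columns (`TAG:TYPE:VALUE`, tab-joined, original order),
  which gives the criterion a stable byte-level target.
* **Degenerate records.**  CIGAR `*` or an unmapped flag fails any CIGAR
  or region constraint but remains eligible under flag-only filters.
* Malformed regexes fail at spec construction, never per record.

Flag algebra covers the 12 standard bits.  `decode_flag` accepts the full
16-bit range but reports only named bits; the upper four are reserved by
the format and carry no standard name.

## Engine

A job = filter spec + file list (one BAM per individual) + output format
+ sink.  Planning produces exactly one task per file, order-stable;
cohort subsetting (explicit sample IDs, or population codes resolved
through the manifest) happens at planning time because it selects whole
files, not records.  Execution uses an in-process thread pool over a
single shared queue: workers pull the next pending task when free, which
is the scheduling contract that makes the merged output multiset
independent of worker count.  Threads (not processes) suffice because
pysam/htslib releases the GIL during decompression and the workload is
I/O-heavy at desk scale.

Failures are isolated per task: a retryable I/O error (unreachable
source) earns exactly one automatic retry, anything else fails the task
with its cause recorded; sibling tasks are unaffected and job-level
failure is reserved for an unusable sink.  Sinks implement a two-method
stateless contract — `put(name, bytes) -> locator`, `get(locator) ->
bytes` — implemented here for local directories; outputs are namespaced
by job id so jobs can share a sink.

Metrics are the standard ones: throughput = Σ bytes streamed / total wall
seconds, speedup Sₙ = T₁/Tₙ, scaled speedup Sₙ/n (1.0 = linear).  They
are computed from task accounting, never measured implicitly.

## Inversion scan

Input is assumed to be the output of a |TLEN| ≥ 600 bp reduction job (600
bp is the default threshold: it sits far above the ~400 bp fragment scale
of short-read protocols, so concordant background pairs cannot reach it).
The scan then applies, in order:

1. **Orientation**: keep paired records with flag bit 0x10 equal to bit
   0x20 (both forward or both reverse).  Using the mate-reverse bit means
   one streaming pass and an identical verdict for both mates — no mate
   lookup.  Properly oriented pairs with inflated |TLEN| (the deletion
   signature) are excluded here.
2. **Purity**: CIGAR must fully match `\d+M` and no XA tag may be
   present; soft-clips, indels and ambiguous mappings are noise for this
   analysis.
3. **Support**: each record's kb-scale bin (start and |TLEN| both floored
   at 1000 bp) must contain ≥ 20 distinct individuals.  Support binning
   and display binning are separate binnings, not rescalings of one
   another.  Note this stage is set-dependent — it does not commute with
   record-level predicates, and the support table must be built from the
   same record set it filters (asserted by tests).
4. **Summary**: per chromosome, the fraction of cohort individuals with
   ≥ 1 surviving alignment per (1 Mb start × 10 kb |TLEN|) display bin.
   Counting is per record with distinct-individual sets, so mates landing
   in the same bin cannot double-count their carrier.

Binning converts SAM 1-based positions to 0-based before floor division
(`⌊(pos−1)/scale⌋`).  Population contrasts subtract matrices built with
each population's own size as denominator; cells therefore live in
[−1, 1].  Heat maps render start bins on y, |TLEN| bins on x, with a
log10 color scale and zero cells masked to background (log of zero is
undefined, and absent evidence should look like background).

## Synthetic cohorts

The generator fabricates alignment geometry directly — no reference
sequence and no realignment, because every consumer of the pipeline reads
flags, positions, template lengths, CIGARs and tags, not base content
(sequence-motif tests plant literal motifs explicitly).  Defaults emulate
a low-coverage paired-end cohort: 100 bp reads, insert ~ Normal(400, 45)
truncated to [max(read length + 1, μ−4σ), μ+4σ], a handful of background
pairs per individual (coverage depth changes no tested contract, only
runtime), and a two-population split (CEU/EUR vs YRI/AFR) so population
contrasts are exercised.  Truncation at 4σ bounds every background
|TLEN| below 600 bp and keeps a planted event's |TLEN| = span + insert
inside a predictable window, which is what makes planted-bin recovery
exact rather than approximate.

Inversion carriers get same-strand pairs (both mates forward), deletion
carriers properly oriented pairs, both with |TLEN| = span + insert draw
and the leftmost mate at the event locus.  TLEN signs follow SAM
(leftmost positive), exercising the |TLEN| convention in the filter.
Noise injection rewrites `round(f·n)` records per class (soft-clip CIGAR
or XA tag), drawn without replacement from a seeded permutation, so
counts are exact and runs reproducible.  Each individual derives an
independent child RNG from the cohort seed; adding individuals never
perturbs existing ones.

What the simulator does **not** model: sequencing error, mapping-quality
structure, chimeric/split reads, duplicates, real insert-size tails, or
reference bias.  Passing tests therefore demonstrate the pipeline's
*logic* — signature selection, support arithmetic, normalization,
scheduling invariance — not calling performance on real data, where
orientation artifacts and mapping noise are substantially messier.

## Problem sizes and numerical choices

Tests run cohorts of 6–100 individuals with tens of read pairs each;
the end-to-end recovery check uses 100 individuals, three planted events
and 20% injected noise.  The randomized predicate-equivalence suite uses
1,000 records × 100 specs; round-trip checks use 10,000 records.  All
comparisons of frequencies are exact up to floating-point division (one
division per cell); no tolerance tuning is involved.  Ties and
degenerate inputs: empty inputs yield empty outputs (never errors),
empty region lists mean "whole genome", and matrices for chromosomes
with no survivors are simply absent rather than all-zero.

## Known limitations

* Start-containment region semantics differ from read-overlap semantics
  at region edges by up to one read length.
* The support filter's record-level counting treats each mate
  independently; distinct-individual sets make this harmless for
  frequencies but bin-level support can count both mates' bins of one
  pair separately.
* The IAF byte layout (leading individual/region columns) is this
  package's convention; other layouts exist in the wild.
* HTTP/FTP sources are passed through to htslib; region queries against
  remote sources are rejected unless the caller asserts an index is
  reachable — correctness is preferred over silent full downloads.
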