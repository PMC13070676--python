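# Methods

This note documents the algorithms, parameter choices and design decisions
behind `fragtyper`, and states precisely what the synthetic-data generator
does and does not emulate.

## Coordinates and variant representation

All public APIs and outputs use 1-based, fully-closed coordinates (the VCF
convention). Zero-based inputs are converted once, at parse time; BAM's
0-based coordinates are converted at read time. Keeping a single internal
convention removes the usual class of off-by-one bugs.

Every input mutation is reduced to one canonical form before analysis:

1. **Allele resolution.** Missing alleles (`-`, `.`, empty) are converted to
   anchored VCF representation by prepending the reference base immediately
   left of the event and decrementing the position. An anchorless insertion
   at position *p* is interpreted as inserting immediately *before* *p*.
   The REF allele is checked against the FASTA; contradictions are errors,
   not warnings.
2. **Normalization.** The standard left-align-and-trim fixed point for
   biallelic small variants (the algorithm `bcftools norm` applies),
   implemented natively: repeatedly trim a shared terminal base, extending
   left with the preceding reference base whenever an allele would become
   empty; then trim shared leading bases while both alleles keep length ≥ 2.
   Left-shifting stops at position 1. Normalization is idempotent, and the
   test suite verifies by brute force (apply-and-compare enumeration of
   every equivalent representation) that the whole equivalence class of an
   indel collapses to one canonical form.

Variants that remain length-changing block substitutions after trimming,
and symbolic/breakend ALTs, are rejected as COMPLEX with a clear error:
the tool's scope is small variants (SNV, MNV, simple indel).

## Fragment selection

Reads are fetched around each mutation within a window of ±`window_bp`
(default **600 bp**, enough to recover the full human cfDNA size range) and
filtered before pairing. Default filters are deliberately permissive:
unmapped, secondary, supplementary, QC-fail and duplicate reads are
dropped, `min_mapq` defaults to 0, proper pairing is not required; all of
this is configurable, including raw required/forbidden flag masks.

Window overlap is evaluated against the **outer span of the pair**, so a
fragment whose reads flank the mutation without covering it is still
selected (its genotype is then non-informative by lack of coverage). The
index query is widened by `pair_gap_bp` (default 1000 bp) so such
straddling pairs are recovered; fragments longer than the selection window
plus this margin would be missed, which is irrelevant for cfDNA (< ~500 bp
molecules). Templates whose mate is missing, unmapped or on another contig
are kept as single-read fragments with an explanatory flag rather than
silently dropped.

## Indel-aware fragment size

```
size = (outer_end − outer_start + 1) + Σ inserted − Σ deleted
       [+ outer soft clips if keep_outer_softclips]
```

Indel events are taken from both mates' CIGARs with VCF-style anchors. An
event lying inside both aligned spans (i.e. both mates *could* report it)
is counted once when the mates agree; when they disagree there, the
higher-MAPQ read's events are used (tie: left read) and the fragment is
flagged `size_discordant_mates`. Events outside the shared region are
counted once each.

Soft-clip policy: `keep_outer_softclips=True` (default) counts clipped
bases at the fragment's outermost aligned boundaries as molecule bases;
`False` treats them as technical artifacts (adapter read-through). A clip
is "outer" when it extends past `outer_start`/`outer_end`; when both mates
carry an outer clip at the same boundary (fully overlapping reads) the
larger one is counted, since they represent the same molecule bases. `N`
(reference skip) ops subtract like deletions by default and always raise a
flag — cfDNA data should not contain them.

Size is reported absent (NA) for single-read and non-convergent fragments.
A positive inner distance (unsequenced gap between mates) is assumed
indel-free: events there are unobservable. This is a documented limitation,
shared by any read-based method.

## End motifs

Motifs are k-mers (default **k = 5**, the conventional end-motif length)
taken **from the reference** at the fragment's aligned outer ends, both
reported reading 5′→3′ into the fragment: `motif5` is the top strand at
`outer_start`, `motif3` the reverse complement of the top strand at
`outer_end` (the end-motif literature's convention); the raw top-strand
string is also emitted (`motif3_top`) so either convention is recoverable.
Motifs anchor at aligned ends even when outer soft clips are kept for the
size; such fragments carry a flag because the true end may extend past the
anchor — reference-derived motifs cannot extend into unaligned sequence.

## Genotyping

**Window construction.** SNV/MNV: the substituted bases, plus a ±1-base
extended interval used *only* to flag potentially larger events (the flank
check changes flags, never the status). Indels: from the anchor base
through every perfect reference copy of the indel unit, plus one
terminating base — the smallest right edge at which no read observation can
be consistent with both haplotypes in a repetitive context.

**Read status.** The read's query bases over the window (insertions
anchored strictly inside it included, soft clips never) are compared with
the wild-type and mutated haplotypes. A read that fully spans the window
must match one of them exactly (neither → OTH). A truncated read is
compared against same-length prefixes (right truncation) or suffixes (left
truncation) of both haplotypes; when these coincide — a read ending inside
a homopolymer run is the canonical case — the read is AMBIGUOUS. Reads
truncated on both sides, or without coverage, are AMBIGUOUS. With
`min_baseq > 0` (default 0 = off), any window base below the threshold
makes the read AMBIGUOUS with flag `low_baseq`.

**CIGAR precedence for indels.** Each I/D event in the read's CIGAR is
left-aligned against the reference (the same normalization applied to input
mutations) and compared to the expected event; type, length and normalized
anchor must match exactly — near-miss lengths count as a different indel.
A matching event makes the read MUT regardless of the sequence verdict
(conflict flagged `cigar_seq_discordant`); a non-matching indel overlapping
the window flags `other_indel_present` but leaves the decision to the
sequence comparison. Because matching happens after left-alignment,
genotyping is invariant to the CIGAR encoding an aligner chose inside
repeats, and to the representation the user supplied the mutation in.

**Fragment aggregation.** Equal mate statuses are concordant; an absent or
non-covering mate leaves a single-read call; a definite status overrides an
AMBIGUOUS mate (`flag_resolved`); two unequal definite statuses are
irreconcilable with only two reads and become discrepant. Discrepant and
ambiguous fragments form the non-informative (NI) class, excluded from the
VAF denominator. A single AMBIGUOUS read yields NI with resolution
`ambiguous`. Aggregating per fragment — never per read — structurally
prevents double-counting overlapping mates in the VAF.

## Output

One TSV row per (fragment × mutation) with a stable documented schema
(`fragtyper.report.COLUMNS`); missing values are `NA`, empty flag sets `.`,
flags semicolon-joined. Per-locus VAF counts and locus status are stored in
`#`-prefixed header lines so a written table round-trips losslessly.
Optional per-read diagnostic columns (`--verbose-reads`) add flag, MAPQ,
CIGAR and status per mate. Output ordering is deterministic — (mutation
input order, outer_start, fragment_id) — and independent of the worker
count: threads parallelize over loci and results are reassembled in input
order. Plot functions compute a numeric matrix first (returned for testing
and reuse) and draw from it; the three motif bar-plot modes are per-group
proportion, raw count, and between-group difference.

The per-mutation cost is O(n·L) for n overlapping fragments of read length
L: every CIGAR is walked a bounded number of times, verified in the test
suite with an instrumented operation counter rather than wall clock.

## The simulator

`fragtyper.simdata` generates everything by construction: a seeded random
contig with planted mutation contexts; molecule lengths from a two-component
normal mixture — (167 bp, sd 10, weight 0.8) + (145 bp, sd 8, weight 0.2),
the mononucleosomal peak plus a shorter tumor-like component — truncated to
[60, 500] bp; paired 100 bp reads cut from each molecule with CIGARs derived
from the known edits (no aligner involved); base quality constant at Q37;
MAPQ 60. Mutated molecules are sampled per-fragment from a Bernoulli(VAF)
draw on the alternate haplotype, so the variant appears in SEQ and CIGAR
exactly as an aligner would place it; an option re-encodes deletions
right-shifted to exercise representation invariance. `TLEN` is written as
the signed outer reference span — deliberately indel-blind, reproducing the
discrepancy the package corrects. Errors are uniform substitutions at a
configurable per-base rate, with every hit logged (read, query index,
reference position) in the truth file.

Soft clips come in three explicit flavors: none (default; emulates
adapter-trimmed data), `read_through` adapter bases appended when the
molecule is shorter than the read (artifacts, excluded from the true size),
and `genuine` unaligned molecule bases at the outer ends (included in the
true size). The truth file labels which, so the size oracle can be checked
exactly under the matching policy.

Placement constraints: every simulated fragment covers its locus, and for
mutated indel fragments at least one read fully spans the event — molecules
whose indel falls entirely into clipped read tails are genuinely
unobservable from the BAM and are resampled. Consequences for
interpretation: passing tests demonstrate correctness of the measurement
given standard aligner behavior on observable events; they say nothing
about mapping artifacts, strand bias, PCR duplicates, quality-score
structure, or GC bias, none of which the simulator models.

Determinism: one `numpy` generator seeded from the scenario seed drives
everything; identical scenarios produce byte-identical FASTA/BAM/truth
outputs.

## Known limitations

- Indels in the unsequenced inner gap, or entirely inside soft-clipped
  tails, are invisible; sizes and genotypes are then computed from what the
  alignment shows.
- Definite-vs-definite mate conflicts are always non-informative; no
  flag-based override between two confident contradictory reads is
  attempted (with two reads there is no majority).
- Reference-derived motifs cannot reflect non-reference fragment ends
  (flagged when outer clips are present).
- Phasing across mutations, somatic-vs-germline classification, UMI
  handling and duplicate marking are out of scope.
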