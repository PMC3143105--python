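# Methods

## Model and procedure

The package operationalises the biogenesis model of piRNA-related 19mers
(pr19RNAs). Primary piRNAs (p-piRNAs, 5′-terminal U) guide endonucleolytic
cleavage of a complementary transcript across from their position 10; the 3′
fragment becomes a secondary piRNA (s-piRNA) with an A at read position 10,
and a second cleavage 19 nt upstream of that site releases an exact 19mer.
Because both cuts are positionally fixed, the 19mer carries no internal
sequence bias — its signature lives in the flanking reference sequence and
in its spacing to partner piRNA 5′ ends:

* configuration A (p-piRNA guided): sense 19mer with A 10 nt downstream of
  its 3′ end and no U immediately downstream (N₁₉·V·N₈·A); a same-sense
  s-piRNA 5′ end at +19 from the 19mer's 5′ end; an antisense p-piRNA 5′
  end at +28 (10 nt past the 19mer's 3′ terminal base).
* configuration B (s-piRNA guided), the mirror: sense 19mer with U
  immediately downstream; same-sense p-piRNA at +19; antisense s-piRNA at
  +28.

All read classification is done by `classify` from length, read positions 1
and 10, and the first and tenth downstream flanking bases; 24–30 nt reads
satisfying both or neither piRNA motif go to an explicit ambiguous class so
classification is total. U1 takes precedence over A10 for 19mers: the V in
the A10 motif excludes a downstream U by definition, so the two classes
cannot genuinely conflict.

Coordinates are 0-based half-open throughout; the internal alphabet is DNA
(reads are cDNA; U→T on ingestion). The 5′ coordinate of a minus-strand
alignment is its rightmost covered base, and all offsets are measured in
the anchor's reading direction — this single convention makes both
configurations land at +19/+28 on either strand, and is used consistently
for offset spectra, coverage densities, annotation (5′-base overlap) and
tile membership.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| homopolymer threshold | runs > 8 | nt | strict inequality; run of exactly 8 is kept |
| tRNA fragment | CCGGGTTTCGGCACC | — | matched in both orientations (conservative contamination filter; forward-only by flag) |
| simple repeats | (GGA)₄,(CCT)₄,(GAA)₄,(CTT)₄ | — | active only in LINE mode, where they cause mapping artefacts |
| mapper mismatches | 0–2 | subst. | substitution-only, end-to-end (-v-style); two-pass: exact vs a repeat database, then ≤2 mismatches vs the consensus |
| max hits | 50000 (pass 1), 10 (consensus) | placements | pass-1 cap mirrors a permissive repeat-database search; consensus hits are few |
| flank length F | 10 | nt | the motifs consult downstream positions 1 and 10 |
| offset window W | 60 | nt | covers both diagnostic peaks (+19, +28) with margin |
| multi-mapper cap | < 6 loci | loci | reads at ≥ 6 loci discarded; the rest assigned uniformly at random, seeded |
| tile width | 2500 | bp | genome split into non-overlapping tiles; final partial tile kept |
| library floor | > 100 | mappable reads | shallower libraries excluded from cross-library comparison |

## The mapper

`align.map_read` finds *all* end-to-end placements on either strand with at
most 0–2 substitutions, via exact k-mer seeding with
k = ⌊len/(mm+1)⌋: by pigeonhole, any qualifying placement contains a
mismatch-free chunk, so seeding is lossless; candidates are verified by
direct comparison. N never matches anything (including N), which both
prevents N-padding artefacts and preserves the pigeonhole guarantee.
Correctness is defined by a naive sliding-window oracle, against which the
mapper is property-tested; the seeding is purely an optimisation.

## The Wilcoxon signed-rank test

Implemented in-package because its exact behaviour is part of the contract:
zero differences dropped (classic; Pratt by flag), midranks for tied
|differences|, exact null distribution by dynamic-programming convolution
over doubled ranks for n ≤ 25, tie-corrected normal approximation with
continuity correction above. It is cross-checked in the tests against
brute-force 2ⁿ enumeration (n ≤ 10) and against an independent library
implementation on tie-free inputs. The normal approximation agrees with
enumeration to within ~10% in the moderate-p regime; in deep tails
(p ≲ 0.01) the relative error of any normal approximation grows, which is
why the exact path extends to n = 25.

## What the simulator emulates — and what it does not

`synthetic` plants both cleavage configurations with the exact geometry
above on an i.i.d. random reference, plus uniform degradation background.
Design choices:

* Site constraints (sense A at the cleavage coordinate with non-T at −9 for
  configuration A; sense T with non-A at +9 for B) are enforced by
  resampling candidate positions, never by editing the reference, keeping
  composition statistics clean. The B-site non-A constraint is required for
  the emitted reads to be unambiguous under the motifs.
* Events keep a minimum spacing (default 150 nt, registered on both
  strands) so no event falls inside another's offset window; noise-free
  offset spectra therefore place all query mass exactly at +19/+28.
  Consequently the default 50 kb reference comfortably hosts the default
  50+50 events.
* Copy counts are log-normal (µ=1.0, σ=0.8) — the heavy right tail typical
  of small-RNA libraries; pr19RNA copies are tied to their partner s-piRNA
  by the target ratio (default 2.5, reflecting pr19RNAs being more than
  twice as abundant as s-piRNAs at enriched loci).
* piRNA lengths follow a unimodal distribution over 24–30 peaking at 26
  (Mili-like) or 30 (Miwi-like) by a config switch.
* Antisense events are planted in reverse-complement sequence context and
  reflected back, so mirrored events satisfy the same motifs exactly.
* `simulate_genome` builds a toy multi-chromosome genome with an LTR repeat
  nested inside a piRNA cluster plus a gene per chromosome, planting events
  inside designated features so expected annotation categories are known —
  including the priority case (repeat beats cluster).

Not emulated: sequencing errors, PCR duplicates, repeat families with
internal phylogeny, chemical end modifications, and realistic abundance
landscapes. Passing tests on this generator demonstrate that the *geometry
and bookkeeping* of the pipeline are exact; they say nothing about
classification performance on noisy real libraries, where background
19mers overlapping piRNAs by chance will inflate configuration percentages
above their true cleavage-derived fraction.

## Numerical and degenerate-input choices

* Logo columns exclude N from the denominator; an all-N column has
  undefined information (reported as missing). Information is 2 − H bits,
  0·log 0 := 0.
* A 19mer whose decisive flank base (position +1 or +10) falls off the
  reference is OTHER_19MER with an `edge` flag rather than a guess.
* Offset spectra deduplicate anchors per (position, strand); window
  normalisation divides by the tallied mass (spectrum sums to 1),
  per-library normalisation by the total query copy count (both emitted,
  as the right choice depends on the question).
* Annotation overlap uses the read's 5′-end base only, making boundary
  reads unambiguous; within a track, ties go to the longest, then leftmost
  interval.
* Tile membership likewise uses the 5′-end base; "abundant p-piRNAs"
  excluded from tile selection is operationalised as p-piRNA > s-piRNA on
  that strand.
* Empty inputs return empty outputs (with warnings) rather than errors,
  except where a statistic is undefined (ratio of an empty tile selection,
  RPM with zero total).
* Class counts are copy-weighted by default (a collapsed read contributes
  its copy count), with a unique-sequence mode by flag, since the
  convention of the source counts is not always knowable.
* The percentage formatter rounds to the nearest whole percent for report
  tables; raw float percentages are always available alongside.

## Reproducibility

A single global seed fans out to per-stage seeds through a fixed
SeedSequence derivation; the run manifest records parameters, derived
seeds, input checksums and per-stage record counts, and reruns are
byte-identical. Multi-mapper assignment is the only seeded stage of the
genome workflow; with no multi-mappers its output is seed-invariant (and
tested to be).

## Problem sizes

The test suite and acceptance script run entirely on simulated data at desk
scale: references of 30–400 kb, libraries of hundreds of planted events,
100,000 background reads on 1 Mb for the null-rate estimate, and 500 tiles
per planted ratio for recovery checks — sizes at which every stage's
behaviour (including the exact-vs-approximate statistics) is fully
exercised in seconds.

## Known limitations

* The mapper is for consensus-scale references (kb–Mb), not whole-genome
  indexing; genome-scale alignments are expected to be imported as minimal
  SAM.
* The SAM dialect is deliberately minimal (all-match CIGAR, substitutions
  only); clipped or gapped records are skipped with a warning.
* Percentages of reads "in configuration" count exact 5′-coordinate
  matches; biological wobble at cleavage sites (±1 nt) is not absorbed, by
  design — it is visible in the offset spectra instead.
* The ambiguous piRNA class (both/neither motif) is reported, not resolved;
  resolving it would require probabilistic modelling outside this scope.
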