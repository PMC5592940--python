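# Methods

This note records the models behind each module, the tunable parameters
and their defaults, what the simulators do and do not emulate, and the
numerical choices made where the design was genuinely open.  It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## k-mer counting (`draftkit.kmers`)

Counting is exact and canonical: each window is keyed by
`min(kmer, revcomp(kmer))`, matching the default behavior of the
standard counters used for unstranded genome profiling.  Windows
containing any non-ACGT byte are skipped whole — no N-expansion — so
the conservation law `Σ_d d·c(d) = number of clean windows` holds
exactly and is property-tested.  For k ≤ 32 a k-mer packs into a
uint64 (2 bits/base) and counting is a few vectorized passes plus one
sort; k > 32 falls back to a dictionary scan.  This is deliberately
desk-scale: exact in-memory counting, no disk spill, no sketches.

## Genome profile (`draftkit.profile`)

Model: a haploid read set's depth histogram is an error limb decaying
from depth 1 plus a single-copy peak near `λ = C(r−k+1)/r`, plus
integer-multiple repeat peaks.  The peak model is fitted on a smoothed
histogram (moving average, default window 3 bins; the window is only
truncated at the low edge, because depths above the observed maximum
are real zeros, not missing data):

* **error cutoff** `d₀`: scan up from depth 1 while the smoothed counts
  strictly decrease; the depth where the descent stops is the valley.
  A histogram that never stops decreasing has no genomic peak and is
  rejected.  If the histogram rises immediately, `d₀ = 1` (no error
  limb, e.g. error-free simulation).
* **peak depth**: argmax of the smoothed counts at or above `d₀`
  (smallest depth on ties), refined to sub-bin precision by parabolic
  interpolation through the mode and its two neighbors, plus a +0.5
  continuity correction: for Poisson-like integer counts the
  histogram's modal bin sits about half a depth unit below the mean
  depth, and it is the mean that the size formula needs.  Without both
  refinements the integer mode alone quantizes `λ̂` by up to half a
  unit — a ~2% relative error at 25× k-mer depth, larger than the
  method's own agreement band.
* **peak bounds** `[d₀, min(2·peak − d₀, 1.5·peak)]`: the upper cap
  keeps the 2× repeat peak out of the single-copy interval.  Both the
  smoothing window and the cap are arguments.

Two expected-depth estimators are exposed, forced to agree on
symmetric peaks: `peak_mode` (the refined peak location) and
`peak_mean` (occurrence-weighted mean depth over the peak interval).
Genome size is `Σ_{d≥d₀} d·c(d) / λ̂`; error k-mers below `d₀` are
excluded as non-genomic.  The read-based uniqueness fraction is the
occurrence mass inside the peak interval over all genomic mass — an
interval definition, labeled as such in the JSON report, since a
fitted-peak decomposition would be a different (and heavier) model.
No mixture fitting for heterozygosity or ploidy is attempted: the
intended data source is haploid tissue.

## Assembly uniqueness (`draftkit.uniqueness`)

"Covered by unique k-mers" is operationalized as the fraction of
k-mer *start positions* whose canonical k-mer has assembly-wide count
exactly 1 — not base-level coverage — because the two differ at repeat
boundaries and the position definition is the sharper one.  N-runs
break windows exactly as in counting.  Counting is canonical
(strand-merged); the TSV output records this.  Ratios are exact, and
the test suite checks them against an independent per-position
dictionary count on every input.

## Read alignment (`draftkit.align`)

A minimal exact-seed (default 31 bp), ungapped-extension aligner
supports the QC and binning stages: seeds are packed uint64 values in
one sorted array, queried at read offsets 0, 31, 62, … plus the
read's trailing window (important for reads whose tail, not head, lies
on aligned sequence), on both strands.  `matched_bp` counts equal
bases over the full read span; the caller picks the threshold (0.9 for
QC alignment, 0.2 for gap binning, where a read half-buried in gap Ns
must still register).  No indels, no clipping across contig ends —
adequate by construction for substitution-only simulations, and
documented as such.

## Mate-pair QC (`draftkit.matepair`)

The junction adapter defaults to the Nextera junction duplex (19-bp
transposase recognition sequence joined to its reverse complement,
38 bp); the kit, not the sequence, is public in most protocols, so the
sequence is configurable.  Adapter search allows ≤ 1 mismatch
(configurable) in either orientation; reads are trimmed to the prefix
before the first occurrence.  Categories: A adapter in both reads, B
read 1 only, C read 2 only, D neither; the read-1/read-2 convention is
internal to the upstream tool family, so this package fixes and
documents it rather than guessing the original.  Category D is removed
before all downstream estimates.

PCR duplicates: a pair is a duplicate when both mates share (contig,
start, strand) with an earlier pair; unaligned pairs fall back to an
exact 32-bp prefix signature.  Coordinates rather than raw sequence
tolerate sequencing error.  Innies: any same-contig placement pair
that is inward-facing (FR) with outer span ≤ `max_innie_sep`, default
`min(1000, 0.2 × nominal insert)` — "too close together" made
concrete; true outward-facing pairs at the nominal span can never
trigger it.  Clone coverage sums inferred fragment lengths (outer
alignment span when both mates place on one contig, nominal insert
otherwise) over non-duplicate kept pairs, divided by genome size.
Rates are reported over kept (A/B/C) pairs, the set actually presented
downstream.

## Gap closing (`draftkit.gapclose`)

Two closers run in sequence per gap, mirroring a two-stage finishing
workflow: exact-span first, mini-assembly second.

**Exact-span closer** (`k_exact = 63`): a single read (either strand)
containing `left_flank[-63:] + interior + right_flank[:63]` as one
exact substring closes the gap; all spanning reads must agree on the
interior, any disagreement falls through.  Arithmetic limits this to
interiors ≤ read length − 126.

**Mini-assembly closer**: the gap's read bin is every read whose
alignment overlaps a 200-bp window on either side of the gap, plus all
their mates (the mate channel is what reaches gap interiors deeper
than a read).  For k from 150 down to 19 — largest k is most
repeat-resistant — the bin (reads + reverse complements) is hashed
with a rolling 64-bit multiplicative hash; edges are (k+1)-mers, and a
walk starts from the k-mer ending at the left flank's gap edge toward
the k-mer starting at the right flank's gap edge, bounded by
`estimated_gap + 2k + 200` steps.  The walk follows an edge only when
it has support ≥ 2 reads (error suppression), but any *observed*
competing edge — even a single read — counts as a branch and fails the
k: a repeat's alternative continuation must not vanish merely because
it was undersampled at the current k.  A path in one direction is
accepted only if the opposite direction did not itself detect a
branch (it may dead-end for coverage reasons); a branch seen from
either side is positive evidence of ambiguity, and the gap stays open.
This is slightly stricter than "unique in at least one direction" and
is the package's safety choice: on the simulated study conditions it
removes the rare spurious closures of repeat-trap gaps without
affecting unique-context closure rates, and a false "open" only costs
a gap, while a false fill corrupts the assembly.  Hash collisions
(~n²/2⁶⁴ per gap) are negligible at bin sizes of a few hundred reads;
the target k-mer is verified by string comparison on hash match.

The flank-anchored reading of the bin/anchor construction is used: the
path is anchored in the flanks, with all bin k-mers available to the
graph.  Closures are applied right-to-left per scaffold so earlier
coordinates stay valid; bases outside gap intervals are never touched
(byte-level invariant, tested everywhere).

**Redundancy removal**: contigs shorter than 2 kb (configurable) are
removed when they, or their reverse complement, align inside a newly
filled region ± one flank at ≥ 98% identity over ≥ 95% of their
length.  Containment is tested by infix edit-distance alignment
(edlib): the full contig at the identity budget first, then its
central 95% core.  The thresholds are not from any published
pipeline; they are chosen conservative and exposed as arguments.

## Assembly statistics (`draftkit.stats`)

Contigs are maximal N-free runs of scaffolds (split at every N by
default; `min_gap_run` restricts splitting to longer runs).  The N50
uses the genome-size-normalized convention; with `G = Σ lengths` it
reduces to the classical N50 (oracle-tested), and an assembly that
never reaches `G/2` returns its smallest element flagged
under-assembled.  The reporting floor is 150 bp, configurable.
Singletons — small contigs never scaffolded — are an input label, not
inferred, and are summarized as their own element class.

## Synthetic data (`draftkit.simulate`)

The generators emulate exactly the statistical structure the
estimators assume, and no more:

* **Genomes**: i.i.d. uniform background with planted repeat families;
  the repeat fraction splits evenly across `n_families ×
  copies_per_family` copies, each copy an independently mutated
  consensus (per-base substitution at the divergence rate, always to a
  different base).  Two copies therefore share a fraction ≈ (1−d)²ᵏ of
  their k-mers.  No transposable-element sequence model, no GC bias,
  no indels.
* **Paired-end reads**: uniform fragment starts, normal insert length,
  FR orientation, substitution-only errors, constant read length
  (default 151 bp) and constant quality.  Per-position depth is
  Poisson to within sampling error (tested).
* **Mate pairs**: true pairs map outward-facing with outer span equal
  to the clone length; the junction adapter sits at the circularization
  point, so the read portion before it comes from one clone end and
  the portion after it crosses the junction.  Categories are drawn
  A:B:C = 0.5:0.25:0.25 with adapter offsets uniform in [40,
  read_len − adapter_len] — offsets below 40 bp would leave trimmed
  reads too short to seed-align, which models size selection rather
  than QC convenience.  Innies are inward FR pairs with spans uniform
  in [2·read_len + 20, 0.2 × insert]; they carry the adapter (they are
  circularization artifacts, not untagged chimeras) and so survive
  category filtering, which is what makes them worth detecting.
  Adapter-free pairs model untagged chimeras and become category D.
  PCR duplicates re-emit a previous clone's reads verbatim.  A pandas
  registry records every pair's clone, kind, category and duplicate
  flag for parameter-recovery tests.
* **Gapped scaffolds**: chosen intervals are overwritten with N-runs
  of the same length; true interiors are recorded.  Random gaps keep
  ≥ 2 flanks of clearance from each other.  **Repeat traps** rewrite
  the genome so a 200-bp block appears both inside a future gap's
  interior and just left of the gap (inside the future left flank):
  any flank-anchored walk then branches on exit from the block in
  both directions at every k ≤ 150, so a sound closer must leave the
  gap open.  Trap zones keep extra clearance from random gaps.

Everything is reproducible from an integer seed; identical seeds give
byte-identical reads, genomes and downstream reports.

What passing these tests does *not* show about real data: indel
errors, coverage bias, chimeric reads beyond the modeled classes,
heterozygosity, and repeat families with realistic internal structure
are all absent.  The estimators' contracts (conservation laws, oracle
equivalence, flank preservation, branch safety) are exact and carry
over; the quantitative recovery results are specific to the simulated
conditions.

## Problem sizes and runtime

The default verification sizes are chosen so the whole suite runs in a
few minutes on one CPU while keeping every estimate comfortably out of
the small-sample regime: 1 Mb genomes at 30× for size recovery, a 2 Mb
genome with 200 random gaps plus 20 traps at 40× for gap closing,
20,000 pairs for mate-pair recovery, and a 150 kb end-to-end demo.
Memory stays under a few hundred MB; the k-mer counter chunks its
input at 8 Mb of sequence per pass.

## Known limitations

* The aligner is ungapped; an indel in a read shifts everything
  downstream of it.  Fine for the substitution-only simulator, a real
  limitation on real reads.
* The one-mismatch adapter search misses junction fragments split
  across a read boundary (partial adapters), which a specialized
  junction caller recovers.
* The gap closer's cross-direction branch veto can leave open a gap
  whose repeat sits entirely on one side; this is accepted as the
  safe direction of error.
* With sequencing errors enabled, the "any observed competing edge"
  branch rule becomes conservative (error k-mers can mimic branches),
  lowering closure rates; raising `min_support` and the error rate
  together has not been calibrated beyond the error-free study
  conditions.
* The peak-model continuity correction assumes a Poisson-like peak;
  strongly overdispersed real libraries may need the `peak_mean`
  estimator instead (which needs no such correction).
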