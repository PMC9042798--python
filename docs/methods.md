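# Methods

## Model and coordinate conventions

eccDNA molecules are modelled as single-chromosome circularisations of a
reference interval `[start, end)` (0-based, half-open; length = end − start).
Sequencing a rolling-circle-amplified circle yields fragments living on the
circle's modular coordinate space, which leaves two alignment signatures on
the linear reference:

- **split reads** — a read crossing the junction aligns in two segments, one
  ending at `end`, one starting at `start`, in *back-to-junction*
  configuration: the matched-then-clipped segment maps downstream of the
  clipped-then-matched one (the reverse of a linear deletion split);
- **discordant pairs** — a fragment straddling the junction without a
  junction-crossing read produces an outward-facing pair (reverse mate at
  the lower coordinate).

Calling operates only on these signatures plus primary-alignment depth; it
does not realign reads. The junction reconstruction rule is strand-symmetric
because SAM stores sequences in reference orientation: for any split with
segments on the same chromosome and strand, `start` is the reference start
of the leading-clip segment and `end` the reference end of the
trailing-clip segment, and the configuration is circular iff the
trailing-clip segment maps downstream.

## Caller parameters

| parameter | default | meaning |
|---|---|---|
| cluster tolerance | ±5 bp | split junctions within this of a cluster's modal breakpoints join it; consensus = mode, ties to the smaller coordinate |
| coverage window | 50 bp | coverage-increase windows just inside/outside each breakpoint |
| score cap | 10 | per-split-read contribution to the circle score |

The six filters (split ≥ 2, score ≥ 20, coverage increase ≥ 0.33 at both
breakpoints, continuity ≤ 0.1, SD < mean) use inclusive comparisons except
the SD criterion, which is strict. **Circle score** here is a documented
surrogate, Σ min(MAPQ, 10) over supporting split reads, chosen so the joint
defaults (split ≥ 2, score ≥ 20) are met exactly by two uniquely mapped
split reads; it is not the probabilistic realignment score of dedicated
callers and is not claimed equivalent. Coverage increase is
`(c_in − c_out)/c_in` (0 when `c_in` = 0), so the 0.33 default means inside
coverage ≥ 1.5× outside. Continuity is the fraction of zero-coverage
positions inside the circle. Only primary alignments (not supplementary,
secondary, duplicate or QC-fail) contribute to coverage.

Deduplication is per sample by exact `(chrom, start, end)`, keeping the
highest-scoring record; pooled totals across samples are reported as
aggregates without cross-sample deduplication. EPM is
`n_circles / (mapped_reads / 10^6)` and is invariant under joint scaling of
both counts.

## Enrichment statistics

Circles are mapped to genomic element classes by their junction coordinates
(`start` and `end − 1`). The observed/expected ratio divides the fraction of
junction coordinates inside the class (two per circle) by the class's merged
length over the genome length. Counting junction *coordinates* rather than
"circles with ≥ 1 junction inside" makes the ratio calibrate to exactly 1 on
a uniform random null for element classes of any length; the per-circle
variant would approach 2 for classes shorter than a circle. Both the
per-circle rule (`mode="circle"`) and an any-overlap rule (`mode="overlap"`)
remain available, and a circle whose two junctions fall in different classes
counts independently in both (no exon-over-intron precedence). Intragenic
statistics deliberately use the per-circle rule (a circle is intragenic when
either junction lies in a gene body), since that is the natural per-molecule
question and gene bodies are long relative to circles.

The repeat mapping ratio divides the fraction of primary-aligned reads
overlapping a repeat class by ≥ 1 bp by the class's genome fraction; a read
overlapping two classes counts once in each.

The random baseline draws each circle's chromosome with probability
proportional to chromosome length — the only reading of a "length-weighted"
genome-wide expectation consistent with a uniform null — with uniform starts
and sizes uniform on [150, 850] bp. Circles running past a chromosome end
are resampled (not clipped), preserving the size distribution. No
assembly-gap masking is applied by default; the generator is exact on toy
genomes without N-runs.

## Junction motifs

Junction context windows are the ±w bp (default 10) of reference + strand
around each breakpoint. Direct repeats are exact longest common substrings
of the two windows with length in [4, min(18, 2w)]; ties resolve to the
smallest start-window offset, then the smallest end-window offset. The
search space is deliberately the ±10 bp windows, so the maximum detectable
repeat is min(18, 2w); set w = 18 for full-range detection. No mismatches
are allowed. Note that two random 20-mers share a ≥ 4 bp substring with
probability ≈ 0.6, so the *detected* direct-repeat fraction of a circle set
is substantially higher than any planted rate; comparisons should always be
against the same detector run on a matched null.

Palindromic units are 10-bp motifs t₁ + s + t₂ (|t₁| = |t₂| = 3, |s| = 4,
t₂ = revcomp(t₁)) required to straddle the junction coordinate
(unit start < w ≤ unit end); a non-straddling scan is available via flag.
Base-frequency matrices are per-position A/C/G/T frequencies over
non-ambiguous bases (columns sum to 1) and are directly renderable as
sequence logos; size-binned matrices split circles at the midpoints between
the configured peak sizes (282.5 / 455.5 / 642.5 bp for the defaults).

## Cohort statistics

Two-group comparisons use a two-sided rank-sum test: full enumeration over
pooled midranks when both groups have ≤ 10 samples (exact even under ties;
identical groups give p = 1), otherwise the normal approximation with tie
correction. Group means carry normal-theory 95% CIs (mean ± 1.96·SE).
Pearson correlations use the t transform with n − 2 df and refuse
zero-variance input, with one convention: in per-chromosome density tables a
constant circle density is reported as r = 0 (no association) rather than
undefined. miRNA recurrence requires full containment
(circle.start ≤ mirna.start and mirna.end ≤ circle.end) and counts each
sample once regardless of how many circles carry the miRNA; the total
circle count is reported alongside and breaks ties.

## Synthetic data: what it emulates, and what it does not

The generator emulates: i.i.d. background sequence at a configurable GC
(default 0.41) with elevated-GC CpG blocks (0.65); non-overlapping genes
(40% of the genome, mean 15 kb) with exon/intron/UTR substructure and
strand-aware 2-kb flanks; SINE/LINE/simple-repeat intervals; miRNA genes of
60–100 bp inside and outside genes; circle sizes from a truncated-normal
mixture at 207/358/553/732 bp (weights 0.06/0.82/0.06/0.06 — the
di-nucleosome peak carries roughly ten times the weight of the others — SD
20 bp, truncation [50, 2000] bp, as ~99% of observed circles are < 1 kb);
origin sampling weighted by exp(β·GC) of the 200-bp window at the start
(β = 4 by default, enough to shift mean circle GC measurably above
background); direct repeats planted at 66% of junctions with lengths
uniform on 4–18 bp; palindromic units at 33%; PE150 reads from 400 ± 60 bp
fragments with positions modulo circle length (reads on circles shorter
than a read wrap and are never dropped); junction-crossing reads emitted as
primary + supplementary alignments with SA tags; junction-straddling pairs
as outward-facing discordant pairs; linear background at 1× with a 5%
MAPQ-0 fraction; MAPQ 60 otherwise. Output is coordinate-sorted SAM,
deterministic per seed. Cohorts share one reference; per-sample circle
counts are Poisson around the configured rate, and disease samples
additionally carry planted circles fully containing a fixed set of miRNA
genes.

Planting order and conflicts: palindromes are written before the
direct-repeat copy at each junction so the repeat (written last at the end
coordinate) always survives; overlapping rewrites across circles resolve
last-wins, are logged, and a bounded repair pass re-asserts clobbered
repeats (on very dense simulations a handful may remain unresolved and are
logged).

Not emulated: sequencing errors, quality-score variation, adapter or PCR
chimeras, multi-mapping ambiguity beyond the MAPQ-0 background fraction,
GC-dependent coverage bias within a circle, structural variation, and
multi-fragment circles. Passing tests therefore demonstrate correctness of
the junction logic, filter semantics and statistics on clean alignments —
not robustness to alignment noise, which on real data is delegated to the
upstream aligner and the six filters.

## Numerical choices

- Kernel densities use a fixed absolute Gaussian bandwidth (5 bp for
  lengths, 0.01 for GC), chosen to resolve the ~151–175 bp inter-peak
  spacing and percent-scale GC contrasts; peak calling takes local maxima
  with prominence ≥ 5% of the global maximum. Both are configurable.
- Length peak calling requires ≥ 100 circles; below that only the histogram
  is returned.
- GC excludes ambiguous bases from the denominator; an all-N window is NaN
  and the circle is flagged. Circles whose equal-length flanks or ±w windows
  run off the chromosome are flagged and excluded from flank/motif analyses
  rather than silently truncated.
- Truncated-normal size draws redraw out-of-range values within their
  mixture component, preserving component weights.
- Circle origins keep a 20-bp margin from chromosome ends so junction motifs
  can always be planted and extracted.

## Test and validation design

Unit oracles are independent of the code paths they check: direct-repeat and
palindrome detection are verified against quadratic brute-force scans; the
exact rank-sum is cross-checked against an independent exact implementation
on tie-free data; enrichment and intragenic fractions are checked on uniform
nulls with analytically known expectations. Null calibration of the
enrichment ratio is measured on a deterministic tiled annotation in which
every class covers ≥ 2% of the genome with interval lengths from 80 bp to
10 kb, so the sampling error of each ratio at n = 50,000 circles is several
times smaller than the ±10% assertion band — a fixture designed for
estimator precision, since classes occupying well under 1% of a toy genome
leave the ratio dominated by binomial noise at that n. Caller recovery is
measured on 200 planted circles over a 3-Mb genome at 20× junction depth
with 1× linear background; the cohort check uses 8 + 8 samples at a 3×
disease rate on a 0.9-Mb genome. These problem sizes are the package's
validation conditions; all scale linearly if enlarged.

## Known limitations

- The circle score surrogate saturates at MAPQ 10 per read; it ranks
  candidates by unique-mapping support only.
- Overlapping circles depress each other's coverage-increase metrics, so a
  few percent of true circles fail the default filters at realistic circle
  densities (a property of the filter design, visible in the worked
  example).
- Multi-chromosome (translocation-joined) circles, copy-number inference
  and probabilistic split-read realignment are out of scope.
- The toy genome's repeat classes are placement labels, not sequence
  repeats; mappability effects of true repeats are not modelled.
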