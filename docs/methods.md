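# Methods

This note documents the models, parameter choices and numerical conventions
behind `synpaint`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversions happen only at
the I/O boundary (GFF3 and RepeatMasker `.out` are 1-based inclusive on
disk, BED is 0-based half-open, tabular `sstart` is 1-based). Soft-masked
(lowercase) FASTA is uppercased on read and is *not* treated as repeat
annotation — repeats come only from interval files. Letters outside
{A,C,G,T,N} are rejected unless a permissive flag maps IUPAC ambiguity
codes to N. Both plain and gzip-compressed text are accepted.

## Painting

* **Markers** are non-overlapping 100-bp tiles from position 0; the trailing
  partial tile is dropped. Tiles containing any N are dropped by default.
  Marker ordinals count *all* tiles, dropped ones included, so a gap tile
  breaks a chained run — blocks never bridge assembly gaps. This is the
  conservative reading of "consecutive"; runs are never allowed to skip a
  missing marker.
* **Best-hit selection** keeps at most one hit per (marker, species), broken
  deterministically by max alignment length, then max percent identity, then
  lexicographically smallest target scaffold, then smallest target start.
  Determinism makes the whole painting invariant under permutation of
  hit-table rows, which a keep-first-row rule could not guarantee for
  arbitrary table order.
* **Filtering** keeps alignments of ≥ 50 bp (default `min_aln_len`). No
  percent-identity threshold is applied; identity is carried for reporting.
* **Chaining** emits maximal runs of consecutive marker ordinals sharing a
  target scaffold with ≥ 5 members (default `min_run`). Target-side
  collinearity and strand are *not* required; an optional strict mode
  additionally demands monotone target starts, for sensitivity analysis.

## Dominance

For query chromosome *i* and species *j*, scaffold weights aggregate marker
counts of accepted blocks (base-span weighting is available and differs only
at block edges). Proportions p_ijk over the m scaffolds with any block give
D = Σ p², C = 1/D. Weights use only markers *inside* blocks: sub-threshold
scatter is exactly what the ≥ 5-consecutive rule is there to remove; a flag
exposes the all-retained-hits alternative. A (chromosome, species) pair with
no blocks is missing data — excluded from means and cumulative sums with a
logged count, never treated as C = 0 or C = m. Summaries report the sample
SD (n − 1) of C across species and per-species cumulative SR.

## Composition

Windows are 1 Mb from position 0; a trailing window is kept iff it reaches
half the window size. GC% excludes N bases from the denominator (a window
with no non-N bases has missing GC). Gene and repeat intervals are merged
before coverage is computed, so overlapping annotations never double-count.
Gene density is the *fraction* of window bases covered by merged gene spans
(0–1), not a gene count — the per-window class contrast this package
computes is unitless, and a count mode (`gene_count`) exists for
sensitivity. The macro/micro contrast is a two-sided Wilcoxon rank-sum test:
exact null distribution when both groups have ≤ 8 tie-free values, otherwise
the normal approximation with mid-ranks, tie-corrected variance and
continuity correction. Both the macro-group rank-sum W and the Mann-Whitney
U = W − n₁(n₁+1)/2 are reported, since either convention appears in the
literature.

## Karyotype curation

Scaffold→chromosome assignment is a majority vote of chromosome-linked
marker hits, with a scaffold flagged ambiguous on a tied vote or a winning
tally below `min_votes` = 2; labels are then renumbered within each size
class by descending scaffold length. A label whose strongest scaffold was
unambiguously won by a different label raises a conflict (an evenly split
scaffold is ambiguous, not a conflict). Size classes: macro ≥ 50 Mb
(inclusive — the squamate convention), micro > 8 Mb (exclusive), otherwise
unplaced.

Breakpoint detection scores each candidate junction by the signed
differences in mean GC and mean repeat fraction between up to 3 whole
windows on each side. Because candidates near scaffold ends estimate flank
means from fewer windows, each delta is first rescaled by
√((2/flank) / (1/n_left + 1/n_right)) so short-flank noise is not mistaken
for a shift. Delta magnitudes are then standardised *leave-one-out* across
the candidate set (each candidate scored against the mean and SD of the
others, as in Grubbs-style outlier statistics) and summed with 1:1 weights
into a composite shift score. A candidate passes the fusion signature when
its score reaches `shift_z_min` = 2 *and* its GC and repeat shifts point in
opposite directions — elevated GC accompanies reduced repeat density across
a real class-boundary junction, while noise shifts have independent signs.
Among passers, the junction with the lowest local gene density (mean genic
fraction of the two straddling windows) is chosen; no passer raises an
error rather than splitting silently. With fewer than 3 candidates the
leave-one-out reference is undefined and no split is supported.

## The simulator

`simulate_query` draws, per 1-Mb window, a target GC%, genic fraction and
repeat fraction, emits bases i.i.d. at the window's GC probability, and
places non-overlapping gene (1–50 kb) and repeat (0.1–5 kb) intervals whose
total coverage meets the drawn fraction to the base (interval lengths are
uniform; placement distributes the uncovered space as a random gap
partition).

Default class parameters (per-window mean ± SD): macro GC 35.9 ± 1.2%,
micro 38.5 ± 2.8%; macro genic fraction 0.19 ± 0.14, micro 0.27 ± 0.16;
macro repeat 44.6 ± 5.6%, micro 39.4 ± 10%. The default karyotype is 6
macrochromosomes × 20 Mb + 11 microchromosomes × 8 Mb (208 Mb, ≥ 200
windows, generated in seconds) — large enough for stable class means and
window statistics while keeping simulation and painting fast.

Two distributional choices matter:

* **Hierarchical GC and repeat draws.** A class-wide window SD conflates
  between-chromosome and within-chromosome variation, and curation depends
  on the distinction: chromosomes must differ from each other while being
  internally coherent. Each chromosome therefore receives a mean drawn with
  SD 0.8 × (class SD) around the class mean, and windows scatter with SD
  0.6 × (class SD) around it (0.8² + 0.6² = 1, so class-wide window moments
  are preserved). Gene density carries *no* chromosome-level component — it
  is not part of the junction signature — and is drawn flat at the full
  class SD, which also keeps simulated class means stable at small
  chromosome counts.
* **Mean calibration.** The class values being emulated are empirical window
  means, but a normal truncated to [0, 1] at location 0.19 with scale 0.14
  has mean ≈ 0.214. All truncated-normal draws therefore solve for the
  location parameter whose *truncated mean* equals the stated value
  (monotone in location, solved by bisection; a no-op when the target is
  many SDs inside the bounds).

`apply_rearrangements` operates on segment lists, so sequence content is
conserved exactly and the truth map (query interval ↔ target interval with
orientation) composes across sequential operations and tiles every query
base exactly once — asserted on every run. `emit_hits` maps each marker
through the truth map, drops it with `drop_rate`, replaces it with a
uniformly placed wrong-scaffold hit with `spurious_rate`, draws alignment
lengths uniform in 50–100 bp (so everything survives the filter; a 30–100
mode exercises sub-threshold behaviour) and shuffles the rows. All
randomness flows from one integer seed through named substreams, so
changing the noise stream never changes the genome.

**What the simulator does not model:** dinucleotide structure or isochores
within windows (bases are i.i.d.), repeat sequence motifs (repeat intervals
are compositionally neutral — only their coverage matters downstream),
alignment-level noise (the noise model is marker-level; the package tests
painting logic, not an aligner), indels/substitutions, or phylogenetically
correlated rearrangements across species. Passing tests therefore show the
*pipeline* recovers known truth under the stated noise, not that any
particular aligner's hit tables satisfy those noise assumptions.

## Scenario fixtures

The curation scenario fuses two microchromosomes whose chromosome-level
means are set apart by class-typical amounts (GC Δ 3.5 points, repeat Δ 16
points — within the between-chromosome spread implied by the class SDs)
into one 19.2-Mb scaffold among 6 macro-class (50-Mb) and 9 ordinary micro
scaffolds; micro lengths are 8.1–10 Mb so every piece, including both
fusion halves, stays strictly above the 8-Mb candidacy bound. Decoy
junctions are placed ≥ 3.5 Mb from the true junction: at 1-Mb windows with
3-window flanks, a nearer candidate shares the true junction's composition
shift and is a confounded hypothesis rather than a null decoy. Under these
conditions the true junction is chosen in ≥ 90% of seeded replicates; the
residual failures are noise tails (a spurious co-passer can win the
lowest-gene-density tie-break, and occasionally the realised shift at the
true junction is simply small).

## Numerical conventions

Proportion vectors must sum to 1 within 1e-9; D and C are exact arithmetic
on them. Marker ids are `<chrom>_<zero-padded ordinal>`; parsing takes the
final underscore-separated field as the ordinal, which is unambiguous for
any chromosome name and rejects non-numeric tails. Ties in best-hit
selection and in the minimum-gene-density breakpoint choice are broken
deterministically (position ascending), so all pipeline outputs are
byte-reproducible for a given seed. Pipeline tables are TSV with `#`
metadata headers; a JSON run summary records per-stage counts.
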