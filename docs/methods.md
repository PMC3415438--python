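# Methods

somascope re-implements, at desk scale, the analysis chain used to
characterize somatic mutation in a UV-exposed tumor sequenced together
with its matched normal: Bayesian per-site genotype scoring, somatic
SSNV/indel/CNV detection with a conservative filter cascade, purity
estimation from somatic allele fractions, mutational-spectrum and
transcribed-strand-bias summaries, resampling-based enrichment of
mutations in functional annotations, and cross-cell-type clustering of
DNase I hypersensitive sites (DHSs).  Every stage runs on output of the
built-in synthetic tumor/normal generator, so the whole chain is
verifiable against known truth without any external data.

## Genotype and variant scoring (MPG / MPV)

At each site, reads are filtered to mapping quality >= Q30 and base
quality >= Q20.  For the 10 unordered diploid genotypes {a1,a2} the
per-read likelihood is

    P(b | a1,a2) = 0.5 P(b|a1) + 0.5 P(b|a2),
    P(b | a)     = 1 - e  if b = a,  else e/3,   e = 10^(-baseQ/10)

with a flat genotype prior.  The MPG score is the posterior odds of the
best versus second-best genotype; the MPV score is the odds of any
non-reference genotype versus homozygous reference.  Scores are
expressed in **natural-log units**.  This is a deliberate calibration
choice: the standard callability rule (MPG >= 10 *and* MPG / Q20-depth
>= 0.5; MPV >= 10 with no ratio rule) is only coherent if a clean
homozygous read contributes more than 0.5 per read, which holds for
ln 2 = 0.69 but can never hold for log10 2 = 0.30 — on a decimal scale
no depth of coverage would ever make a homozygous site callable, and
callable-territory accounting would be impossible.  Scores are capped
at 255 to avoid infinities; genotype ties break lexicographically and a
tied best/second-best pair scores 0 (uncallable).  The prior is flat
rather than reference-biased; with >= 15 clean reads the likelihood
dominates either choice.

Two code paths exist — a per-site reference implementation and a
vectorized path over count tensors used genome-wide — and the test
suite holds them equal against a brute-force enumeration oracle.

## Somatic SSNV detection and validation filters

A site is a somatic candidate when the tumor's best variant genotype
(MPV >= 10) contains an allele absent from the normal's MPG-callable
genotype.  Sites whose tumor alleles are a subset of the normal's (loss
of heterozygosity) are dropped — no novel allele is acquired.  "Subset"
is the operational definition; tumor hom-to-het transitions sharing
both alleles with the normal are therefore also dropped.  Candidates at
known germline-variant positions, or within 10 bp (inclusive, measured
to the nearest indel breakpoint base) of a tumor indel call, are
subtracted.

Three filters then flag residual artifacts: a **normal lookup** (>= 1
normal read at mapQ >= 1 carrying the somatic allele), **indel
proximity** (an indel called from mapQ >= 1 reads with score >= 10
within 10 bp), and **strand bias** (all somatic-allele reads on one
strand).  The strand-bias filter requires at least two somatic-allele
reads before "exclusively one strand" can trigger; a single read is not
evidence of bias.  Flagged calls leave the pass set but are retained
with their flags, and the cascade is idempotent.

The repository's validation fixtures encode the Sanger-resequencing
outcomes this cascade was designed around: a tissue set of 73 candidate
calls (43 orthogonally concordant, 30 discordant, 29 of them carrying
filter-triggering evidence) and a cell-culture set of 78 calls (75
concordant, 3 discordant, 2 triggering).  Running the cascade on them
yields post-filter concordances of 43/44 (97.7%) and 75/76 (98.7%).

## Copy number

Mean retained depth is computed in non-overlapping 5 kb tiles; tiles
with < 80% mappable bases or zero normal depth are uncallable.  The
tumor/normal ratio is normalized by its genome-wide median (removing
library-size effects) before log2.  Tiles at log2 >= +0.25 or <= -0.25
(a single-copy change at ~60% purity; configurable — the upstream
caller's exact thresholds are not recoverable, so these are this
package's defaults) are classified and maximal runs of >= 2 adjacent
same-direction tiles become segments.  Copy number is purity-adjusted:
CN = (2·2^r − 2(1−p))/p, clipped at 0.  A segment is *sample-specific*
only if every overlapped tile of the other sample lies strictly inside
(−0.1, 0.1); the complementary strict window also defines the non-CNV
mask used by the indel and purity stages.  GC-content correction of
depth is omitted; the generator produces no GC-coupled coverage bias,
so on synthetic data the omission is exact, while on real data it would
widen ratio noise.

## Purity

At a clonal heterozygous somatic site in copy-neutral diploid
territory, the expected somatic-allele read fraction is purity/2.
Fractions are computed from mapQ >= 30 reads at filter-passing somatic
sites inside the non-CNV mask; sites with < 10 retained reads are
excluded to keep the fraction grid finer than the histogram bin.  The
histogram (bin 0.01) is smoothed with a Gaussian kernel (bandwidth
0.02) and the mode m located on (0, 0.5]; percent normal cells is
(0.5 − m)·2·100, floored at 0.  A mode of 0.29 gives 42%.  The
pure-tumor reference distribution is a Binomial(depth, 0.5) pooled over
the observed depths (per-depth fitting adds nothing at these depths).
The estimate needs >= 100 sites (configurable) and its precision is
limited by depth: at 30x the fraction grid is ~0.037 coarse, at 100x
the round-trip error is within ~3 points.

## Spectrum and strand bias

The 12 stranded substitutions collapse into 6 pyrimidine-keyed classes
(C>A, C>G, C>T, T>A, T>C, T>G), purine-reference mutations counting in
the complement slot of their class.  For transcribed-strand analysis
only intronic variants in genes of unambiguous strand are used
(overlapping genes on both strands are excluded); variants in
minus-strand genes are reverse-complemented first.  Each class's
key/complement split is tested with a two-sided exact binomial test at
p0 = 0.5; sidedness is this package's choice, as a one-sided test would
presuppose which strand repair favors.

## Enrichment statistic

Enrichment of a variant set in a feature set is log2(observed /
mean(null)) with the null SD reported alongside, over 10,000 samplings
by default; results with fewer than 10 observed overlaps are
suppressed as unreliable.  The null preserves the variant set's
clustering: positions are mapped into the compressed coordinates of the
callable territory and circularly rotated by one uniform offset per
chromosome per sampling, preserving inter-variant spacing exactly.
This replaces the segmentation-aware block bootstrap of the published
genome-structure-correction machinery — which depends on a genome
segmentation that is not reproducible here — with a seedable,
structure-preserving null.  Consequences to note: for a single large
feature block the rotation null has high variance (the whole variant
cloud swings in and out of the feature), while for fragmented feature
families such as chromatin states it is tightly calibrated; the test
suite checks calibration in the fragmented regime the pipeline actually
uses.  The common-variant control profile uses the germline
heterozygous set under identical territory and paired rotation streams.

## Genomic features

Gene-landmark partitioning assigns every base to exactly one category
by priority: coding > 5' UTR > 3' UTR > intron > TSS-proximal (within
5,000 bp of any TSS) > TSS-distal, with the two TSS categories
restricted to intergenic territory; partition conservation (disjoint
categories summing exactly to the genome) is asserted at run time.
Query intervals such as DHSs are assigned whole to the
highest-priority category they overlap by >= 1 bp.  Chromatin-state
segmentations drop states 14/15 (repeat-dominated).  Non-genic
analysis masks everything within 10 kb of any part of a gene, tiles the
remainder with 50 kb windows, scores each by constrained-base fraction,
drops zero-overlap tiles, sorts, and splits into ten equal bins with
the remainder in the last bin.  Mutation accumulation per bin is then
regressed (OLS) on constraint, GC content, and transcribed fraction,
with a Spearman correlation against transcribed fraction reported for
the transcription-coupled-repair signal.

## DHS analysis

Per-cell-type DHS peaks are single-linkage clustered: any >= 1 bp
overlap links peaks (touching intervals do not), and connected
components become clusters spanning the union interval with the
contributing cell types as members (k = 1 cell-type-specific, k = all
ubiquitous).  Each cell type's binary on/off vector over clusters is
clustered agglomeratively under Euclidean distance; the linkage is
average (the metric, not the linkage, is dictated by the method being
reproduced) with lexicographic leaf ordering for determinism, and the
tree can be re-rooted on an outgroup clade (the GM lymphoblastoid
lines, by default).  Trees serialize to Newick with branch lengths from
merge heights and round-trip structurally.  The combination analysis
scores, for every number of active cell types k, the enrichment of
somatic mutations in clusters containing versus lacking a focal cell
type, gated at >= 10 overlaps.  A cluster is *transcribed* if >= 1 RNA
read interval with mapQ >= 30 overlaps it; two cluster sets are
compared with a two-sided Fisher exact test.

## Synthetic data generator

The generator defines the study conditions: 42 somatic SSNVs per Mb,
purity 0.58 (42% normal-cell admixture, the tissue condition), ~30x
coverage, and a UV-biased spectrum.  The UV fraction of somatic events
defaults to 0.7 (the source analysis reports a strong C>T/G>A excess
without printing a fraction; 0.7 is a realistic melanoma value, chosen
once).  Germline heterozygosity is 6.7e-4/bp with one-third of variant
sites homozygous-alternate.  Base qualities follow a discrete mixture
(Q10/Q20/Q30/Q40 at 5/15/30/50%), mapping quality a two-point mixture
(5% at Q10, else Q37) — the pipeline only ever thresholds at Q30 and
Q1, so two points suffice.  Sequencing errors are uniform over the
three non-template bases at the Phred rate; no context-dependent error
model is attempted, so error-driven artifacts in real data (strand-
correlated error, systematic context effects) are outside what passing
tests demonstrate.  Tumor reads draw alleles from tumor cells with
weight purity·CN and from admixed normal cells otherwise; copy-number
segments scale both coverage and allele weights.  Somatic events sit on
one copy of an otherwise hom-ref site (a single tumor clone plus normal
admixture; no subclonal structure).  Evidence is generated as per-site
count tensors over (base, baseQ, mapQ, strand) rather than simulated
reads — alignment is out of scope and every consumer works from pileup
columns — with exact expansion to per-read tuples for the TSV dialect.
Annotation landscapes (genes with nested UTR/CDS/exon structure,
15-state chromatin tilings, per-cell-type DHS sets with configurable
ubiquitous/clade/specific sharing, constrained regions, mappability
holes, RNA read intervals) are generated with the structural invariants
the feature code assumes, not with realistic genomic sequence
composition or linkage.

Indel evidence is generated at the call level (position, allele,
score), not at the read level: the somatic-indel logic consumes scored
call tables, and read-level indel realignment is out of scope.

All randomness flows from a single integer seed through named
per-stage, per-chromosome streams, so identical configurations produce
bit-identical evidence, truth sets, and pipeline outputs.

## Problem sizes and numerical choices

The bundled demonstration genome is ten 1 Mb chromosomes — large
enough for every stage to operate in its intended regime (hundreds of
somatic events, thousands of germline controls, hundreds of DHS
clusters) while a full pipeline run stays in a few minutes on one
core.  Unit tests use 2 kb-500 kb fixtures.  Purity parameter-recovery
checks run at 100x with ~2,000 sites, where the estimator's
granularity supports a 3-point tolerance.  Enrichment defaults to
10,000 samplings (1,000 in calibration tests).  Posterior computations
are done in log space with logsumexp; degenerate inputs (no retained
reads, empty territories, empty variant sets, all-tied genotypes) are
explicit no-call or error paths rather than NaN propagation.

## Known limitations

- The genotype model ignores mapping-quality uncertainty beyond the
  hard Q30 gate and has no reference bias, indel realignment, or base
  quality recalibration.
- CNV calling has no GC correction and fixed log2 thresholds; it
  recovers integer copy states at 5 kb resolution but not breakpoints.
- The rotation null is conservative for single-block features.
- The simulator's single-clone model cannot produce multi-modal allele
  fraction distributions; the purity estimator would report only the
  dominant mode on such data.
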