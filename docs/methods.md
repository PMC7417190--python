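# Methods

This note documents the models, parameter choices and study designs behind
chromtrace, and what the synthetic benchmarks do and do not demonstrate about
real data.

## Coordinate model and formats

All intervals are 0-based half-open (BED convention); 1-based coordinates
appear only in logs. Merging treats touching intervals (end = start) as
contiguous, consistent with the broad-peak construction where ±200 bp
extensions are meant to fuse adjacent peaks. bedGraph output run-length
collapses equal values, omits zero runs, and prints 6 significant digits;
round-trip identity holds at that precision. Records on chromosomes absent
from the genome model are dropped with a warning rather than failing, so a
pipeline restricted to a chromosome subset tolerates stray contigs.
Chromosome inclusion is therefore a property of the genome model the caller
supplies, not a hard-coded list.

## Synthetic-data generator

`synthetic_data.SimConfig` defines one simulated experiment; all randomness
flows from a single seed through named integer-tagged streams
(`numpy.random.default_rng([seed, stream])`), so every sample is independently
reproducible and platform-stable.

The genome is uniform random A/C/G/T with binding sites planted on a 2 kb
pitch (1.2 kb margin from chromosome ends). Site classes: A-only, B-only,
shared (bound by both factors), and unbound motif copies planted in closed
background. The 12 bp Zic-like consensus is inserted verbatim, on the +
strand at even-indexed sites and as its reverse complement otherwise, forcing
strand-aware scanning. Each bound site sits at the center of a 600 bp open
region; accessibility weights are 1 for single-factor regions and 2 for
shared regions (so co-bound regions carry twice the accessibility signal, the
contrast the class-summary study measures). Knockdown/knockout of a factor
multiplies its dependent regions' weights by `knockdown_scale` (default 0.25,
a 4-fold drop).

Nucleosome dyads flank every planted site at ±`dyad_spacing` (150 bp) and
±(`dyad_spacing`+180); under overexpression of factor A the arrays flanking
bound A/shared sites shift outward by `displacement_delta` (default 80 bp).
Adjacent dyads are ≥ 60 bp apart by construction.

ChIP samples are uniform background fragments (150–300 bp,
`chip_depth_per_100kb` = 5000 per 100 kb) plus, per bound site, a Poisson
number of enriched fragments with centers Normal(site center, 60 bp). The
enriched mean is (enrichment − 1) × expected background coverage, so coverage
at site centers is ≈ enrichment-fold over background and enrichment = 1 is an
exact null. An `input` sample is background only.

ATAC samples contain exactly `atac_depth` fragments in three classes:

- **sub-nucleosomal** (40–99 bp), multinomially distributed over open regions
  in proportion to width × condition weight, normalized against the wild-type
  total so that accessibility lost under knockdown is reassigned to
  background — depth stays exact while planted regions drop by the stated
  fold;
- **nucleosomal**, lengths uniform in `nucleosomal_band` (120–200 bp
  inclusive), midpoints Normal(dyad, 20 bp) over the condition's dyads. The
  20 bp jitter is fixed: it makes ±20 bp dyad recovery meaningful without
  being trivial;
- **background**, placed by a log-normal per-1 kb block rate
  (`background_lognormal` gives the log2-scale mean/SD) in the genome
  complement of the open regions. Background models closed chromatin;
  keeping it out of open regions means planted fold changes are realized as
  stated and the signal/background zone dichotomy of the normalization stage
  is exact.

`simulate_track` additionally builds a per-bp RPM track directly — i.i.d.
log2-normal background plus `signal_amplitude` × weight in open regions —
giving the background-model fit an exact truth to recover. Fragment-derived
coverage is *not* log-normal per-bp (Poisson placement adds variance), which
is why parameter-recovery claims are made on constructed tracks and
self-consistency claims on anything.

Not emulated: sequencing error, PCR duplicates, mappability, Tn5 sequence
bias, single-end/paired-end mixtures, replicate structure. Benchmarks
passing here show the *estimators* are correct under their stated noise
models, not that those models capture every artifact of real libraries.

## Peak calling

One declared procedure serves ChIP and ATAC. Candidates are w-bp windows at
step w/2 (ATAC w = 150, ChIP w = 200); the statistic is the fragment-midpoint
count k per window. λ is the max of (i) the local mean over a 50 kb window
centered on the candidate, excluding the candidate itself (standard
local-lambda practice), (ii) the genome-wide rate, and (iii) the depth-scaled
control count when an input sample is given. p = Poisson upper tail;
Benjamini–Hochberg over all candidates genome-wide; survivors require
q ≤ `q_threshold` (10⁻⁵ for ChIP) and fold k/λ ≥ `min_fold`, and are accepted
greedily by ascending p (ties to the leftmost coordinate) subject to centers
≥ `min_dist` (50 bp) apart. Reported peaks have fixed width w.

The fold gate differs by use: the ATAC preset keeps `min_fold` = 4 (a
HOMER-like default), the ChIP preset uses 2 — q is the primary ChIP gate, and
in dense-site simulations the 50 kb local λ absorbs enrichment from
neighboring sites, so a 4-fold gate rejects genuinely enriched windows. When
the pipeline calls ATAC peaks merely to generate broad candidate regions for
differential analysis, it loosens the ATAC fold gate to 2 as well: candidate
generation should be sensitive, and the differential caller applies its own
gates.

Because `min_dist` (50) is smaller than the window, one strong pileup can
yield several overlapping peaks; recovery metrics therefore match peak
*centers* to site centers within w/2.

## Differential accessibility

Candidates are control-condition peaks extended ±200 bp and merged. Both
libraries are scaled to the smaller depth. For each candidate, a 200 bp
window slides at 25 bp steps; each placement gets a direction by fold
orientation (+1 pseudocount on both normalized counts) and a Poisson tail
p at λ = normalized control count (lower tail for depletion, upper for
enrichment). The placement with the smallest p represents the candidate; it
is called when fold ≥ 2 and p ≤ 10⁻⁴. The p-gate guards against 2-fold
"changes" at single-digit counts; 10⁻⁴ was chosen a priori as roughly a
per-candidate-set Bonferroni level for the study sizes used here and is
configurable.

## Background-zone normalization

Signal windows are 150 bp candidates (step 75) whose mean track value is
≥ `peak_min_fold` (4) × the genome-wide mean — a deliberately generous,
track-level detector whose job is only to exclude non-background. Each is
extended from its center to 20 000 bp *total* width ("extended from the
center to form" a zone is read as total width; the extension is
configurable). The complement is background. 100 000 random 150 bp regions
are drawn uniformly (seeded); those entirely inside background zones are
kept; μ and σ are the mean and SD (ddof = 1) of log2 of the strictly positive
per-bp values in kept regions. Fewer than 100 kept regions, fewer than 2
positive scores, or σ = 0 abort with an error — the background is
unidentifiable, not silently zero.

Normalization: z = (log2 y − μ)/σ for y > 0 (NaN at y = 0);
y_norm = max(0, 2^z − pseudocount) with pseudocount 1. z is strictly
increasing in y; the clamp affects only the browser-track companion (tracks
are conventionally non-negative), while analyses use z. Self-consistency on
generated tracks: background z has |mean| < 0.05 and |sd − 1| < 0.05, and the
constructed (μ = 3, σ = 0.5) parameters are recovered within ±0.05 (observed:
within ±0.001 at 100 000 regions on 1 Mb). Downstream differential calls use
raw counts, never z.

## Motif scanning and the mutation audit

Consensus mode reports every window at Hamming distance ≤ `max_mismatch`
(default 1) on either strand, case-insensitively; windows containing non-ACGT
symbols are skipped and tallied. A window matching on both strands collapses
to the better-scoring strand (ties to +) — the distance analysis is
strand-agnostic, so one locus is one match. PWM mode scores log2-odds against
a uniform background with +0.25 pseudo-weight per cell. The scanner is tested
for equality with a character-by-character exhaustive scan.

`site_mutation_audit` computes case-insensitive Hamming distances for the
five printed (wildtype, mutant) enhancer binding-site pairs shipped as input
data in `ENHANCER_SITE_PAIRS`; the audit asserts every distance lies in
[2, 4] (the sites were mutagenized by 2–4 bp each). Observed: [3, 2, 3, 2, 4].

## Dyad calling and distance analysis

The dyad caller is deliberately simple and fully testable: filter fragments
to the nucleosomal band ([120, 200] inclusive), histogram their midpoints at
1 bp, smooth with a Gaussian (σ = 20 bp), and take local maxima greedily
thinned to ≥ 120 bp separation (`scipy.signal.find_peaks` with `distance`).
It replaces a full signal-decomposition nucleosome model: the downstream
statistic depends only on dyad positions. Two occupancy floors apply: an
absolute `min_occupancy` (default 0 — a single 147 bp fragment yields its
midpoint as a dyad) and a region-relative floor
(`min_relative_occupancy` = 0.2 × the analysis region's maximum density).
The relative floor is the load-bearing one: background fragments of
nucleosomal length produce low-density bumps in nucleosome-free gaps, and an
absolute threshold cannot be depth-independent. Analysis regions that retain
no dyad are dropped (the "at least one nucleosome" filter).

Distances are |motif center − nearest dyad| for matches inside retained
analysis regions, summarized per category (bound/unbound) as an ECDF with
median and the fraction within 73 bp (half of the 147 bp nucleosomal
footprint; configurable). Category shifts between conditions are tested with
a two-sample KS test plus the signed median difference. Motif-center (not
edge) distances are used; for a 12 bp motif the difference is ≤ 6 bp, well
under the 20 bp dyad jitter.

In simulations, the unbound category inside accessible analysis regions is
populated by motifs of the non-perturbed factor (and any background copies
landing in analysis windows): truly closed unbound copies carry no
accessibility signal and are excluded by the region filter, exactly as in the
field's practice of restricting to accessible peaks with called nucleosomes.

## Annotation and signal summaries

Nearest-TSS distances are signed by chromosome coordinate (region center −
TSS); gene strand is recorded but not applied to the sign, so callers can
re-sign. Promoter-proximal means |distance| ≤ 3000 (inclusive). Ties break to
the lexicographically smaller gene name. Region centers use floor(start +
width/2). Signal matrices cover center ± 2000 at 10 bp bins (400 columns);
windows running off a chromosome get NaN cells excluded from row means and
column profiles (zero-filling would deflate edge regions). Rows are sorted by
the first sample's row mean, descending, and that order applies to all
samples. Class summaries average the 1 kb window centered on each region and
report n/mean/quartiles per class; empty classes report an undefined marker,
never 0.

## Pipeline and verification

`run_pipeline` executes simulate → ChIP peaks (A, B vs input) → region
classes → ATAC coverage → normalization → motif scan/partition → broad
peaks → dyads and distances (wt vs overexpression) → differential (knockdown
vs wt) → TSS annotation → matrices, writing plain BED/bedGraph/TSV/JSON and a
manifest of SHA-256 content hashes; identical configs reproduce identical
hashes. Every stochastic stage derives its stream from the single config
seed. A stage failure aborts with the stage name and partial manifest.
`verify_against_truth` scores a simulated run: peak sensitivity/precision
(center within w/2), classification accuracy against planted site classes,
background z mean/SD on freshly sampled regions, dyad recovery within
±20 bp, differential sensitivity/false-rate, and the bound-category distance
shift. The demo configuration uses a 2 × 100 kb genome, 40 000 ATAC
fragments, and a 2 kb zone extension (20 kb zones would swallow a 200 kb toy
genome); it completes in a few seconds.

## Benchmark study sizes

Chosen so each estimate is well-powered while the full suite stays fast:

| study | genome | key conditions |
|---|---|---|
| peak recovery | 10 × 100 kb | 200 bound sites, 8× enrichment, 5000 bg fragments/100 kb |
| normalization | 1 × 1 Mb | background log2-normal (3, 0.5), 10 signal regions, 100 000 random regions |
| dyad recovery | 2 × 100 kb | 248 true dyads, ~200 nucleosomal fragments each |
| displacement | 10 × 100 kb | 200 bound + 120 unbound-class sites, Δ = 80 bp vs Δ = 0, ~100 fragments/dyad |
| differential | 4 × 100 kb | 60 regions at 4× drop vs 60 unchanged, 100 000 fragments/sample |
| signal ratio | 2 × 100 kb | co-bound weight 2 vs single-factor weight 1 |

The 200-site peak study spreads sites over ten 100 kb chromosomes because
sites are planted on a 2 kb pitch; depth is specified per 100 kb.

## Known limitations

- The peak caller is a single declared procedure, not a reimplementation of
  any external tool; absolute peak counts are not comparable to other
  callers' output, only the recovery properties are claimed.
- The dyad caller has no notion of nucleosome occupancy vs fuzziness and will
  merge nucleosomes closer than `min_separation`.
- The generator's open regions are disjoint by construction; overlapping
  regulatory elements, which complicate real differential calls, are not
  modeled.
- The KS shift test treats motifs as independent observations; in real data
  nearby motifs share nucleosomes and the effective n is smaller.
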