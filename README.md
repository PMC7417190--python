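# chromtrace

Integrative analysis of transcription-factor ChIP-seq and ATAC-seq data at the
interval level: enrichment peak calling, two-factor peak-overlap
classification, background-zone log-normal signal normalization, consensus
motif scanning with bound/unbound partitioning, nucleosome-dyad calling and
motif-to-dyad distance analysis, two-condition differential accessibility, and
TSS-centric annotation.

The package is written for regulatory genomicists studying how a
sequence-specific factor reshapes chromatin — the motivating setting is a
zinc-finger factor that binds a 12 bp Zic-like consensus in early embryos,
opens factor-dependent regions, and displaces the nucleosomes flanking its
bound motifs. Because the interesting claims are about *recovering* planted
structure, every stage ships with a synthetic-data generator that emits
genomes, fragment sets and ground truth, so the whole pipeline is testable
end-to-end with no external downloads.

## The methods at its core

**Peak calling.** Candidate windows of width *w* (step *w*/2) are scored by
their fragment-midpoint count *k* against a Poisson background
λ = max(λ_local, λ_genome, λ_control), where λ_local is the mean over a
50 kb window excluding the candidate, and λ_control is the depth-scaled count
in a matched input sample. p = P(Pois(λ) ≥ k); q-values are Benjamini–Hochberg
over all candidates; survivors (q ≤ 10⁻⁵ for ChIP) are selected greedily by
significance subject to a minimum center distance.

**Background-zone normalization.** 150 bp signal windows are extended from
their centers to 20 kb "signal zones"; the complement forms "background
zones". 100 000 random 150 bp regions falling entirely in background zones
sample the noise; the positive per-bp RPM scores y_bkg are modeled
log-normally, and the whole track is centered and scaled with pseudocount 1:

    z = (log2 y − mean(log2 y_bkg)) / sd(log2 y_bkg),    y_norm = max(0, 2^z − 1)

**Nucleosome displacement.** Fragments of nucleosomal length (120–200 bp)
report protection; their midpoints, Gaussian-smoothed (20 bp), give a dyad
density whose thinned local maxima are the called dyads. For each motif match
(bound = overlapping a ChIP peak; unbound otherwise) the distance to the
nearest dyad is recorded; condition-wise ECDFs of those distances, compared by
a two-sample KS test, detect outward nucleosome displacement at bound motifs.

**Differential accessibility.** Peaks from the control condition are broadened
±200 bp and merged into candidates; each candidate's best 200 bp window is
tested for a ≥2-fold, Poisson-significant depth-normalized drop
(`closed_in_target`) or gain (`opened_in_target`).

## Worked example

The numbered drivers under `analysis/` run the study end to end on simulated
data; each prints what it found and writes tables under `results/`. The
displacement analysis, for example:

```
$ python analysis/05_nucleosome_displacement.py
bound motifs (n=202): median distance shift +80 bp (KS=0.995, p=4.93e-118)
unbound motifs (n=161): median shift +1 bp — unchanged, as planted
zero-displacement control: bound median shift +0 bp, p=0.988 (no significant shift)
conclusion: the ECDF comparison detects the planted outward displacement at bound motifs only
```

The generator planted an 80 bp outward shift of the dyads flanking bound
motifs in the overexpression condition; the pipeline recovers exactly that
shift at bound motifs, no shift at unbound motifs, and no shift in the
zero-displacement control. Similarly, `analysis/02_call_peaks_and_classify.py`
recovers 200 planted binding sites with sensitivity/precision 1.000 at 8-fold
enrichment, and `analysis/03_normalize_background.py` recovers the background
log-normal parameters (μ = 3, σ = 0.5) to four decimals and leaves background
z-scores at mean −0.0006, sd 1.0000.

A single command runs every stage with one seed and a manifest of content
hashes (`run-all`), or verifies the run against ground truth (`verify`):

```
chromtrace run-all --seed 1 --outdir results/pipeline
chromtrace verify --seed 1 --out verification.json
```

The `chromtrace` CLI also exposes each stage on files
(`call-peaks`, `classify`, `atac-normalize`, `scan-motif`, `call-dyads`,
`distances`, `diff-peaks`, `annotate`, `matrix`, `simulate`).

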