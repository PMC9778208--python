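# Methods

## Signal processing chain

QBU/ChIP coverage enters as bedGraph and is resampled onto fixed 50 bp bins
(`bin_width`, configurable). Each bin's value is the per-bp mean of record
values over the bin, with uncovered base pairs counting as zero; partial
overlaps are bp-weighted, and the final (truncated) bin of a chromosome is
normalized by its true width. This makes binning conserve mass
(Σ value·bin-bp = Σ value·record-bp) and makes `write_bedgraph` /
`read_bedgraph` a bit-exact round trip at bin resolution. All coordinates
are 0-based half-open (BED convention) throughout.

Smoothing is a per-chromosome running median. A nominal 1 kb window at 50 bp
bins is 20 bins; a centered filter needs an odd count, so 21 bins (1050 bp
effective) are used and recorded in provenance. Windows shrink at chromosome
ends rather than padding — no data are invented, and the order-statistic
bound (output within input min/max) is preserved exactly.

Replicates are smoothed first, then averaged element-wise; pairwise Pearson
correlations (computed genome-wide on the smoothed tracks, zero bins
included, no log transform) are recorded in provenance and reported in
`correlations.tsv`, but no correlation threshold gates the analysis.

Cross-strain comparability uses total-signal scale normalization: each
strain's track is multiplied by one scalar so genome-wide totals agree
(default target: mean of input totals). A single scalar preserves every
within-strain value ratio, i.e. profile shape. Quantile normalization was
rejected because it distorts peak shape, which the peak-width analysis
depends on. The Dbf4 ChIP comparison is deliberately *not* scale-normalized
across strains: the lost centromeric enrichment in the Zn-finger mutant is
itself the signal of interest, and rescaling would push the difference into
the genome-wide background.

## Origin groups

Origins carry flags: `confirmed` (the OriDB-style confirmed set),
`fkh_activated`, `fkh1_sensitive` (the subset responsive to loss of FKH1
alone; always a subset of Fkh-activated), and `rdna` (origins in the rDNA
locus, removed from genome-wide statistics because of the locus's copy
number). The Fkh lists are treated as input annotations, not recomputed.

CEN-proximal origins are defined operationally as the closest confirmed,
non-rDNA origin on each side of each centromere, using origin midpoint to
centromere point distance. Choices where the definition is underdetermined:
midpoint (not edge) anchors for symmetry; an origin exactly at the
centromere counts as left-flanking; equidistant candidates tie-break to the
lexicographically smaller name (deterministic); classification runs on the
rDNA-excluded confirmed set, whose size (408 on the reference-sized fixture)
is the base population for heatmaps and group tests. Distance stratification
(e.g. origins > 25 kb from a CEN) is exposed separately via
`distance_to_nearest_cen` rather than by redefining the group.

## Window statistics and tests

Per-origin activity is the bp-weighted mean of bin values in a 500 bp window
centered on the origin midpoint, clipped at chromosome ends (clipped windows
are kept, averaged over their actual extent). The mean (not sum) makes the
statistic invariant to window clipping and proportional under scale
normalization. ΔQBU is reference − test per origin; positive values mean
activity lost in the test strain, and the table is exactly antisymmetric
under swapping roles.

Group summaries are five-number boxplot statistics with linear-interpolation
quartiles (deterministic across group sizes; Tukey hinges rejected). Group
contrasts use Welch's unequal-variance two-sided t-test with
Welch–Satterthwaite degrees of freedom; a permutation oracle in the test
suite confirms the p-values at small n. Degenerate zero-variance inputs
follow the convention t = 0, p = 1 for equal means. Benjamini–Hochberg
q-values are appended to `ttests.tsv` as an extra labelled column; the
primary results are the raw tests.

Peak width is FWHM with a local baseline: within ±`search_bp`/2 of the
origin midpoint, baseline = span minimum, half-height = baseline + (peak −
baseline)/2, crossings located by linear interpolation between bin centers.
A flat span is an error; a crossing not reached inside the span marks the
result censored rather than silently truncating. Two geometric identities
pin the definition in tests: a triangle of base W has FWHM W/2, and a
Gaussian of width σ has FWHM 2√(2 ln 2)·σ.

Heatmaps are feature × offset matrices (default 10 kb span → 200 columns at
50 bp), with NaN outside the genome; rows follow input order unless
mean-sorting is requested (flagged). Scatter fits are ordinary least squares
with Pearson r, per origin group.

## The simulator

The generator embodies the limiting-initiator competition model:

* **Weights.** w = ε · F · C · g as in the README. Fkh1-sensitive origins
  require Fkh1 specifically; other Fkh-activated origins accept Fkh1 or
  Fkh2 (so `fkh2-dsm` alone leaves them active). The CEN boost decays
  linearly from `cen_boost` at d = 0 to 1 at `cen_range` = 25 kb and is
  active only with Ctf19 present and wild-type Dbf4. The Zn-finger alleles
  lose the CEN pathway but keep Fkh targeting (g = 0.8); the C-terminal
  truncation loses the CEN pathway, retains only `dc_fkh_retention` = 0.3 of
  the Fkh boost above baseline, and is a general hypomorph (g = 0.4).
* **Firing.** Each cell fires `pool_size` = 10 origins, drawn without
  replacement with probability proportional to weight, implemented by
  exponential race keys (Exp(1)/w, smallest K win) — distributionally
  identical to successive weighted draws and validated against exhaustive
  enumeration for small origin sets. Firing times collapse to t = 0 (the HU
  arrest snapshot); an exponential-waiting-time mode exists behind
  `exponential_firing_times` and is off by default.
* **Forks.** Fired origins replicate [m − e, m + e) clipped to the
  chromosome, with per-side extent e = min(vT, B/2K′) where v = 100 bp/min
  (HU-slowed), T = 60 min (90 min for `dbf4∆C`, which is held in HU longer),
  B = 120 kb the per-cell synthesis budget and K′ the number of forks' pairs
  actually firing. The budget models the shared dNTP limitation in HU and is
  what couples peak width to firing number: with more origins active each
  fork travels less, so mean fired-origin FWHM falls as the pool grows. At
  the defaults the vT limit binds for K ≤ 10 and the budget binds above.
* **Readout.** QBU tracks are Poisson(read_depth × per-bin replicated-cell
  fraction), read_depth = 100 per bin; a gamma-mixing `overdispersion` knob
  exists and defaults to 0. Dbf4 ChIP tracks are Poisson(chip_depth ×
  intensity) with flat background 1.0, Gaussian peaks (σ = 400 bp) of
  amplitude 4 at centromeres and 1 at CEN-proximal origins, both scaled by
  0.3 in the Zn* mutant; other origins carry no strain-dependent enrichment.
* **Layout.** The default toy genome is 16 chromosomes × 300 kb with origins
  every 30 kb (160 total), a mid-chromosome centromere each (flanking
  origins therefore sit 15 kb from the CEN, inside the 25 kb boost range),
  basal efficiencies drawn once per config seed from U(0.1, 0.4), and three
  Fkh-activated origins per chromosome (one Fkh1-sensitive) — proportions
  close to the 95/410 and 35/95 ratios of the reference annotation sets.

A separate deterministic annotation fixture (`oriquant.fixtures`) mirrors
the reference set *counts* — 410 confirmed origins over the real sacCer3
chromosome lengths, 95 Fkh-activated, 35 Fkh1-sensitive, 2 rDNA origins on
chrXII, 16 centromeres, 32 CEN-proximal after classification — with fully
synthetic positions (evenly spaced origins, centromeres at 45% of each
chromosome). It exercises set construction, not real coordinates.

## What the generator does and does not emulate

Emulated: per-origin peaks of genotype-dependent height, the competition
coupling between origin classes (suppressing one class elevates the others),
replicate-level counting noise, fork-extent-limited peak widths, and
CEN-enriched Dbf4 occupancy with allele-dependent loss. Not emulated:
late/dormant origin activation kinetics through S phase, checkpoint
signalling, fork stalling/restart, GC/mappability bias, fragment-size
effects, copy-number artifacts (the rDNA flag stands in for the locus's
pathology), or realistic inter-origin spacing heterogeneity. Passing tests
therefore demonstrate that the pipeline recovers the model's structure from
noisy track data, not that the model quantitatively matches any real
dataset; absolute fork speed, pool size and boost magnitudes are free
parameters, never estimates of the biology.

## Problem sizes and determinism

Simulation-based checks run the default conditions: 2000 cells per strain,
two replicates, 20 seeds per claim (the toy genome keeps a five-genotype
panel near three seconds per seed). Fired-origin peak widths are measured at
origins with empirical firing frequency ≥ 0.05, where the peak stands clear
of Poisson noise. Every stochastic component takes a `numpy` Generator
seeded from a single master seed; fixed seed implies byte-identical output
files, which the CLI tests assert.

## Known limitations

* The 21-bin median window differs from a hypothetical 20-bin
  implementation; results are insensitive at 50 bp resolution but widths are
  recorded in provenance for exactness.
* `scale_normalize` preserves value ratios up to one floating multiply
  (~1 ulp), not bit-exactly.
* The FWHM estimator assumes a unimodal peak in the search span; closely
  spaced origins need a narrower `search_bp`.
* Weighted without-replacement inclusion probabilities are only
  enumeration-validated for small origin sets; for large sets the χ² check
  covers the K = 1 law.
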