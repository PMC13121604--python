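# Methods

This note records the statistical model, the simulation design, the numerical
conventions, and the genuinely open design choices made in `rtswitch`, in
enough detail to reimplement each step.

## RT profiles

Per window, RT = log2((E_rpm + ε)/(L_rpm + ε)) with each fraction scaled to
reads per million of its own library. ε defaults to 0.5 RPM applied
symmetrically, which keeps the antisymmetry RT(E,L) = −RT(L,E) exact and
avoids ±∞ at empty fractions. Windows with raw E + L below a coverage floor
(default 20 reads per 50 kb window) are masked; the floor is a package
choice — deep datasets can raise it — and every masked count is logged.

Two grids are used: 50 kb windows for all statistics, 5 kb for display
tracks. Display tracks may additionally be affine-scaled (the 0.5 % and
99.5 % genome-wide quantiles mapped to ∓3, values outside mapped linearly
unless clipping is requested — this reproduces the conventional compression
of a raw ~−7…7 log2 dynamic range into ~−3…3) and smoothed with a centered
moving average (default 300 kb window). The smoothing window holds
`window/bin` bins at offsets −w//2 … w−w//2−1 around the center; it shrinks
at chromosome ends, so the average is mean-preserving only over windows that
lie fully inside a chromosome — exact linearity and the interior
moving-average identity are what the tests assert. Masked bins enter neither
numerator nor denominator. A loess smoother was considered and rejected: the
moving average is deterministic, linear, and its boundary behavior is
exactly testable. **Scaled or smoothed values are never used in statistics**;
profile provenance flags are checked by the pipeline before testing.

Quantile normalization maps unmasked target values onto the reference
distribution by average rank (ties receive the mean of the tied reference
quantiles; unequal counts interpolate reference quantiles linearly). It is
intended for harmonizing real samples from different library preparations
and is off by default for synthetic runs, whose samples are calibrated by
construction. Normalization is genome-wide; a per-chromosome variant is a
config flag.

### Compositional offset

When part of the genome genuinely advances in one condition, that
condition's early library grows and its late library shrinks, so RPM scaling
shifts log2(E/L) at **every unchanged window** (about −0.09 log2 for the
default synthetic study). The pipeline therefore median-centers the
per-window delta distribution before testing (`center` flag on both window
tests, on by default in the pipeline). The median over windows is the right
location estimate here because the delta distribution is null-dominated and
unimodal; centering each profile by its own genome-wide median was tried and
rejected — the RT value distribution is bimodal and its median sits in a
low-density gap that moves erratically when planted mass shifts.

## Window tests

Observed statistic per window: Δ = mean(RT₂) − mean(RT₁) over unmasked
replicates.

**Monte-Carlo empirical null** (pipeline default). The null pool is every
within-condition replicate-pair difference at every genome window. A pooled
draw d has variance 2σ² when a single replicate has variance σ²; the
statistic Δ has variance σ²(1/n₁ + 1/n₂); each draw is therefore rescaled by
√((1/n₁ + 1/n₂)/2) so the null matches the statistic's sampling
distribution. This assumes window-level noise is roughly homoscedastic
across the genome — true under the Poisson count model away from extreme
RT, and approximately true in real data of uniform coverage. p-values use
the add-one estimator and are never 0; n_mc defaults to 50,000 in the
pipeline so the p floor (1/(n_mc+1) = 2×10⁻⁵) clears the BH-adjusted
per-window α at q ≤ 0.001.

The empirical null is preferred over per-window t-tests for small replicate
counts for a concrete reason: with 4 vs 4 replicates a paired t has df = 3
and Welch's df collapses toward 3 whenever one side's sample variance is
small, so even t ≈ 25 yields p ≈ 10⁻⁴ — above the BH-adjusted α needed at
q ≤ 0.001 — and region boundaries are missed stochastically. The pooled
null has effective degrees of freedom in the tens of thousands. Both t-test
modes remain available (`test_mode: ttest`, `paired` flag) and are verified
against closed-form oracles; the paired t is used at region/domain level for
transcription and RT change, where the p < 0.01 threshold is reachable at
df = 3.

BH q-values follow the step-up definition q_i = min over p_j ≥ p_i of
(m·p_j/rank_j), capped at 1; NaN p-values (zero-variance sentinel windows)
are excluded from m and propagate as NaN.

**Stitching.** Windows with q ≤ 0.001 are partitioned by sign of Δ and each
direction merged with a 300 kb gap tolerance under `bedtools merge -d`
semantics (separation ≤ gap merges; book-ended intervals merge at gap 0).
Regions are direction-pure by construction — a region-level ΔRT needs a
sign. Region statistics (mean ΔRT, min q, window count) aggregate over the
constituent significant windows only.

## Transcription

Region RPKM = reads in region / (region kb × library millions), strand-
agnostic (nascent RNA), per replicate and condition, with edge windows
apportioned by overlap length. The library size is the total sequenced
reads declared in the dataset manifest, not the sum of the loaded track —
on synthetic data with sparse gene models the track total would be a
condition-dependent underestimate and bias fold changes.

The noise threshold is the 0.99 quantile of the pooled RPKMs of the
RT-advancing regions shuffled into intergenic space (complement of merged
gene spans) 100 times, placements uniform over eligible integer start
positions, lengths preserved, independent per region (a no-self-overlap
flag exists). The quantile is a declared package choice: it fixes the
false-positive rate for "transcribed" calls at 1 % under the background
distribution, and the shuffled sample is written out so the distribution
can be plotted and the threshold re-derived at any quantile.

Region transcription change: paired t on per-replicate RPKM; log2 fold
change uses a pseudocount c = 0.01 RPKM so silent→induced regions get a
finite FC. Classification: significant (p < 0.01) regions split by FC sign;
non-significant regions split by condition-2 RPKM above/below the noise
threshold; cross-tabulated against RT class (advance/delay from overlapping
switching regions, otherwise no-change). The partition is exhaustive and
exclusive by construction. No FDR correction at region level (a BH option
exists); domain-level integration runs the same paired tests per
replication domain.

Barcode counting is an exact substring match of the 16-nt barcode against
each read (reverse-complement matching behind a flag, off by default); a
read containing the barcode twice counts once; RPM = count/total × 10⁶.

## Synthetic data

The generator emulates the data layout of an allele-resolved differentiation
Repli-seq study: two conditions, configurable replicates, one or two labeled
alleles (allelic structure is modeled as two labeled coverage tracks — the
pipeline consumes post-SNP-parsing coverage, so simulating reads would add
no test power).

*RT field*: per chromosome, equal-width replication domains with levels
cycling through a configurable list, joined by linear timing-transition
ramps of slope `ttr_slope` (log2/Mb), so a −3→+3 boundary at slope 4 spans
1.5 Mb. Planted switches add a signed ΔRT to condition 2 over bin-aligned
intervals (bin alignment makes boundary-recovery metrics unambiguous);
allele-specific offsets add to one allele in condition 2 (or both
conditions, for baseline asynchrony).

*Counts*: for true RT s, the early-fraction probability is the base-2
logistic pE = 2ˢ/(1+2ˢ), and E ~ Poisson(2λ·pE), L ~ Poisson(2λ·(1−pE))
independently per replicate/allele, so E[E]/E[L] = 2ˢ and the measured
log2 ratio is calibrated to s (empirically to <0.001 at λ=100). Poisson is
the deliberate simplest null; an overdispersion knob (gamma-multiplied
rates, i.e. negative-binomial counts) exists to stress type-I behavior but
is off by default because no published estimate of real E/L overdispersion
was available to anchor it.

*Transcription*: reads are placed by Poisson sampling at rates matching
each gene's condition-specific target RPKM given the declared library size
(RPKM × lib_millions / 1000 reads per bp over the gene body, at 5 kb track
resolution), over a uniform intergenic background (default 0.01 RPKM).

*The standard study* (`demo_config`): five 20 Mb chromosomes (100 Mb), 50 kb
bins, 4 replicates per condition, λ = 100 reads/window/fraction, baseline
domains of 2 Mb alternating between −1 and +1 log2 with slope-4 ramps.
Thirty planted evaluation regions: 8 advance+up, 6 advance+silent, 6
delay+up, 5 no-change+up, 5 no-change+silent; switches are ±2 log2 over
200–600 kb. Advances are planted in late (−1) domains and delays in early
(+1) domains — the biologically typical late↔early switch — which also
keeps both endpoints at |s| ≤ 1 where the log-ratio noise is smallest;
planting an advance on an already-early domain drives late-fraction counts
toward ~10 reads and the per-replicate noise above 0.5 log2, a property of
the measurement, not the caller. Silent evaluation regions are gene-free
and fixed at 600 kb (the top of the span range) so their RPKM sampling
spread is tighter than that of the pooled shuffled regions they are
compared against. "Up" genes go from 0 to 10 RPKM; 15 constitutive genes
(2–4 RPKM in both conditions) populate the distal 4 Mb of each chromosome
so intergenic space is realistic for the shuffle. Bru-seq libraries are
declared at 20 M reads/replicate.

Problem sizes throughout (100 Mb demo genome, 20,000-window null, 10,000–
50,000 MC draws, 100 shuffles) are the package's standard configuration;
the full demo simulates and analyzes in a few seconds on one CPU.

**What the generator does not model** — and hence what passing tests do not
establish about real data: mappability and GC bias, fragment-level effects,
SNP density variation between alleles, overdispersed counts (unless
enabled), partial-S-phase RT changes that E/L ratios cannot see,
autocorrelated biological noise along the chromosome, and any form of
read-level alignment artifact. The type-I calibration result in particular
holds under the Poisson null; on real data the empirical-null construction
absorbs extra replicate-level variance but not spatially structured
artifacts.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based half-open everywhere, including bedGraph.
- Determinism: every stochastic path (count sampling, MC draws, shuffles)
  takes an explicit seed; rerunning the pipeline with the same seed produces
  byte-identical statistical outputs.
- Zero-variance test windows: identical data → t = 0, p = 1; nonzero
  difference with zero variance → NaN sentinel, excluded from BH, logged.
- Empty null pool (single replicates both sides) is an error instructing
  the user that neither MC nor t-test mode is possible.
- Degenerate scaling spread (equal quantiles) is an error rather than a
  divide-by-zero.
- Region shuffling errors out identifying any region longer than every
  allowed interval.
- A chromosome-exclusion config filters one or more chromosomes (e.g. a
  homozygous chromosome in a hybrid clone) from coverage, genes and truth
  tables before any statistic.

## Known limitations

- The MC null assumes genome-wide homoscedasticity of window noise; at
  extreme RT (|s| ≳ 3 at λ = 100) late/early counts get small and windows
  there are noisier than the pooled null, inflating tail risk locally.
- Delta centering assumes changed windows are a minority; a genome where
  most windows change direction-asymmetrically would bias the center.
- Welch/paired window tests are underpowered at BH-adjusted thresholds for
  ≤4 replicates (see above); they are provided for larger designs.
- The quantile-normalization identity "sorted output equals sorted
  reference" holds exactly only when unmasked counts match.
- `domain_integration` excludes (and flags) domains whose RT is entirely
  masked in any replicate rather than imputing.
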