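# Methods

## Scan statistics

### Pairwise F_ST

For each (dairy, non-dairy) breed pair the per-SNP statistic is the
unbiased two-population Weir–Cockerham estimator computed from the diploid
variance components. With per-SNP usable sample sizes n₁, n₂ (missing
calls removed), allele frequencies p₁, p₂ and observed heterozygote
proportions h₁, h₂, let n̄ = (n₁+n₂)/2, n_c the sample-size correction,
p̄ and h̄ the weighted means and s² the weighted between-population
frequency variance. Then

    a = (n̄/n_c)·[ s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1) ]
    b = (n̄/(n̄−1))·[ p̄(1−p̄) − s²/2 − ((2n̄−1)/(4n̄))·h̄ ]
    c = h̄/2
    θ̂ = a/(a+b+c)

A SNP is flagged invalid — never silently zeroed — when either population
has fewer than two usable individuals or the denominator is exactly zero
(both samples fixed for the same allele with no heterozygotes). Negative
estimates are **retained** by default so that window means stay unbiased;
`truncate_negative` zeroes them for replication of conventions that do.
Invalid SNPs are excluded from windows rather than imputed: a window is a
run of exactly nine consecutive *valid* SNPs, and an invalid SNP breaks
the run instead of widening the window, keeping every window at nine
informative markers.

Under equal per-breed Balding–Nichols drift F the estimator centres near F
itself (E[a] ≈ F·pq while E[a+b+c] ≈ F·pq/2 + pq(1−F/2)); the test suite
checks this against a large-sample frequency-level oracle.

### Observed and normalized heterozygosity

ObsHtz at a SNP is the heterozygote fraction among non-missing
individuals. Window means (9 SNPs, step 1, labeled by the center SNP) are
standardized per breed as Z_w = (H_w − mean H)/sd H with the sample SD,
computed genome-wide; the Z track is reported alongside the raw windows
but outlier calling uses the raw ObsHtz windows.

### Asymptotic regression

At each test position (every 50 kb from the first to the last SNP of a
chromosome; a chromosome shorter than one step gets a single position at
its first SNP) the per-SNP heterozygosity of all valid SNPs within the
bracket (±5, 10 or 20 Mb; 10 Mb feeds the CCR stage) is regressed on
distance in Mb:

    y = A + B·R^x,  0 < R < 1.

Per-SNP (not window-averaged) heterozygosity feeds the fit, since the
model describes marker-level variation. Fitting uses variable projection:
at fixed R the model is linear in (A, B), which are solved exactly, so the
residual sum of squares is a smooth 1-D function of R. A 25-point grid
over R ∈ [0.02, 0.98] locates the global basin and bounded Brent
refinement polishes it (default tolerance 1e-12 on R; the genome scan
uses 1e-8). This profiles out the linear parameters rather than running a
3-parameter descent from a few starts — the same objective and optimum
with far fewer local-minimum failures, and fast enough for ~10⁴ fits per
scan. Parameter standard errors come from the Jacobian at the optimum.

Significance is the F statistic comparing the 3-parameter model to the
intercept-only model, F = ((SS0 − SS1)/2)/(SS1/(n−3)), p = Pr[F₂,ₙ₋₃ ≥ F],
charging two degrees of freedom for B and the estimated R; variance
explained is 1 − SS1/SS0. Although R is not identified under the null
(B = 0), the 2-df charge absorbs its estimation in practice: over 1,000
null fits the fraction with p < 0.05 measures ≈ 0.045. Fits need ≥ 8
points; exactly constant y returns an unconverged fit with zero variance
explained instead of raising. Only converged fits in the predicted
direction (B < 0, diversity recovering with distance) receive a −log10 p
score; unscored positions are excluded from the percentile distribution,
which makes this route more stringent than the window statistics (fewer
eligible positions). −log p is base 10. Distances enter in Mb; results
are reparameterization-equivalent (scaling x by c maps R to R^(1/c)).

## Thresholds and region calling

Outlier cutoffs are genome-wide empirical order statistics (type-1, no
interpolation) per breed (heterozygosity) or breed pair (F_ST): the k-th
most extreme window with k = floor(0.005·N); ties at the cutoff are all
flagged, so at least k windows flag. Fewer than 200 windows (empty 0.5%
tail) and all-identical distributions are errors, not silent passes.

Flags within 2 Mb of each other (center-to-center for windows,
position-to-position for grid points; **inclusive** at exactly 2 Mb — the
rule is "within 2 Mb") chain by single linkage into candidate regions
spanning the first to the last member window. Consensus groups candidate
regions of different breeds/pairs whose intervals are within 2 Mb
(overlap = gap 0), again single-linkage; chains are allowed (A near B and
B near C groups all three even if A is far from C). A group survives with
≥ 2 distinct dairy breeds (heterozygosity methods) or ≥ 2 breed pairs with
disjoint breed sets (F_ST) — two pairs sharing a breed are a single line
of evidence and do not qualify. Non-dairy breeds never count toward
heterozygosity support; they are excluded from the grouping itself (so a
non-dairy region cannot bridge two otherwise-distant dairy regions) and
re-attached to surviving groups as annotations. Consensus spans are the
envelope (min start, max end) of qualifying members.

A convergence candidate region (CCR) requires an F_ST consensus region to
**strictly overlap** (≥ 1 bp) at least one heterozygosity-based consensus
region — the 2-Mb proximity rule deliberately does not apply at this
stage, so near-misses are excluded. Heterozygosity regions join the same
CCR only through a shared overlapping F_ST region. The CCR span is the
envelope of the contributing intervals. On the published worked example
(six differentiation intervals, six reduced-heterozygosity intervals, one
regression interval) this yields exactly six CCRs, one of which carries
all three methods.

## Enrichment test

Regions of the same lengths as the called CCRs are placed independently
and uniformly over all feasible positions: a chromosome is chosen with
probability proportional to its count of valid starts (length − region
length + 1) and the start is uniform among them, so placements always fit.
Placed regions may collide with each other — CCRs occupy well under 1% of
a genome, so conditioning on non-collision would change nothing measurable
and would complicate the null. Overlaps are counted as (region, gene)
pairs sharing ≥ 1 bp by default; counting distinct genes hit is an option.
The empirical p-value is the fraction of replicates reaching the observed
count (optional (k+1)/(n+1) smoothing, off by default). The default
1,000,000 replicates match the protocol scale; the test suite validates
the machinery against exhaustive enumeration on a 100-bp toy genome
(91 possible placements) rather than against any external gene database.

## Synthetic-data generator

The generator emulates a medium-density ovine SNP-array dataset: 26
autosomes of 100 Mb (real sheep chromosomes vary around this mean), SNP
spacing jittered uniformly on [0.5, 1.5]× a 55-kb nominal spacing (about
47k autosomal SNPs genome-wide), ancestral allele frequencies uniform on
[0.05, 0.95] to mimic array ascertainment, and per-breed allele
frequencies drawn from the Balding–Nichols Beta distribution with mean p
and variance F·p(1−p). The ten-breed default panel uses the study's
sample sizes (22–103 individuals) with drift coefficients of 0.04–0.15
chosen once so that pairwise genome-wide differentiation falls in the
0.05–0.3 background range observed between related sheep breeds.
Genotypes are Binomial(2, p) under Hardy–Weinberg within breed; missing
calls are uniform at a configurable rate (default 0).

A sweep is implanted on the frequency vector of its carrier breeds: at
distance d from the locus each frequency moves toward the nearer of
{0, 1} (ties at 0.5 toward 1) by the fraction intensity·exp(−d/decay).
This collapses expected heterozygosity at the locus (to exactly 0 at
intensity 1) with asymptotic recovery over the decay scale — precisely
the signal class the three statistics target — and simultaneously creates
local differentiation against non-carrier partners. The implanted sweeps
are emitted as a truth table for power evaluation.

What the generator does **not** reproduce: linkage disequilibrium and
haplotype structure (sweeps act on marginal frequencies, sufficient
because all three statistics are frequency/heterozygosity functionals; no
haplotype statistic is in scope), recombination-rate variation,
chromosome-length variation, ascertainment against particular breeds, and
realistic demography beyond single-parameter drift. Passing power tests
therefore demonstrate that the pipeline localizes frequency-level sweep
signatures under known background differentiation, not that real-data
power equals the measured rates.

## Problem sizes and defaults

Power and specificity studies run at a reduced genome of 2 chromosomes ×
50 Mb with 4 breeds × 60 individuals — large enough for ~4,000 windows
(so the 0.5% tail holds ~20 windows per track) while keeping a 50-
replicate study comfortably inside a single-CPU session; the scan
protocol parameters themselves (9-SNP windows, 0.5% tails, 50-kb grid,
10-Mb CCR bracket, 2-Mb gap, min support 2) are never scaled. Measured at
these conditions: top-F_ST-window and regression-argmax localization
within 1 Mb of the true locus in ≳ 90% of replicates, a CCR covering the
locus in ≳ 90%, and no CCR on ≳ 90% of neutral datasets (occasional
chance convergences are expected: two pairs and two dairy breeds can
align by accident on a small genome).

## Numerical and edge-case policy

* Coordinates are 1-based inclusive everywhere inside the package; BED
  conversion ([s−1, e) half-open) happens only at the write boundary.
* Missing genotypes are a distinct code (−1), never conflated with 0
  copies; every statistic recomputes its denominator after removing them.
* All TSV output uses a fixed float format, making reruns byte-identical;
  the run manifest records the configuration and stage counts.
* Chromosome labels are opaque strings; numeric-aware ordering is applied
  only when reports are written.
* Random draws flow from explicit integer seeds through
  `numpy.random.default_rng`; independent generator stages derive
  separate child streams so adding a stage does not shift another's draws.

## Known limitations

* Two-population F_ST only; no multi-population estimator, no haplotype
  statistics (iHS/EHH), no expected heterozygosity.
* Regression standard errors are Jacobian-based point estimates; no
  profile-likelihood or bootstrap intervals.
* The enrichment null is uniform placement; GC- or SNP-density-matched
  nulls are out of scope.
* The percentile rule assumes enough windows genome-wide (≥ 200 at the
  0.5% default); tiny genomes should lower the window count or widen the
  fraction deliberately rather than rely on a silent fallback.
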