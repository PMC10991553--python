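# Methods

## Geometry and strand conventions

Coordinates are 0-based, half-open throughout; bedGraph I/O preserves
this. The forward strand is the reference strand 5′→3′ with increasing
coordinate. A DSB at coordinate x0 falls between positions x0−1 and x0.
Because resection degrades the 5′-terminated strand of each fragment,
total-DNA loss appears on the forward strand over [x0, x0+d_right) and
on the reverse strand over [x0−d_left, x0); RPA-bound 3′ ssDNA has the
opposite polarity (reverse strand right of the break, forward strand
left of it). Mirror offsets are defined so that position x0+k on the
right corresponds to x0−1−k on the left; with symmetric per-end kinetics
the expected profiles are exact mirror images, a property the tests
exploit.

## Resection population model (simulator)

A cell is cut with probability `cut_efficiency` (default 0.9; HO cutting
is efficient but incomplete). Each cut end resects independently; the
tract length at time t is lognormal with arithmetic mean
`speed_mean · max(0, t − init_delay)` and coefficient of variation
`speed_cv`. Defaults: 4,000 nt/h per end, CV 0.3, no delay, time points
0/2/4 h — speeds of a few kb/h over a 2–4-h induction time course are
the regime the readouts are designed for. The lognormal is a modeling
choice (per-cell tract distributions are not observable in the assays it
emulates); it guarantees positivity and a tunable tail, and CV 0
degenerates to a deterministic tract. Extents are clipped at chromosome
ends. Uncut cells never resect.

Coverage is rendered as per-base *expected fragment depth* and then
Poisson-sampled (or left noiseless): total DNA at `mean_depth` (default
50×) times the intact-cell fraction at each position; RPA-ChIP as
`beta + alpha · occ` where occ is the ssDNA occupancy fraction, beta a
uniform background (default 2) and alpha the fully-occupied enrichment
(default 40, giving realistic ~20-fold peak-to-background contrast).
DSB-independent background RPA peaks add `beta·(amplitude−1)` on both
strands over their footprint. Read-level simulation (fragment sampling,
adapters, alignment) is deliberately not modeled: the quantification
consumes coverage, and the Poisson field is the correct noise model for
per-base depth at these scales.

What the simulator does **not** emulate: mappability and repeat
structure, GC bias, chromatin accessibility bias in ChIP, fragment-end
effects at the break, replication, repair, or inter-cell correlation of
left/right tracts. Passing tests therefore demonstrate correctness of
the computations under an idealized noise model, not robustness to
every artifact of real libraries; the masked-ratio semantics (below) is
where real-data pathology would first be absorbed.

## Total-DNA quantification

Samples are subsampled to the common minimum read count (uniform,
without replacement, per-sample seeded) before coverage is built, so
ratio tracks compare like with like. Each time point's per-strand,
per-base coverage is divided by the uninduced sample; positions with
zero t0 coverage are masked (NaN), never given pseudocounts — a
pseudocount would fabricate apparent loss at unmappable positions. The
ratio is averaged in 2-kb bins tiling a 20-kb window centred on the DSB
(published geometry; both are configurable). A bin's value is the mean
of its unmasked positions; a fully masked bin stays masked.

The resection front summary scans the degraded strand's bins outward
and linearly interpolates the first upward crossing of ratio 0.5. With
cut efficiency c, the expected ratio at distance d is 1 − c·S(d) where
S is the per-cut-cell tract survival; the 0.5-crossing therefore
estimates the median of the *whole-population* extent distribution
(uncut cells included), which is what the tests compare against. The
front analyses in the demo and acceptance script widen the window to a
24-kb half-width (same 2-kb bins) so the 4-h front (~16 kb) lies inside
the window; the package default keeps the published 20-kb window.

Note on the ratio statistic: a positionwise Poisson/Poisson ratio has
mean inflated by the factor λ·E[1/Y | Y>0] ≈ 1 + 1/λ (≈2% at 50×).
Closed-form checks against ground truth use the exact inverse moments
of the Poisson denominator rather than the naive expectation; users
comparing conditions are unaffected because the factor cancels between
samples of equal depth.

## RPA normalization

Reference peaks are maximal runs of strand-summed coverage at or above
`multiplier × median` (default 6×, genome-wide median including zeros),
kept when 100–500 bp wide. Strands are summed because DSB-independent
RPA binding is not strand-resolved; zeros are included because the
median is meant to be the typical genome background. Candidates from
the pooled coverage of all samples (the anchor) are retained only where
every individual sample also has a peak (≥1 bp overlap) — pooling
stabilizes the anchor, and the recurrence rule keeps only loci common
to the experiment. Peaks intersecting a ±50-kb window around the DSB
are excluded so break-proximal signal cannot normalize itself. The
scale factor is the mean strand-summed coverage over all reference-peak
positions — the simplest scale-equivariant statistic — and both strand
tracks are divided by it. Normalized profiles use 500-bp bins over
±25 kb (binning is for stable desk-scale statistics; the half-width is
the published plotting window).

## qPCR models

Restriction protection: template counting per cell gives undigested
templates 2−f and digested templates f (f = resected fraction), hence
r = 2^(−ΔΔCt) = f/(2−f) and f = 2r/(1+r) = 2/(2^ΔΔCt+1), with the
control amplicon (no restriction site) absorbing tube-loading
differences. ΔCt formulas assume exact doubling; the standard-curve
path covers assays where efficiency matters. A digested Ct at the
40-cycle cap reports f = 0. Replicates are averaged on the Ct scale
(common practice; quantity-scale averaging differs only at high noise)
and replicate scatter is propagated to f by the delta method. An
optional cut-efficiency correction (f divided by the measured cut
fraction) converts per-cell to per-cut-molecule fractions; it is off by
default because either convention is defensible and the uncorrected
number is what the Ct values directly encode. Fractions above 1 beyond
a tolerance (default 0.1) raise an assay-failure error rather than
being silently clipped.

Cut efficiency uses an amplicon spanning the cut site in undigested
DNA: surviving template r = 2^(−ΔΔCt) relative to the uninduced
reference, cut fraction 1 − r.

The simulator's Ct model anchors a reference Ct (default 15 cycles for
the undigested, unresected locus) and adds −log2(fraction)/log2(1+E)
cycles plus optional Gaussian noise, capping at 40 cycles.

## Fluctuation analysis

The estimator maximizes the Luria–Delbrück likelihood over log m using
the MSS recursion, with counts above `r_max` (default 10⁴) pooled into
a tail term P(R ≥ r_max) so jackpot cultures cannot force unbounded
recursions. All-zero counts put the maximum on the m = 0 boundary
(one-sided interval from n·m = 1.92). Confidence intervals are
likelihood-ratio bounds at ΔlogL = 1.92. The truncated pmf sums to
1 − Θ(m/r_max) because the distribution's tail is m/(r(r+1)); the tail
term restores a proper likelihood. A plating-dilution correction is
exposed but off by default.

The culture simulator uses the classic deterministic-growth model:
mutations ~ Binomial(nt − n0, mu) over cell births, each founding a
clone at uniform population size N that grows to floor(nt/N). This was
chosen over a synchronous-doubling scheme because doubling restricts
clone sizes to powers of two, measurably distorting the low-count pmf
(empirically ~5% MLE bias) — whereas the deterministic-growth model
reproduces P₀ = e^(−m) exactly and matches the MSS pmf to chi-squared
goodness of fit at 10⁵ cultures. Defaults (n0 = 100, nt = 10⁷, 8
cultures) mirror a typical 7–8-colony assay design.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; no global random state; derived
seeds stay below 2³¹. Peak thresholding uses ≥ (a run at exactly the
threshold counts); an all-zero-median genome is rejected as degenerate.
Ratio masks are NaN; binned means ignore NaN and all-NaN bins stay NaN.
Front interpolation requires a bracketing pair of bins; no crossing
returns None ("no detectable loss") and a fully masked side is an
error. Standard curves require ≥3 distinct positive quantities, a
negative slope, and an implied efficiency in (0, 1.2]. MSS optimization
is bounded Brent on log m (xatol 1e-10) with brentq root-finding for
the interval edges.

## Problem sizes

Tests and the acceptance script run on a 200-kb chromosome with a break
at 100 kb, 2,000 cells, 50× depth, 10⁴ fluctuation cultures (10⁵ for
distributional checks) — sizes chosen so each stage's statistical
properties are resolvable while the whole suite stays interactive on a
laptop-class machine.

## Known limitations

Single DSB per genome; left/right tracts independent (no per-cell
speed coupling); no repair, so late time points keep resecting; the
BED score column stands in for mapping quality because alignment is out
of scope; bigWig/BAM are not read (text formats only); reference-peak
selection assumes at least one DSB-independent peak exists — an
experiment without them correctly refuses to normalize.
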