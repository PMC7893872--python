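# Methods

## Model and procedure

`ngslod` treats the allele frequency (AF) measured at a locus as a noisy
estimate of a true alt-allele fraction p. One technical replicate yields, per
locus, base-type tallies (A, C, G, T) from quality-filtered aligned reads;
the AF is 100·alt/(A+C+G+T) percent. The denominator is the total of all four
tallies rather than ref+alt only: sequencing errors landing on third bases
then slightly depress the AF, which is the conservative direction for a
detection limit.

Precision across n replicates is summarized per locus by the mean AF x̄, the
sample standard deviation s (n−1 denominator; with n = 4 the distinction from
the population SD is material) and the percent relative standard deviation
%RSD = 100·s/x̄. The limit of detection is defined through the classical
requirement that a detectable signal exceed 3.3 times its own standard
deviation; in relative terms x̄ = 3.3·s is %RSD = 100/3.3 ≈ 30, so
LOD_30%RSD is the AF at which the precision profile reaches 30 %RSD.

Because the per-locus %RSD from a handful of replicates is itself very noisy
(with n = 4, s has ~41% relative sampling error), the profile is smoothed
before the read-off: loci are ordered by mean AF (ties broken by locus key,
deterministically) and the %RSD series is averaged over a centered k-point
moving window, k ∈ {1, 3, 5, 7}, default 7. Edge windows truncate to the
available points rather than dropping them, so the low-AF end of the curve —
where the LOD lives — keeps a smoothed value. The smoothed curve is taken as
piecewise linear in (mean AF, smoothed %RSD); the LOD is the AF where it
equals the threshold, by linear interpolation between the bracketing points.
This formalizes "reading the value off the plotted curve" in a reproducible
way; whether a human reader interpolates linearly is of course not knowable,
so the linear rule is a definition, not a reproduction claim.

A noisy profile can cross the threshold several times. The reported LOD is
the **largest** crossing AF — the value a reader tracing the curve from the
right would stop at, and the conservative (highest) choice; the number of
crossings is exposed as `crossing_count` so multi-crossing profiles are
visible. Points exactly on the threshold count once even though two segments
share them. If the whole smoothed curve lies below the threshold the result
is censored `below_min` (the true LOD is smaller than the smallest panel AF);
entirely above, `above_max`. Censored results carry no LOD value.

## Downsampling

Reducing a dataset to a target size (e.g. 40 → 5 Gbp) is modeled as
independent per-read retention with probability f = target/total. At
single-locus resolution this is equivalent in distribution to binomially
thinning each base tally with success probability f, which is what
`downsample_counts` does; read identity never needs to be tracked. Thinning
is deterministic given (counts, fraction, seed): the generator is seeded per
invocation from the seed and the locus coordinates. Two consequences are used
as test invariants: thinned tallies never exceed the originals, and thinning
by f1 then f2 equals thinning by f1·f2 in distribution (checked on moments).

## Accuracy assessment

When targets carry pre-validated AFs (e.g. ddPCR values), each replicate's
measured AFs are compared to them by Pearson correlation, with the two-sided
p-value from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom, and by ordinary
least squares with the validated AF as predictor (the axis convention of
reference-vs-measured scatter plots). Sidedness is not dictated by the
method; two-sided is the conservative default and is what is reported. No
multiple-testing correction is applied across replicates or tiers.

## Synthetic data

The simulator emulates a reference-standard validation experiment: a truth
panel of point mutations with known AFs, measured in independent replicates
at one or more depth tiers.

Defaults encode the quadruplicate reference design: 20 loci with true AFs
evenly spaced over 1.0–33.5% (the span of the commercial ddPCR-validated
standard; its individual per-locus values are proprietary, so the even grid
is an emulation, labeled synthetic, never the standard's true composition),
4 replicates, and tier depths 63×, 189×, 377×, 503× keyed to the labels
5Gbp/15Gbp/30Gbp/40Gbp.

Per locus and replicate: depth d is either fixed at the tier mean or Poisson
with that mean (minimum 1; Poisson is the default because capture depth
varies across loci in real data, while fixed mode keeps the closed-form
oracles exact); the replicate's alt fraction is p, or, with overdispersion
rho > 0, a Beta draw with mean p and intraclass correlation rho
(concentration a+b = 1/rho − 1); the alt tally is Binomial(d, p_rep); of the
remaining bases a Binomial(d−alt, error_rate) spill goes to one fixed third
base (exercising the all-bases denominator) and the rest to ref.

With rho = 0 and error_rate = 0 (the defaults) the model is pure binomial
sampling, for which the AF estimator's RSD is 100·√((1−p)/(D·p)) and the LOD
at threshold t has the closed form 100/(1 + D·(t/100)²) percent — 5.55% at
D = 189, t = 30. These closed forms are the package's independent oracles:
the full pipeline on a dense grid (50 loci, 100 replicates, fixed depth)
recovers the closed-form LOD within ±1 percentage point, averaged over 20
seeds.

What the simulator deliberately does **not** model: library-preparation and
capture noise (which make real replicate variance exceed binomial, and real
LODs exceed the closed form — empirically ~9% at 189× vs 5.55% binomial),
GC/capture bias, mapping artifacts, overlapping mate pairs, and read-level
sequence context. Passing tests on synthetic data therefore demonstrate that
the estimator is correct for its sampling model, not that any particular real
assay achieves these LODs. The `overdispersion_rho` knob exists to produce
qualitatively realistic (inflated) variance — variance inflation factor
1 + (d−1)·rho — for demonstrations, but no rho value is claimed to reproduce
any real library chemistry.

Reproducibility: all generators are numpy `default_rng` seeded with integer
vectors [seed, crc32(tier label), replicate index], so every replicate is an
independent stream, reruns are bit-identical, and all derived seeds stay
below 2³¹.

## Counting parameters

`count_bases_at_loci` excludes reads flagged unmapped, secondary,
supplementary or duplicate, and applies min base quality 13 and min mapping
quality 20 by default (both configurable). Full production pipelines
recalibrate base qualities before counting; recalibration is out of scope
here, so these mild fixed filters are explicit stand-ins and are stated
rather than silent. Deletions and reference skips at the target position
contribute to no tally (only substitution evidence defines an SNV AF). All
external coordinates are 1-based (VCF convention); 0-based conversion is
internal. A locus on a chromosome absent from the alignment header yields
depth 0 with a warning rather than an error. Overlapping read pairs are not
deduplicated — a known limitation that can double-count a fragment's
evidence at a locus.

## Numerical and degenerate-input choices

- AFs are carried in percent everywhere; fraction-scale inputs are converted
  at the I/O boundary only.
- Loci with zero depth in any replicate, or mean AF exactly 0, are excluded
  from the precision profile with a logged count; %RSD is undefined there
  and exclusion is the only well-defined choice.
- %RSD bins ([0,10), [10,20), [20,30), [30,∞)) are half-open with the worst
  bin closed on the left, so RSD exactly 30 counts as ≥ 30.
- The moving-average window must be odd; an even k raises immediately.
- Crossing deduplication tolerance is 1e-12 in AF, only to avoid
  double-counting an exact-hit point shared by two segments.
- Report floats are serialized at 4 decimals; JSON reports round-trip at that
  precision.

## Problem sizes used in the checks

The stochastic checks run at desk scale, chosen to keep Monte-Carlo error
well inside the asserted tolerances: oracle recovery uses 50 loci × 100
replicates × 20 seeds; the replicate-design median LOD uses the default
20 × 4 design over 100 seeds (median ≈ 7% AF at 189×, censoring rate ~10%);
the depth-trend check uses 50 seeds per tier; thinning moments use 1000
seeds. Deeper tiers censor often (the whole binomial curve sits below
30 %RSD when the panel starts at 1% AF), so medians are taken over
uncensored runs and the uncensored count is reported alongside.
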