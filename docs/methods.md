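# Methods

This note documents the models, defaults and design choices behind
`ddrain`, in the package's own terms.

## Partition statistics and quantification

Templates are assumed distributed over droplets independently at
random, so per-droplet copy numbers are Poisson.  For a channel with
rate λ the probability a droplet is negative is `e^−λ`, giving the
zero-class estimator

    λ̂ = −ln(n_negative / n_accepted)

per channel (mutant-channel negatives are NN+NP droplets, wild-type
negatives NN+PN).  The variant allele frequency is the rate ratio
`VAF% = 100·λ_mut/(λ_mut+λ_wt)`.  Two degenerate cases are flagged
rather than imputed: a channel with zero negatives (saturation — the
estimator diverges; raising the dilution, not imputation, is the remedy)
and λ_mut = λ_wt = 0 (no template; VAF undefined).  Confidence
intervals on λ or VAF are out of scope; only point estimates are
reported.  Concentration in copies/µL is not computed: it would need
the droplet volume, and the VAF needs only the ratio of rates.

## Classification

**Manual gating.** Per-channel cuts at `mean + m·SD` (sample SD) of the
NTC amplitudes, default multiplier m = 5 — a conservative gate just
above the no-template cloud.  A droplet is channel-positive only when
*strictly* above the cut, so boundary droplets count as negative and
are never double-counted.  Gating partitions the plane into exactly
four quadrants; manual gating never emits RAIN.

**k-NN.** Supervised nearest-neighbour classification with k = 3 by
default, Euclidean distance in raw (ch1, ch2) amplitude space — raw
space matches the geometry manual gating operates in, and the two
channels are on comparable scales; per-channel standardisation was
considered and rejected as an extra degree of freedom with no benefit
on comparable-scale channels.  The label is the majority vote of the k
nearest training droplets.  Tie rule: among the classes sharing the
maximal vote count, the class of the nearest neighbour belonging to one
of them wins.  For k = 3 this is exactly "the nearest neighbour
breaks the tie"; the formulation also keeps the majority property in
corner cases at larger k where the single nearest neighbour's class is
not among the top-voted ones.  Neighbour order ties at equal distance
follow stable training order; with continuous amplitudes these have
probability zero.

**Training sets** pool manually classified droplets from
`wells_per_plate` (default 3) randomly chosen eligible wells per plate,
drawn with a seeded generator; source well and sample ids are recorded
so that comparisons can exclude training material.  Droplets already
set aside as RAIN are dropped when pooling, since RAIN carries no
cluster identity.

**Rain filter.** Two rules relabel droplets as RAIN: (1) the larger of
the two channel amplitudes below `low_bound` (broken droplet) or above
`high_bound` (multi-template/outlier); (2) Euclidean distance from the
droplet to the centroid of its assigned class's training droplets above
`rain_distance`.  Defaults: `low_bound` 300 and `high_bound` 12,000
fluorescence units — with the default simulator geometry these sit
several SD clear of the legitimate clusters — and `rain_distance`
derived from the training data as 3× the pooled within-class
per-channel SD (the df-weighted root-mean of per-class, per-channel
sample variances).  For a symmetric Gaussian cluster the distance to
centroid is Rayleigh-distributed, so a 3σ cut removes roughly 1% of
genuine droplets (symmetrically in both channels, leaving the VAF
essentially unbiased) while catching nearly all degraded droplets,
whose displacement toward another cluster is many σ.  The filter is
idempotent and monotone: shrinking `rain_distance` can only increase
the RAIN count.

## QC, replicate selection and positivity calling

A reaction fails QC when fewer than 10,000 accepted (non-RAIN) droplets
remain, or when the mean of its three positive-class counts (PP, PN,
NP) is below the same mean in the NTC — the literal three-number mean,
not the total positive count.  With several NTC wells on a plate the
per-well means are averaged (summing counts across NTC wells would
scale the comparison with the number of NTC wells).  Among replicate
reactions of one sample, the QC-passing replicate closest to the
reference measurement is kept (ties → lowest replicate index); without
a reference value the lowest-index passing replicate is used.

The positivity threshold is `mean + t_{1−α/2, n−1}·s/√n` over the
negative-control VAFs, i.e. the upper bound of a *two-sided*
confidence interval on the mean (default confidence 99.98%,
α/2 = 10⁻⁴ per tail) under the t distribution.  A sample is positive
only strictly above the threshold; an undefined VAF yields a distinct
`no-call`.  The pipeline's fixed default threshold of 9.82% is a
documented legacy constant from pyrosequencing negative controls, kept
as a configuration default rather than a reproducible output; setting
`threshold_percent: null` derives the threshold from the run's own
negative-control wells instead.

## Comparison statistics

Spearman rank correlation (mid-ranks for ties) with the p-value from
the t approximation `t = R·√((n−2)/(1−R²))` — standard at the n ≈ 90+
of realistic method comparisons.  An exact permutation p-value mode is
provided for n ≤ 8 by full enumeration (beyond 8 the factorial
enumeration buys nothing over the approximation).  Qualitative
agreement is a 2×2 positive/negative table whose discordant total is
the off-diagonal sum.  Replicate variability reports per-sample
maximal pairwise |difference|, the mean of per-sample mean pairwise
differences, and the mean of per-sample sample SDs; samples with a
single replicate are excluded from these summaries.  Samples that
trained the k-NN classifier are excluded from all comparisons.
LOESS/density visualisations are deliberately not implemented; the
correlation statistic is the quantitative comparison.

## The simulator

`simulate_well` draws mutant and wild-type copy counts
`Poisson(λ_mut)`, `Poisson(λ_wt)` per droplet; presence/absence fixes
the true class.  End-point PCR saturates, so amplitude depends only on
presence, not copy number: amplitudes are Gaussian (SD 400) around
class centers NN=(1000,1000), NP=(1200,9000), PN=(9000,1200),
PP=(9000,9000) — values chosen once for well-separated clusters with
plausible rain geometry on a QX100-like amplitude scale.  Artifacts
are a single categorical draw per droplet (so the three fractions are
mutually exclusive and capped at 1): *rain* pulls a positive droplet
linearly toward the NN center by a Uniform(0.2, 0.9) factor, and
symmetrically raises an NN droplet toward a randomly chosen positive
center (elevated background); *broken* droplets get |N(0, 50)|
amplitudes in both channels; *outliers* multiply both amplitudes by
Uniform(2.5, 4).  Artifacts never touch the drawn copy counts, so the
ground-truth VAF `100·λ_mut/(λ_mut+λ_wt)` is invariant to artifact
injection.  Defaults: 15,000 droplets per well (middle of the
10,000–20,000 partition band), λ_wt = 0.5 (a comfortably unsaturated
loading), reference-method noise SD 1.32 percentage points (a realistic
pyrosequencing replicate SD).  One global seed derives per-well seeds
(seed + well index), making plates reproducible bit-for-bit.

What the simulator does *not* emulate: amplification kinetics and
per-cycle chemistry, droplet volume variation, channel cross-talk, and
the heavy-tailed, sample-specific degradation of real FFPE DNA.
Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under the stated statistical model, not
clinical performance on real plates.

The study-level generator (`SimStudyConfig`) lays out plates with
samples in replicate plus one NTC, one positive control (VAF 50) and
one negative control (VAF 0) per plate; true sample VAFs come from a
mixture — 20% near-zero (wild-type) samples, else a broad positive
population N(30, 15) truncated to [5, 70] — emulating a cohort where
most specimens carry the mutation at widely varying allele fractions.

## Numerical and interface choices

Amplitude CSVs are written with 17 significant digits and parsed with
numpy's correctly-rounded string conversion, so write→read round-trips
are bit-exact.  Droplet order is preserved everywhere; classification
is per-droplet, hence permutation-equivariant.  All tabular outputs
use fixed column orders and 6-decimal formatting, and every random
choice flows from the run seed, so identical configs reproduce
byte-identical outputs.  Problem sizes in the test suite and the
reproduction script (e.g. 100 recovery wells per VAF level at 15,000
droplets; 30–50 rain simulations; a 3-plate simulated study) are chosen
to make the Monte-Carlo checks stable at desk scale.

## Known limitations

* The Poisson model ignores droplet volume variation; λ is per-droplet,
  not per-µL.
* The k-NN route needs a manually labeled training set; no unsupervised
  fallback is provided.
* The rain-distance default (3× pooled within-class SD) is a
  data-driven convention, not a universal constant; wells with unusual
  cluster geometry may need an explicit value.
* Saturated channels are refused, not rescued; heavily loaded samples
  must be diluted and re-run.
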