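# Methods

## Weighted-averaging calibration

Taxon TP profiles are weighted-averaging (WA) estimates on the log₁₀ TP
axis: the optimum is the abundance-weighted mean of log₁₀ TP over occupied
samples, the tolerance the abundance-weighted standard deviation in the
population form (denominator Σw) — the direct analogue of the weighted
mean, chosen because nothing in the method's definition singles out a
frequency-corrected form. Presence means relative abundance strictly > 0;
relative-abundance zeros are "not counted", not missing data.

Cross-validation repeats the estimate over `n_repeats` (default 100)
unstratified random partitions with `train_fraction` 0.75; repeat *r* draws
its permutation from seed `base_seed + r`, so a whole plan is reproducible
from one integer. Per repeat, taxa occurring in fewer than
`min_occurrences` (default 10) training samples are dropped; a taxon's
final optimum/tolerance is the unweighted mean over the repeats in which it
passed the filter (profiles exist only for retained taxa, so averaging over
all repeats would be undefined). Taxa retained in no repeat are omitted.

Sensitivity classes use fixed breakpoints 1.1, 1.2, 1.5, 1.7 log₁₀ µg/l
bounded by 0 and 3; intervals are lower-inclusive, upper-exclusive, with
the top class closed at 3 (one convention has to be fixed; it is
configurable). Optima outside (0, 3] clamp to the nearest class with a
warning. Indicator classes split the *final* tolerance range — after
repeat-averaging, not per repeat, since one class per taxon is published —
into three equal-width bins, lowest tolerance = class 1, same edge
convention; a degenerate (zero-width) range puts everything in class 1.

Known estimator property, asserted by sign in the tests: taxa whose niches
are truncated by the sampled gradient get WA optima biased toward the
gradient centre. On data where taxa sit well inside the gradient a small
*outward* compositional drag can dominate instead (relative abundances
inflate where competitors are scarce); the shrinkage test therefore places
taxa explicitly near the gradient edge.

## The index

PDI_SE = Σ a_j s_j v_j / Σ a_j v_j with a_j = √(relative abundance) by
default (`identity` available). Unscored taxa are excluded from both sums —
the ratio renormalizes implicitly — and the abundance fraction carried by
scored taxa is reported as `coverage`; no minimum coverage is enforced, the
user decides. Because the ratio cancels any positive rescaling of a sample,
percent and proportion inputs give identical values. Cross-validated
scoring fits profiles per training split (classes assigned per split, the
indicator intervals from that split's tolerances) and averages each site's
value over the repeats in which it fell in the test set.

Site-specific community optima weight the taxon optima by *raw* relative
abundance: the square root belongs to the index formula only, and the
community optimum is defined as a plain abundance-weighted mean.

## Dip statistic and test

Hartigan's dip — the sup-norm distance from the empirical CDF to the
nearest unimodal CDF (convex increasing, then concave increasing, an atom
allowed at the mode) — is computed by the iterative modal-interval
construction on the greatest convex minorant (GCM) and least concave
majorant (LCM): narrow the candidate modal interval to the hull touchpoints
bracketing the largest GCM–LCM gap, accumulate the deviation of the CDF
from the minorant left of the interval and from the majorant right of it,
and stop when the within-interval gap no longer exceeds the accumulated
deviation; the dip is half that deviation. Ties are compressed to distinct
values carrying left/right cumulative counts; at a modal-interval terminal
only the CDF's one-sided limit binds, so a tie run at a terminal
contributes nothing. The result satisfies 1/(2n) ≤ D ≤ 1/4 and is invariant
under duplication of the sample and under monotone transforms.

The same module carries an independent reference: the defining minimax
problem solved exactly as linear programs, one per candidate mode position,
with the CDF's left limit at the mode as an explicit variable so the
mode's atom and the chord-convexity constraints are modelled exactly
(positions interior to inter-point gaps are scanned on a grid). The
production algorithm agrees with it to < 1e-10 across several hundred
fuzzed vectors including heavy ties; the equivalence test runs on 50
vectors at tolerance 1e-8.

p-values are Monte-Carlo: the fraction of uniform(0,1) samples of the same
n whose dip reaches the observed value (the dip is scale-free, so the
uniform calibrates any continuous unimodal null). `null_dip_distribution`
lets many tests at one n share a null sample; at least 500 replicates are
required.

## Thresholds, groups, SIMPER

Mode finding uses a Gaussian KDE with Silverman's rule-of-thumb bandwidth
evaluated on a 512-point grid spanning the data range ± 3 bandwidths.
Candidate modes are grid local maxima; wiggles below 5% of the peak density
are discarded, and the two highest-density modes at least one bandwidth
apart become m₁ < m₂ (fewer than two ⇒ "unimodal — thresholds undefined").
The "first interquartile" is read as the 25th percentile of the observed
values in [min, m₁] (a data quantile, consistent with the overlaid
symmetric-distributions picture), reflected about m₁: t_low = m₁ + (m₁ −
q_low); symmetrically t_high = m₂ − (q_high − m₂) with the 75th percentile
above m₂. Reflection assumes reasonably compact components: with long
outer tails the reflected points can cross (t_low > t_high), which the
pipeline reports as "modes not well separated" and skips group assignment
rather than failing. Group assignment uses strict inequalities on the
linear-scale thresholds; values exactly at a threshold fall in the
intermediate ("lukewarm") group.

Bray–Curtis dissimilarities come from scipy's pdist. SIMPER is computed
directly from its definition on untransformed relative abundances (the
convention of the software it is usually run in): a taxon's contribution to
a group contrast is the mean over all between-group site pairs of its term
|y_ik − y_jk| / Σ_m (y_im + y_jm), expressed as percent of the mean
between-group dissimilarity; an `overall` table pools all between-group
pairs across the three groups. Contributions sum to 100% by construction,
which the tests assert to 1e-9; a brute-force pair enumeration serves as
the oracle.

## Boundary conversion

Ordinary least squares (y = index, x = log₁₀ TP, matching the published
equation orientation; no errors-in-variables treatment) backs the
regression step; the shipped defaults are the published fits
PDI_SE = −0.29·IPS + 8.0536 and PDI_SE = 1.84322·log₁₀TP + 0.6493 — the
higher-precision coefficient pair is used because it reproduces the
published boundary TP values exactly. Display rounding (EQR and PDI to two
decimals, TP to integers) never feeds back into the chain; exact values are
kept in `*_exact` columns. TP values outside the 4–100 µg/l linear response
range are replaced by a "no response" marker.

## Synthetic communities

The generator emulates the statistical structure the calibration assumes,
with defaults fixed to the study conditions:

* **Gradient** — log₁₀ TP ~ Normal(1.4, 0.45) over 820 sites: median
  ≈ 25 µg/l and a realized range of roughly 1–900 µg/l.
* **Niches** — Gaussian response on log₁₀ TP. Taxon optima ~ Normal(1.49,
  0.35) (median ≈ 31 µg/l, interquartile ≈ 18–54 µg/l) in *every* regime:
  the taxon-optimum distribution is always unimodal, as observed in real
  calibration sets. True niche SD is log-normal with median 0.12 log₁₀
  units — the realized abundance-weighted tolerances come out larger
  (≈ 0.12–0.19) because the estimator mixes gradient spread into the niche
  breadth. Carrying capacities are log-normal (σ = 0.5).
* **Counts** — 400 valves per sample, multinomial (the fixed-effort
  counting protocol), divided by the valve count, so rows sum to 1 exactly
  and converge to the expected shares as the count grows.
* **Two-pool regime** — taxa are labelled low / intermediate / high by the
  optimum band (1.25, 1.60); `generate_bimodal_regime` multiplies the
  intermediate pool's capacity by `suppression` (default 0.3). Bimodality
  of *site* optima thus emerges from abundance suppression alone: at
  suppression 0.3 the pool abundance shares land near 40/17/43%, echoing
  the observed scarcity of intermediate-optimum abundance, and at 0.2 the
  dip test rejects unimodality of site optima (p < 0.01 at n = 800 across
  seeds) while suppression 1.0 reduces exactly to the base model and stays
  unimodal. A binary per-label suppression was kept (rather than a smooth
  capacity valley) because the pool label is the unit the analysis
  reasons about; it is a phenomenological stand-in, not a mechanism claim.

What the generator does *not* emulate: spatial autocorrelation, temporal
revisits, a correlated pH co-gradient, taxonomic misidentification, or the
heavy rank-abundance skew of real assemblages. Passing tests therefore
demonstrate that the algorithms recover known structure under their own
assumptions — not that the index performs on real monitoring data.

## Problem sizes and numerical choices

The test suite runs its Monte-Carlo at the sizes the checks need rather
than survey scale: 200 sites × 30 taxa for parameter recovery (Spearman
ρ > 0.9), 500 sites for split-averaging stability (optima agree to < 0.02
log₁₀ units between independent base seeds at 100 repeats), n = 800 with a
shared 500-replicate null for dip-test calibration and power, 4000-point
mixtures for threshold recovery. All randomness flows from explicit seeds
(simulation configs seed per-stage independent substreams; split r uses
`base_seed + r`). Abundance rows are validated to sum to 1 within 1e-6;
delimiter sniffing accepts comma, semicolon (with decimal comma) and tab;
missing abundance cells read as 0. Pipeline outputs are written atomically
(temp file + rename), carry the toolkit version and seed in a `#` comment
header, and are summarized in a manifest of SHA-256 checksums, so identical
config + seed yield byte-identical manifests.

## Known limitations

* The dip test's p-value is Monte-Carlo, so its resolution is 1/n_null_reps.
* Quartile-reflection thresholds are undefined for unimodal data and
  unreliable when the two components overlap strongly or have long outer
  tails (reported, not guessed).
* WA calibration inherits the classic edge bias; no deshrinking or
  tolerance down-weighting variants are provided.
* The comparison regressions against IPS/TDI require user-supplied index
  values; no IPS or TDI coefficients ship with the package.
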