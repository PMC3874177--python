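# Methods

## Problem and model

Meiotic recombination starts with programmed DNA double-strand breaks (DSBs)
that cluster at hotspots — in fission yeast up to ~400-fold above the cold
background. The package compares per-hotspot DSB levels between two meiotic
induction conditions (generically "A", the reference, and "B", the test
condition) and quantifies the downstream recombination intermediates:
DSB fragments on Southern blots, Holliday junctions (HJs) and a Y-shaped
novel species (NS) on 2D gels, crossover restriction fragments, and
recombinant frequencies among viable spores.

### Array model

A tiling array reports IP (Rec12–DNA immunoprecipitate) and WCE
(whole-cell-extract) intensities per probe. Enrichment is

    ratio_i = (ip_i / wce_i) / median_j(ip_j / wce_j),

so the genome median is exactly 1 and cold background sits at ratio ≈ 1.
Median normalization is idempotent. Arrays are placed on a common scale in
log space: with sₖ and rₖ the mean log₁₀ ratios of the target and reference
array over six prominent reference hotspots, the factor

    c = argmin_c Σₖ (c·sₖ − rₖ)²  =  Σₖ rₖsₖ / Σₖ sₖ²

multiplies the target's log ratios. The reference array is the one with the
highest mean log ratio over the reference set (ties by input order); a
warning is raised for c outside [1.0, 1.5]. Integrated hotspot signal is

    S(h) = Σ_{probes in h} max(ratio − 1, 0) · probe_width   [bp·fold],

an above-baseline mass proportional to enriched DNA; probes belong to an
interval when their midpoint falls inside (midpoint rule; coordinates are
0-based half-open throughout). Percent DNA breakage is `slope · S(h)` with
the slope fitted through the origin on Southern-blot calibration pairs
(zero signal ⇔ zero breakage); hotspots above 0.3 % are "passing", counted
as the union over conditions because a de novo hotspot has signal in only
one condition.

### Differential calling

Per-hotspot log₁₀ percent-breakage values of condition B are regressed (OLS)
on condition A. A new observation at x lies, with 95 % probability, inside

    ŷ(x) ± t₀.₉₇₅,ₙ₋₂ · s · sqrt(1 + 1/n + (x − x̄)²/Sxx),

so points above/below the interval are called increased/decreased; a point
exactly on a limit is inside. Replication is the error control: a hotspot
is *reproducibly* changed only when called in the same direction in every
replicate comparison. No FDR correction is applied beyond this PI-plus-
replication rule; with 288 hotspots ≈ 14 null points fall outside any single
comparison's interval, so single-comparison calls are never interpreted
alone — this is a deliberate, documented caveat. The regression universe is
hotspots above threshold in the replicate mean of both conditions; hotspots
with signal in only one condition are routed to the de novo detector, which
requires > 0.3 % breakage in the new condition and < 0.15 % in the other
(half-threshold guard band against boundary flicker). The log₁₀ scale is
the default (a linear option exists) because cross-array scaling operates in
log space and hotspot intensities are closer to log-normal.

### Gel densitometry

Lane traces carry named band windows (parental, DSB fragments, recombinant
fragments R1/R2). Per window, a straight baseline interpolated between the
window-edge intensities is subtracted and negative net signal clipped to
zero; fractions are of the whole-lane integral ("total DNA"), making all
quantities invariant to exposure. Crossover DNA is `2 × R2 fraction × 100`
— only the shorter recombinant fragment is counted (and doubled) because
partial digestion can contribute to the longer one. On 2D grids the
background is the median of a 4-pixel ring around each rectangular spot
window. HJ frequency is the IS+IH volume fraction ×100; IS:IH is the IS
volume over the summed small- and large-fragment IH volumes, reported as
undefined (None) when IH volume is zero.

### Recombination genetics

Haldane's no-interference map function `d = −50 ln(1 − 2R)` and its inverse
`R = (1 − e^(−d/50))/2` (round trip exact to <1e-9 over 0–300 cM). With
only group summaries (mean ± SEM, n) available, the unpaired t statistic is
`|Δmean| / √(sem_a² + sem_b²)`; the default df rule is the pooled count
`n_a + n_b − 2`, with Welch–Satterthwaite (from the SEMs) as an option — the
two give p ≈ 0.062 and p ≈ 0.076 on the packaged example summaries, and the
correct variant behind a published p can rarely be determined, so both are
exposed rather than forced. The 2×2 chi-square is Pearson's without
continuity correction by default (Yates by flag).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure needed to test each
quantifier, not the biochemistry:

* **Arrays.** Desk-scale genome of 3 chromosomes, 2.4 Mb, 300 bp probe
  spacing (~8,000 probes; the same spacing over a full 12.57 Mb genome gives
  ~44,000). The default scenario plants 288 non-overlapping hotspots of
  width 1.5–2.5 kb with truncated log-normal intensities (10^N(1.4, 0.22),
  clipped to [5, 400]) plus six reference hotspots at 150–400×, Gaussian
  kernels (sd = width/4, truncated at the interval bounds so noiseless
  integration round-trips exactly; a rectangular shape is available).
  Noise is hierarchical in log10: per-(hotspot, condition) sd 0.020,
  per-(hotspot, array) sd 0.037, per-probe sd 0.010, calibrated once so
  replicate integrated signals correlate at r ≈ 0.98 and cross-condition
  comparisons at r ≈ 0.8 (the planted outliers themselves drag the overall
  cross-condition r down from the unchanged-hotspot value, as in real
  comparisons where changed hotspots are part of the scatter). Each
  non-reference array gets a log-scale gain drawn uniformly in
  [1/1.3, 1/1.1], so fitted scale factors land in the 1.1–1.3 range.
* **Planted effects.** 11 hotspots increased in condition B with factors
  log-spaced in [3.3, 5], 6 decreased with factors in [0.10, 0.25] (placed
  at the most intense non-reference sites so their reduced signal stays
  above threshold), 1 de novo hotspot present only in B. The factors sit
  well clear of the prediction-interval boundary because the planted truth
  mirrors hotspots that were *reproducibly called*: with 17 outliers among
  288 points, the outliers themselves inflate the OLS residual SD to
  ~0.30–0.35 log₁₀ units, so effects much below ~2.2-fold are statistically
  uncallable under this design regardless of noise level — a real
  limitation of the PI rule that the scenario deliberately respects.
  Breakage truth is κ·S(h) with κ set so the weakest hotspot reaches 0.5 %
  in its stronger condition.
* **Lanes.** Band mobility is `95 − 40·log₁₀(size in kb)` (arbitrary
  constants; only monotonicity matters). Broken fractions follow a
  piecewise-linear rise (onset 5 h, peak 6.5 h) and fall (complete by 8 h);
  rad50S mode rises and plateaus. Bands are window-truncated renormalized
  Gaussians, so noiseless planted fractions are recovered to ≤1e-6.
* **2D gels.** Spots are window-truncated 2D Gaussians on a uniform
  baseline absorbing the residual signal, so fractions are conserved
  exactly. The "mbs1-25C" preset plants HJ = 2.1 % of total DNA at IS:IH =
  3:1 (IH split equally between its two restriction-fragment forms) and
  NS = HJ/1.3; the time-course preset plants HJ:NS = 1.3/1.7/2.6 at
  7/8/9 h. Default preset noise is 1e-6 per pixel against a grid total
  of 1.
* **Crosses.** Recombinants ~ Binomial(n_spores, R) with R from the inverse
  Haldane function (intergenic) or a given per-10⁶ frequency (intragenic).

Not emulated: scanner images, dye or hybridization chemistry, probe GC
effects, lane/spot detection from real scans, chromatin context, or any
mechanistic meiotic kinetics. Passing tests therefore demonstrate that the
quantifiers are correct and well-calibrated on data with this statistical
shape — not that the biological conclusions would survive artifacts real
data may contain (spatial background gradients, saturation, partial
digestion beyond the R1 case handled above).

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawn keys; no global RNG state. Identical
  seeds give bitwise-identical simulations and byte-identical pipeline
  output files.
* Probe tables and intervals are strictly parsed (a malformed line aborts
  with its line number); overlapping intervals are rejected everywhere.
* Empty inputs raise rather than return empty results (empty probe table,
  empty interval list, zero-total lane/grid); a calibration fit requires at
  least two pairs with positive signal and a positive slope.
* Negative background-subtracted areas are clipped to zero; IS:IH with zero
  IH volume is None, never infinity; a point exactly on a PI limit is
  unchanged; fractions are reported against whole-lane/grid totals so all
  gel quantities are scale-invariant.
* The Monte-Carlo PI coverage check accepts 4–6 % outside on Gaussian nulls:
  in-sample points sit slightly below the nominal 5 % because the interval
  is evaluated at fitted points rather than new observations.

## Problem sizes

The default test and acceptance configuration uses the desk-scale genome
(~8,000 probes, 288 hotspots, 2 replicate pairs × 2 conditions), 1000-
simulation Monte-Carlo checks at n = 288, and 10⁵-spore crosses; the whole
suite runs in well under a minute. All sizes are ordinary function
arguments, so full-genome scenarios only require a different `GenomeSpec`.

## Known limitations

* The "integrated value" statistic and the densitometry baselines are one
  defensible reading of under-specified published practice; alternatives
  (window means, global backgrounds) would change absolute values but not
  round-trip correctness, and the calibration step absorbs linear
  rescalings.
* The scale factor is fitted per array against a single reference, not
  jointly.
* The PI caller controls errors only through replication; it is not an FDR
  procedure and a factor-2 effect among ~6 % gross outliers is below its
  detection floor (see above).
* Summary-level t-tests cannot reproduce a replicate-level computation when
  only SEMs survive; both df conventions are provided instead.
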