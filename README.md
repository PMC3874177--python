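# dsbquant

Quantitative comparison of meiotic DNA double-strand-break (DSB) hotspots and
recombination intermediates between two meiotic-induction conditions in
fission yeast — for example a synchronous meiosis driven by an ATP-analog-
sensitive *pat1* kinase allele at 25 °C versus the classical temperature-
sensitive allele at 34 °C.

The package is aimed at researchers analyzing ChIP-chip tiling-array DSB
maps, Southern-blot densitometry and 2D-gel joint-molecule assays who need a
tested, seedable implementation of the full quantitative chain:

1. **Array normalization** — per-probe IP/WCE ratios, genome-median
   normalized so cold background sits at ratio 1; arrays are put on a common
   scale by multiplying each array's log₁₀ ratios by a factor
   `c = Σ rₖsₖ / Σ sₖ²` fitted over six prominent reference hotspots against
   the array with the highest signal there (typical factors 1.1–1.3).
2. **Hotspot integration and calibration** — integrated signal
   `Σ max(ratio−1, 0) × probe width` per hotspot interval, converted to
   percent DNA breakage through a through-origin fit against Southern-blot
   calibration pairs; hotspots above 0.3 % breakage are "passing".
3. **Differential calling** — OLS of condition-B on condition-A log₁₀
   signals with the two-sided 95 % prediction interval
   `ŷ(x) ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (x−x̄)²/Sxx)`; a hotspot outside the
   interval in *every* replicate comparison is reproducibly
   increased/decreased, and hotspots with signal in only one condition are
   caught by a separate de novo detector.
4. **Gel densitometry** — percent DNA broken per lane, crossover DNA as
   `2 × R2 / total DNA`, 2D-gel spot volumes giving Holliday-junction (HJ)
   frequency, the intersister:interhomolog (IS:IH) ratio, and HJ:novel-
   species time-course ratios.
5. **Recombination genetics** — Haldane's map function
   `cM = −50 ln(1 − 2R)`, fold changes, an unpaired t-test from mean ± SEM
   summaries, and the 2×2 contingency chi-square.

Every stage is exercised against seeded synthetic data with planted ground
truth (`dsbquant.synthetic`), so the whole pipeline is testable without any
external downloads.

## Worked example

```python
from dsbquant import build_scenario, run_scenario_pipeline

scenario = build_scenario(preset="paper-emulation", seed=1)
report = run_scenario_pipeline(scenario)["report"]
print(report.passing_counts["union"], report.pearson_r,
      report.n_increased, report.n_decreased, report.n_de_novo)
```

prints

```
288 {'0': 0.789, '1': 0.793} 11 6 1
```

meaning: all 288 planted hotspots exceed the 0.3 % breakage threshold in at
least one condition; the two replicate cross-condition comparisons correlate
at r ≈ 0.79 (replicates within a condition correlate at r ≈ 0.98); and the
prediction-interval caller recovers exactly the planted 11 reproducibly
increased hotspots, 6 decreased hotspots and the single hotspot present only
in condition B. The `examples/` directory contains one narrative script per
capability (array calling, lane time courses, 2D gels, cross statistics).

A thin CLI mirrors the stages:

```sh
dsbquant simulate array --preset paper-emulation --seed 1 --out sim/
dsbquant gelquant grid.tsv --windows grid.meta.json --grid --out quant.json
dsbquant run --config pipeline.yaml
```

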