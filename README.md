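# c3pco2

Reconstruction of atmospheric pCO₂ across a negative carbon isotope
excursion (CIE) from the carbon-isotope fractionation of C₃ land plants,
built for the Permian–Triassic mass extinction interval (~252 Ma) but
usable for any hyperthermal with paired terrestrial plant δ¹³C, marine
carbonate δ¹³C and sea-surface temperature records.

It is aimed at stable-isotope geochemists and palaeoclimatologists who
want a tested, end-to-end implementation of the proxy chain — from
scattered multi-section isotope measurements to a pCO₂ curve with a
Monte Carlo 68% confidence band — plus the carbon-isotope mass-balance
scenarios used to identify the carbon source of the excursion.

## The proxy

Photosynthetic carbon isotope fractionation in C₃ plants increases
hyperbolically with CO₂:

    Δ¹³C = A·B·(pCO₂ + C) / (A + B·(pCO₂ + C)),   C = A·4.4 / ((A − 4.4)·B)

with A = 28.26 ± 0 ‰, B = 0.22 ± 0.028, so Δ¹³C(0) = 4.4 ‰ (diffusive
floor) and Δ¹³C → A at high CO₂.  Δ¹³C is measured from fossil plant
tissue and the coeval atmosphere,

    Δ¹³C = (δ¹³C_CO₂ − δ¹³C_p) / (1 + δ¹³C_p/1000),

where δ¹³C_CO₂ comes from marine carbonate via δ¹³C_DIC = δ¹³C_carb − 1 ‰
and a temperature-dependent DIC–CO₂ fractionation.  To cancel
diagenetic/preparation offsets the proxy inverts the *relative* change
Δ(Δ¹³C) = Δ¹³C(t) − Δ¹³C(t=0) against a pre-event reference with known
pCO₂(t=0) = 425 ± 68 ppmv (stomatal estimate).  The closed-form
rearrangement gives pCO₂(t); draws demanding fractionation at or beyond
the asymptote A are flagged invalid and excluded, as are reconstructed
values outside (0, 10⁶] ppmv.  Uncertainties propagate by Monte Carlo
(10,000 Gaussian draws of every input), summarised per 0.002 Myr
gridstep by the median and 16th/84th percentiles.

Supporting analyses: LOESS stacking (tricube, degree 1, cross-validated
span) of multi-section records onto the regular age grid; CIE-magnitude
statistics across substrates (Kruskal–Wallis, exact Wilcoxon rank-sum);
the single-box mass balance M_added = −CIE·M_background /
(δ¹³C_peak − δ¹³C_added) with 1 Gt C = 0.3 ppmv; Earth system
sensitivity ESS = ΔT / log₂(pCO₂_peak / pCO₂_background).

Because the real compiled records are not shipped, the package includes
a first-class synthetic-record generator with a known true history
(piecewise-linear four-stage CIE: −3.5 ‰ in carbonate, pCO₂ 425 → 2507
ppmv in 75 kyr, +10 °C SST) whose plant δ¹³C is forward-modelled through
the same equations — so every stage of the pipeline is testable against
truth.

## Worked example

```bash
c3pco2 all --seed 1 --out c3pco2_out
cat c3pco2_out/metrics.json
```

generates a synthetic four-plant-section / ten-carbonate-section /
five-SST-section dataset under the default conditions, stacks it,
reconstructs pCO₂ and prints:

```json
{
  "delta_t_degc": 10.626195832726602,
  "ess_degc_per_doubling": 4.387134615879046,
  "pco2_background_ppmv": 423.579426068643,
  "pco2_peak_ppmv": 2270.218422882403,
  "pco2_ratio": 5.35960503075639,
  "pco2_rise_ppmv": 1846.63899681376,
  "correlation": {"computable": true, "r": 0.9724, "p": 1.6e-157, "n": 248}
}
```

The background median recovers the 425 ppmv truth almost exactly; the
peak median (2270 ppmv vs. a true 2507 ppmv) sits a few percent low
because the asymptote-exclusion rule trims only the upper tail of the
draws — an intrinsic property of the method, discussed in
`docs/methods.md`.  The strong pCO₂–SST correlation reflects the
co-timed ramps in the generated truth.  `c3pco2_out/mass_balance.csv`
classifies each carbon-source scenario against the reconstruction's 68%
rise band (volcanic CO₂ alone overshoots it; organic matter and methane
scenarios fall within).

Library use mirrors the CLI: `generate_dataset()`, `fit_stack()`,
`mc_reconstruct()`, `scenario_table()` etc.; see the module docstrings.

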