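# Methods

## Model

The core model is the hyperbolic dependence of C₃-plant photosynthetic
fractionation on CO₂,

    Δ¹³C(pCO₂) = A·B·(pCO₂ + C) / (A + B·(pCO₂ + C)),

with C = A·4.4/((A − 4.4)·B) so that Δ¹³C(0) = 4.4 ‰ (the diffusive
floor) and Δ¹³C → A (the saturation fractionation) as pCO₂ → ∞.  The
proxy never uses absolute Δ¹³C: diagenesis and sample preparation shift
plant δ¹³C by quasi-constant offsets, so the inverted quantity is the
relative change Δ(Δ¹³C) between the time of interest and a pre-event
reference whose pCO₂ is known independently.  Solving
Δ¹³C(p) − Δ¹³C(p₀) = Δ(Δ¹³C) for p gives a rational expression whose
denominator, A²B − ddc·A·B − ddc·B²·p₀ − ddc·B²·C, vanishes as the
demanded fractionation reaches the asymptote; such draws carry no
information about pCO₂ and are flagged invalid rather than raised, so
the Monte Carlo layer can count and drop them.

Atmospheric δ¹³C_CO₂ is derived from marine carbonate: δ¹³C_DIC =
δ¹³C_carb − 1 ‰ (temperature-independent), then a temperature-dependent
DIC–CO₂ fractionation of 0.91·(−0.1141·T + 10.78) + 0.08·(−0.052·T +
7.22) ‰ — an abundance-weighted bicarbonate/carbonate-ion mix equal to
10.3874 ‰ at 0 °C and shrinking by 0.10799 ‰ per °C.  All δ values are
‰ VPDB floats everywhere; no fraction/per-mil dual representation
exists anywhere in the code.

### Key parameters

| parameter | default | units | why |
|---|---|---|---|
| A | 28.26 ± 0 | ‰ | saturation fractionation of the curve fit |
| B | 0.22 ± 0.028 | ‰ per ppmv (scaled) | curvature of the fit; dominant systematic |
| pCO₂(t=0) | 425 ± 68 | ppmv | stomatal pre-event baseline |
| δ¹³C_p(t=0) | −24.42 ± 0.5 | ‰ | measured pre-event plant baseline (used in `plant_ref='params'` mode); ±0.5 treated as 1σ |
| DIC–carbonate offset | 1.0 | ‰ | constant, temperature independent |
| grid step | 0.002 | Myr | stacking resolution |
| n_draws | 10,000 | — | Monte Carlo sample size |
| validity bounds | (0, 10⁶] | ppmv | exclusion window for reconstructed values |
| Gt→ppmv | 0.3 | ppmv per Gt C | Earth-system conversion for the mass balance |

A's uncertainty is exactly zero but A is still sampled (with zero
variance) for uniformity of the propagation code.

## Reference anchoring

A self-contained record must anchor its own baseline, so by default the
reference state (plant δ¹³C, carbonate δ¹³C, SST at t=0) is read off
the three stacked curves at the oldest gridpoint covered by all three,
and sampled once per draw from Gaussian(center, se).  An interior
reference age can be supplied, but points close to the excursion onset
are contaminated by the smoother's window overlapping the ramp, which
systematically inflates the reference fractionation and collapses the
reconstructed peak; the old-edge anchor avoids that at the price of a
one-sided (higher-variance) local fit.  Alternatively
`plant_ref='params'` uses a fixed, externally measured plant baseline
(−24.42 ± 0.5 ‰).  The closed-loop recovery property holds in 'stack'
mode: with noise-free inputs and zero parameter variances the
reconstruction returns the true pCO₂ to machine precision.

Note the absolute forward chain is offset relative to measured plant
values: chaining the default background state (carbonate +2.2 ‰, SST
25 °C, 425 ppmv) predicts plant δ¹³C ≈ −27.8 ‰, not the measured
−24.42 ‰.  This is expected — the equations are calibrated for relative
changes, which is exactly why the proxy differences out the reference —
and is why 'stack' anchoring is the default for synthetic closed loops.

## Monte Carlo propagation

All inputs are Gaussian.  Systematic parameters (A, B, pCO₂(t=0), the
reference state) are drawn once per draw and shared across all
gridsteps; the stacked δ¹³C_p, δ¹³C_carb and SST values are drawn
independently per gridstep from their LOESS center ± standard error
(measurement-level error).  A flag (`shared_params=False`) redraws
everything per gridstep instead.  Draws are excluded when the inversion
denominator is ≤ 0 or the result leaves (0, 10⁶] ppmv; survivors are
summarised by the median and the 16th/84th percentiles using linear
interpolation between order statistics (type 7) — stated because
percentile conventions differ across ecosystems.  The positive error is
p84 − median, the negative error median − p16.  One master seed feeds a
single `numpy` Generator; reruns are bit-identical.

A consequence worth knowing: the excluded draws are always in the
*upper* tail (toward the asymptote), so near the peak the reported
median sits a few percent below the value a noise-free inversion gives
(~6% under the default uncertainties).  This is a property of the
exclusion rule itself, not of this implementation.  Uncertainty is
strongly right-skewed at high pCO₂ — the hyperbola flattens, so a fixed
fractionation error maps to an ever larger CO₂ interval upward.

## LOESS stacking

Classical LOESS: degree-1 local polynomial, tricube kernel over the
span-nearest neighbours, evaluated at each gridpoint of a regular
0.002 Myr age grid (integer-indexed from the old end, half-open at the
young end, so float step error never changes the point count; ages are
Ma before present, decreasing toward younger).  The standard error of
the fitted value is σ̂·‖l‖₂ with l the equivalent kernel of the local
intercept and σ̂² the tricube-weighted local residual variance; on
constant truth this reproduces the familiar σ/√n_local behaviour.  The
"central value" of a gridstep is the LOESS fitted value (the
local-regression point estimate); a per-bin density mode was considered
as an alternative reading and rejected as less stable at these sample
densities.  No extrapolation: gridpoints outside the data span are
missing, never filled.

The span is chosen by 5-fold cross-validation over a log-spaced
candidate grid whose floor adapts to the sample count
(geomspace(max(4/n, 0.01), 1) with 10 points).  A fixed floor of 0.1
was tried first and rejected: on clean, densely sampled records the CV
error is still strictly decreasing at span 0.1, and the forced
over-smoothing leaves up to ~0.9 ‰ error at the stage corners of a
kinked signal — which the pCO₂ inversion amplifies by ~90 ppmv/‰ near
background and ~2000 ppmv/‰ near the peak.  Letting CV reach
near-interpolation spans removes that failure mode while noisy data
still select moderate spans.  Robustness refits (random 80% subsamples;
leave-one-section-out) reuse the full-fit span; refits left with fewer
than 10 samples are skipped and logged.

The implementation is cross-checked in the tests against
`statsmodels`' lowess (identical centers to ~1e−15 at equal span);
standard errors are computed here because no installed smoother exposes
fixed-span local-fit standard errors.

## Synthetic records

The generator emulates the study layout: four terrestrial plant
sections (mixed cuticle/wood substrates), ten marine carbonate
sections, five SST localities, ~40 unevenly spaced samples each over a
0.5 Myr window.  The true history is piecewise linear in time through
four stages — pre-CIE plateau (carbonate +2.2 ‰, 425 ppmv, 25 °C), a
75 kyr onset ramp to the peak state (−1.3 ‰, 2507 ppmv, 35 °C), an
excursion body holding the peak (with an optional transient dip to
1300 ppmv, off by default), and a linear recovery (to +0.5 ‰, 700 ppmv,
30 °C).  Plant δ¹³C is never free: it is forward-modelled from the
truth through the proxy equations, which automatically amplifies the
−3.5 ‰ carbonate CIE to ≈ −7 ‰ in plants as pCO₂ rises — the signature
the method exploits, and absent when pCO₂ is held flat.

Measurement noise is i.i.d. Gaussian per sample: 0.5 ‰ (plants), 0.3 ‰
(carbonate), 1.0 °C (SST).  The stated analytical precision of the
measurements is ±0.2 ‰; the defaults add geological scatter
(inter-sample heterogeneity) on top, which is why they exceed the
purely analytical figure.  The generator does **not** emulate
autocorrelated geological noise, hiatuses, facies effects, age-model
error, or any carbon-cycle dynamics (the injection is prescribed).
Consequently, passing tests demonstrate correctness of the estimator
chain under the model's own assumptions — not robustness to correlated
stratigraphic noise or dating error in real compilations.

## Calibration experiment

Band calibration is checked by simulation-based calibration: per
replicate the *true* systematics (B, background pCO₂, with the peak
scaled to preserve the fold change) are drawn from the same priors the
reconstruction samples, a full noisy dataset is generated and
re-analysed, and the fraction of gridsteps whose 68% band contains the
truth is recorded.  Over 20 replicates (2,000 draws each) the mean
coverage is ≈ 0.68.  Holding the true parameters fixed at the prior
means instead yields ~0.98 coverage — the band then carries systematic
uncertainty the truth never exercises — which is why the calibrated
design is the one tested.

## Numerical choices and degenerate inputs

- Stage tie-break: a sample exactly on a boundary age belongs to the
  older stage.  Boundaries outside the sampled span are legal and yield
  the degenerate all-pre/all-post labelings.
- CIE background is a trailing mean over the last 5 pre-CIE samples
  (window configurable); peak is the raw pointwise minimum over
  onset ∪ body.
- Rank-sum tests are two-sided, exact for groups of ≤ 20 (falling back
  to the tie-corrected normal approximation when ties make the exact
  null unavailable), Kruskal–Wallis across all substrate groups;
  degenerate groups are reported as not-testable, never raised.
- Local fits with a rank-deficient design (all selected ages equal)
  fall back to the weighted mean.
- Off-grid ages in interval queries snap to the nearest gridpoint with
  a warning; SSTs outside [−5, 60] °C warn but compute (sanity bounds,
  not physics).
- Headline masses are rounded to two significant figures (3,900 /
  12,000 Gt C); the band comparison uses the asymmetric 68% interval
  verbatim, no symmetric approximation.
- The pCO₂–SST correlation is Pearson on the per-gridstep Monte Carlo
  median against the SST stack center; a per-draw correlation
  distribution would be a straightforward extension but is not
  computed.

## Problem sizes

Default runs use a 250-step grid (252.30–251.80 Ma at 0.002 Myr),
~760 samples, and 10,000 Monte Carlo draws (seconds on one core).  The
calibration experiment uses 20 replicates at 2,000 draws, chosen as the
smallest design whose coverage estimate is stable to a few percent.

## Known limitations

- The reported median is biased low near the asymptote (see above);
  users comparing peak medians across parameter choices should prefer
  the sensitivity sweep, which holds the seed fixed.
- LOESS corner bias at abrupt stage transitions is irreducible at
  realistic sample densities; the noise-free closed-loop guarantee
  applies to the inversion chain, not to smoothing of kinked signals.
- The single-box mass balance ignores weathering/burial fluxes and
  assumes the background reservoir is the marine DIC pool; it brackets,
  rather than resolves, the source mixture.
- No Bayesian age-model uncertainty; section correlation is taken as
  given via the supplied stage boundaries.
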