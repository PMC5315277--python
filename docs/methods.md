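# Methods

This note documents the models, conventions and numerical choices behind
`tepflux`, and what the synthetic-data generators do and do not emulate.

## TEP number size distribution

Microscopy enumeration classifies TEP into `n_classes` logarithmic
diameter classes between `d_min` and `d_max` (defaults 15 classes,
1–135 µm, the standard grid for counting at x200/x400 magnification).
Boundaries follow a geometric progression with common ratio
`(d_max/d_min)^(1/n)`; endpoints are set exactly. The representative
diameter dp_i of a class is the **arithmetic mean** of its boundaries by
default — "mid-point" read literally — with the geometric mean available
via `midpoint_kind="geometric"` since logarithmic binning is often paired
with it. On the default grid the two conventions give numerically
indistinguishable slope fits (differences < 10⁻³ in δ).

The number size distribution is dN/d(dp) = N(dp_i)/width_i (# mL⁻¹ µm⁻¹),
and the power law dN/d(dp) = k·dp^δ is fitted by **unweighted ordinary
least squares in log10 space** over the classes with strictly positive
counts only; no pseudo-counts are added (log 0 is undefined and imputation
would bias the tail), and the number of classes used is reported as
`n_bins_used`. At least two positive classes are required; fewer raise an
error rather than return a degenerate fit. On count tables generated
exactly from a power law the fit recovers the generating exponent to
better than 10⁻⁹.

Summary statistics: abundance [TEP] = Σ N(dp_i); its SD is
`counting_error_fraction × abundance`, defaulting to the conservative
20 % end of the 3–20 % range quoted for the microscopy method, applied to
the **total** (a per-class application is possible by constructing
per-class samples, but totals are what the published SDs correspond to).
D_av is the abundance-weighted mean of midpoints; C_v sums spherical
volumes at the midpoint diameters, with 10⁻⁶ converting µm³ mL⁻¹ to ppm
(v/v). δ is carried at full precision internally; display rounding (one
decimal) is left to output formatting.

## Trap mass budgets

Assumptions, in order of load-bearing:

1. **All particulate Ca is CaCO₃**, so %PIC = %Ca × 12/40 and
   %POC = %TC − %PIC. If PIC exceeds TC the input is infeasible under
   this assumption and the budget raises instead of clamping — a negative
   organic fraction always indicates a data or assumption problem.
2. **All trap Al is dust-borne**, so lithogenic mass = Al mass / 0.0412
   (the dust analog is 4.12 ± 0.39 % Al). Dust recoveries above 100 % are
   tolerated up to the bound implied by the Al-fraction SD
   (≈ 110 %) with a warning; beyond that they raise.
3. When the total dry mass was not recorded it is inferred as
   `al_mass / al_percent × 100` — the only closure the %/mass pairs
   permit. Because the trap Al percentages (4.4–5.4 %) exceed the
   analog's 4.12 %, the Al-implied lithogenic mass exceeds this inferred
   dry mass for every published trap; the budget reports both and warns
   (plausibly calcite dissolution altering the composition in the trap)
   rather than reconciling them.

Fluxes: total = stock / area (0.36 m² default), daily = total / duration
(6 d default), mmol C = mg / 12.

Reproduction tolerances: the published derived cells are rounded (stocks
to 0.1 mg, fluxes to 0.1 or 10 mg m⁻², percentages to 0.1), so recomputed
cells are compared at 1 % relative tolerance. Two quantities need more
slack for rounding propagation, not model error: POC stocks re-derived
through the dry-mass inference inherit the ±0.05-in-1.5 rounding of the
published POC % (up to ~3 %, checked at 5 %), and mmol stocks are printed
to 0.1 of values near 1–2.7 (checked at 5 %).

## Ballast regression

The fit is y = a·x through the origin over per-minicosm daily flux pairs
(x = lithogenic, y = POC, mg m⁻² d⁻¹): a = Σxy/Σx², the exact
least-squares solution, cross-checked in tests against a refined grid
search and a generic no-intercept solver. Daily fluxes are the canonical
axis; since both axes share the time basis, slope and r² are identical
for event-integrated fluxes.

r² for a through-origin fit is convention-dependent. We report the
**centered** convention, 1 − RSS/Σ(y−ȳ)², which matches how the published
value for this regression was computed; the uncentered convention
(1 − RSS/Σy²) gives ≈ 0.999 here and is not comparable. On the six
packaged flux pairs the centered r² evaluates to 0.9843. The published
value, 0.985, was computed from unrounded stocks and Al masses that are
not available; rebuilt from the rounded published inputs the value lands
0.0007 lower, so comparisons are made to within one unit in the last
published digit (±0.001). The slope is insensitive to this (0.01235,
printing as 0.012).

The p-value is the two-sided t-test on the single regression parameter
with n−1 degrees of freedom (SE = √(RSS/(n−1)/Σx²)); with a perfect fit
(RSS = 0) it is reported as 0.

Extrapolations use the **unrounded** fitted slope: 0.01235 × 22 g m⁻²
gives 0.27 g m⁻² for an extreme event (the rounded 0.012 would give
0.26), which is 34 % of the 0.8 g m⁻² export measured after such an
event; at the annual scale (11.4 g m⁻² yr⁻¹ dust, 2.4 g m⁻² yr⁻¹ POC) the
ballast share is ~6 %. Two large in-situ mesocosm flux pairs serve as
out-of-sample validation: their observed POC_litho falls within 25 % of
the line's prediction (errors measured relative to the prediction, 24.9 %
and 12.9 %).

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
at the magnitudes the minicosm experiments exhibit; their defaults are
those study conditions, not tuning knobs.

**Counts.** Expected class shares are the exact integral of dp^δ over
each class — `(b₂^(δ+1) − b₁^(δ+1))/(δ+1)`, with the logarithmic
antiderivative at δ = −1 — so discretisation bias is excluded by
construction and recovery tests isolate estimator behaviour. Counts are
one multinomial draw of size `total_abundance` (post-seeding peaks are
~10⁴–1.4×10⁴ # mL⁻¹), multiplied by a single unit-mean lognormal factor
with CV = `counting_cv` (default 0.20). A single factor models the
enumeration error on the whole sample: it perturbs abundance and C_v but,
deliberately, not the fitted slope. The noise family (multinomial +
lognormal) is a modelling choice; only the 3–20 % error range is
empirically anchored.

**Known estimator bias.** With the positive-class OLS fit, steep spectra
at realistic abundances carry a positive (flattening) truncation bias:
at δ = −3.3 and 10⁴ total counts the far-tail classes have expected
counts ≪ 1, are usually empty (and excluded), and occasionally hold a
single count whose high leverage flattens the fit. Over 200 seeds the
mean fitted δ is ≈ −3.21 (bias ≈ +0.09, SD ≈ 0.11). The bias is
< 0.01 at δ ∈ {−1.7, −2.1} and shrinks below 0.02 at abundances ≳ 10⁵
for δ = −3.3. It is a property of the published fitting procedure at
those study conditions, not of the generator (it is identical for
integral vs midpoint generation and either midpoint convention), so we
document it rather than re-parameterise around it; the corresponding
recovery test records it as a known failure at the −3.3 condition.

**Time series.** Abundance follows `peak·exp(−decline_rate·t)` (default
peak 14,000 # mL⁻¹, rate 0.008 h⁻¹, giving ~4,400 at 144 h) on the
standard sampling schedule (1, 6, 12, 24, 48, 72, 96, 144 h); the
generating δ drifts linearly in **log-time** from −2.0 to −3.2, matching
how these experiments are presented and the observed shift toward small
particles. The generator does not model the transient aggregation bump
(a mid-run δ/diameter peak) seen in some runs.

**Traps.** A composition is built by mixing `dust_fraction_exported` of
the added dust (3.6 g; Al 4.12 %, calcite 30 %) with organic matter of
carbon content `organic_c_fraction` (default 0.5, a typical OC fraction
of marine organic matter) sized so POC/dry hits
`poc_to_dry_ratio_percent` (default 1.5 %, the observed saturating
value). The measured quantities (%TC, %Ca, %Al, Al mass) follow exactly
from stoichiometry; optional unit-mean lognormal noise at
`measurement_cv` is applied per quantity. With zero noise, running the
result through the budget recovers the generating dust fraction and POC
ratio to machine precision; there is no empirically anchored default for
`measurement_cv`, so noise is off unless requested.

What passing synthetic tests do **not** show: the generators contain no
aggregation/coagulation dynamics, no settling-velocity physics, no
carbonate-system chemistry and no biology; they validate the estimators
and budget algebra, not mechanistic claims about real seawater.

## Reproducibility and I/O

All generators take integer seeds (numpy `default_rng`) and are
bit-reproducible for a fixed seed and parameter set. Tabular I/O is
headed CSV; every output file starts with a comment line carrying a
SHA-256 hash of the full parameter set and the seed. The packaged
minicosm dataset ships as a small CSV of published measured inputs plus
published derived cells used only for verification. `tepflux reproduce`
recomputes all 41 derived quantities and fails loudly on any mismatch
beyond the rounding tolerances above. The test suite and the acceptance
script complete in a few seconds on one CPU; the heaviest checks are the
200-seed slope-recovery Monte Carlos.
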