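# tepflux

Analysis pipeline for **dust-seeding minicosm experiments**: the
quantitative chain linking transparent exopolymer particle (TEP) size
spectra, sediment-trap elemental mass budgets, and the lithogenic-ballast
regression that relates organic-carbon export to dust flux.

When Saharan dust settles onto seawater it triggers the abiotic assembly
of TEP — sticky gel particles of acidic polysaccharides — which glue
mineral grains into fast-sinking organic-mineral aggregates. The
particulate organic carbon (POC) exported this way is proportional to the
lithogenic (dust) flux, and the proportionality can be used to estimate
the carbon export induced by real deposition events. `tepflux` is for
marine biogeochemists who run (or simulate) such tank experiments and
need the full chain from raw count/composition tables to event-scale
extrapolations, with every step unit-checked and testable against
synthetic data.

## What it computes

**TEP size spectra** (`tepflux.size_spectrum`). Counts per mL in 15
logarithmic diameter classes (1–135 µm) are normalised by class width and
fitted with a power law

&nbsp;&nbsp;&nbsp;&nbsp;dN/d(dp) = k · dp^δ

by ordinary least squares in log–log space over the positive-count
classes. The spectral slope δ (more negative = relatively more small
particles), the abundance-weighted average diameter
D_av = Σ N(dp_i)·dp_i / Σ N(dp_i), the spherical-equivalent volume
concentration C_v = Σ (π/6)·dp_i³·N(dp_i)·10⁻⁶ (ppm), and total abundance
with a conservative 20 % counting-error SD are reported per sample.

**Trap mass budgets** (`tepflux.trap_budget`). From the dry-mass
percentages of total carbon, calcium and aluminium: %PIC = %Ca × 12/40
(all Ca assumed calcite), %POC = %TC − %PIC, POC stocks and fluxes from
the tank geometry (0.36 m², 6 days by default), and — using Al as a dust
proxy (Al = 4.12 ± 0.39 % of the dust analog) — the percentage of added
dust recovered and the lithogenic flux.

**Ballast regression** (`tepflux.ballast`). The zero-intercept
least-squares fit F_POClitho = a · F_litho across minicosms (slope
a = Σxy/Σx², centered r², one-parameter t-test p-value), plus event- and
annual-scale extrapolations of the fitted slope.

**Synthetic data** (`tepflux.synthetic`). Seed-deterministic generators
for power-law count tables (exact class-integral allocation, multinomial
sampling, lognormal counting error), declining post-seeding time series,
and trap compositions built by mixing dust analog with organic matter —
so the whole chain is testable without unpublished raw data.

## Worked example

Simulate a post-seeding TEP time series and compute its spectra:

```bash
tepflux simulate timeseries --seed 7 --out counts.csv
tepflux spectrum --counts counts.csv --out spectrum.csv
```

```
sample_id  abundance     sd  delta       k  n_bins_used  d_av_um  cv_ppm
       T1    14020.0 2804.0  -2.00 14665.0           15     5.07   67.90
       T6    14933.0 2987.0  -2.46 23165.0           15     2.98   14.91
      T12    10002.0 2000.0  -2.54 15441.0           15     2.65    7.68
      T24    12558.0 2512.0  -2.72 21396.0           15     2.31    6.00
      T48     9230.0 1846.0  -2.80 14813.0           14     2.11    3.30
      T72     6635.0 1327.0  -2.90 12077.0           14     2.07    1.32
      T96     6181.0 1236.0  -3.02 12335.0           13     1.96    0.49
     T144     3548.0  710.0  -3.01  6303.0           13     1.89    0.27
```

Abundance peaks just after seeding (~14,000 # mL⁻¹ ± the 20 % counting
SD) and decays; δ drifts from −2.0 toward −3.0 and the mean diameter
shrinks from ~5 µm to ~1.9 µm as large aggregates settle out — the
signature of ballast-driven export.

Budgets and the ballast fit for the six packaged minicosm trap samples:

```bash
tepflux budget --trap traps.csv --out budget.csv
tepflux ballast --fluxes budget.csv --predict-dust 22 --total-poc 0.8 --out ballast.json
```

```
     label  poc_stock_mg  poc_flux_total  poc_flux_daily  dust_exported_percent  litho_flux_total
CHIPIE1-NA          13.8            38.3             6.4                   31.0            3101.4
 CHIPIE1-A          13.9            38.6             6.4                   31.6            3155.3
CHIPIE2-NA          32.4            90.0            15.0                   73.1            7308.5
 CHIPIE2-A          31.3            86.9            14.5                   73.6            7362.5
CHIPIE3-NA          24.3            67.5            11.2                   54.7            5467.9
 CHIPIE3-A          29.4            81.7            13.6                   61.9            6189.3

slope=0.01235 r2=0.9843 p=2.74e-08 (n=6)
```

Each mg of settling dust drags ~0.012 mg of organic carbon with it. For
a 22 g m⁻² extreme deposition event the fit predicts 0.27 g m⁻² of
ballast-driven POC export — 34 % of the 0.8 g m⁻² total export observed
after such an event, but only ~6 % of a typical annual carbon export
(2.4 g m⁻² yr⁻¹) at an average dust load of 11.4 g m⁻² yr⁻¹.

`tepflux reproduce` recomputes every published derived cell of the
packaged minicosm dataset and exits non-zero on any mismatch beyond the
printed rounding.

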