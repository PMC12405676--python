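# Methods

## One-pool radiocarbon model and normalization

The soil carbon pool is assumed at steady state with constant inputs whose
¹⁴C signature tracks the atmosphere. At annual steps,

    F_SOC(j) = F_atm(j)·k + F_SOC(j−1)·(1 − k − λ),

with decomposition rate `k` (turnover time 1/k) and radiocarbon decay
constant λ = ln 2/5730 yr⁻¹. The recursion runs from −53 000 (the practical
limit of the radiocarbon method) to the sampling year and is initialized at
the equilibrium value `F_atm(start)·k/(k + λ)` for the earliest atmospheric
level rather than at zero: 53 kyr of spin-up would not equilibrate a 50 kyr
pool from zero, and the closed form removes that bias exactly (under
constant forcing the simulated value matches `c·k/(k+λ)` to ~1e−14).

Turnover times are restricted to [1, 50 000] yr. At 1 yr the update factor
`1 − k − λ` is slightly negative; the recursion still contracts (it requires
only `k + λ < 2`) and converges to the same fixed point, so the 1-yr fast
end of the grid is admitted. Turnovers below 1 yr are rejected.

The turnover lookup uses 600 log-spaced grid points on [1, 50 000] yr,
enough that piecewise-linear interpolation error (linear in log turnover) is
far below measurement precision (~1e−4 in fraction modern near the bomb
region). Lookups are cached per (forcing curve, year).

Normalization to the reference year (2000): a measurement's turnover time is
inferred by inverting the lookup at the sampling year, then the modeled
value for that turnover is read at 2000. Because the bomb spike makes the
fast end non-monotone, a post-bomb measurement can match two turnovers; the
**largest** turnover is returned with an `ambiguous` flag — the conservative
(older) choice, which biases against rejuvenation claims while keeping the
decision auditable. Measurements at or below 0.16 fraction modern (inferred
turnover beyond ~48 kyr for any sampling year) are left unnormalized but
flagged, and still enter the mixing regression as raw values; the cutoff is
applied to the raw measurement. Values below the slowest grid point saturate
at 50 kyr (`saturated`); values above the modeled maximum are flagged
`super_modern`.

Forcing curves are spliced from a pre-bomb record reaching −53 kyr and a
post-bomb zonal record, with the post-bomb record taking precedence from its
first year (bomb-era points are direct atmospheric measurements), linear
interpolation to integer years, and hold-last-value extension beyond the
last datum (configurable to a linear extrapolation of the final decade's
trend) so that sampling years slightly beyond curve coverage do not abort a
run. Hemispheric zones are assigned at ±15° latitude by default,
approximating the published zonal compilations; both boundaries are
configurable since the underlying zonation choice is not uniquely
determined.

## Mixing regression

Per profile, ordinary least squares of `Y = SOC·F¹⁴C` on `X = SOC` (layers
as observations, no weights). The slope is the active pool's fraction
modern; aOC = −intercept/slope. The standard deviation of aOC is obtained
by the first-order delta method through −b/m, **including** the
slope–intercept covariance from the regression — X values sit far from
zero, so the covariance term is material. R² is taken from this (X, Y)
regression. Negative aOC estimates are physically meaningless, recorded
pre-clamp, and set to zero; clamped profiles stay in downstream summaries
with zero ratios. The magnitude of the median of the negative estimates
across a dataset defines the limit of quantification (LOQ), used only as a
reporting flag (`below_loq`), never as a filter. A profile is accepted when
R² > 0.9 and the maximum layer ratio aOC/SOC is < 1 (a single layer at or
above 1 is impossible under the model). Non-positive slopes mark the fit
invalid: the active pool must carry ¹⁴C.

Profile selection before fitting: layers with SOC ≥ 120 mg/g are treated as
organic (not mineral soil) and dropped — the bound is read strictly — and a
profile is retained only if at least 4 surviving layers span at least
50 cm, the span being measured over the surviving layers. Layers reported
as Δ¹⁴C are converted with the standard convention
`F = (Δ/1000 + 1)·exp((year − 1950)/8267)` using the sampling year as the
measurement year (configurable, since reporting-year metadata is often
absent from database exports).

## Loess correction

Loess profiles carry a third pool: glacial-age biospheric carbon of known
concentration `C_g` and age (typically 15–25 kyr) from nearby paleoclimate
records. Its fraction modern is `F_g = exp(−age·ln2/5730)` and it is
removed by mass balance per layer,

    SOC′ = SOC − C_g,   F′ = (SOC·F − C_g·F_g)/SOC′,

before the standard binary fit. `C_g` and the age are per-profile
configuration inputs, not estimated, and the pool is taken constant with
depth, mirroring the constancy assumption for aOC. The identity
`SOC·F = SOC′·F′ + C_g·F_g` holds to ~1e−14 by construction and is enforced
by tests.

## Ages, bins, stocks

Raw mean age: `−(5730/ln 2)·ln F¹⁴C`. The cycling carbon's signature is
`F/(1 − aOC/SOC)`; its age can be negative (super-modern, bomb-influenced)
and negatives are retained in summaries — truncating them would bias
corrected topsoil means upward. Layers are assigned to topsoil [0, 30),
subsoil [30, 100) and deepsoil [100, ∞) cm by layer **midpoint** (a
deterministic, symmetric rule for straddling layers); summary means and SDs
are unweighted across layers (thickness weighting would be an alternative
but SD dispersion at layer level is the quantity reported), and only
accepted profiles contribute. First-meter summaries pool layers with
midpoints shallower than 100 cm. Global aOC stocks multiply published SOC stocks
(defaults 704 Gt topsoil, 801 Gt subsoil, 910 Gt for 1–2 m) by the bin mean
ratios, rounded to integer Gt for reporting.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes:
per-profile constant aOC with F¹⁴C = 0, an active pool following the
one-pool model under a synthetic atmosphere, SOC declining with depth, and
Gaussian measurement noise on the composite fraction modern (noise enters
where real measurement error does — at the measured mixture, not at the
pool end-members). Defaults:

| parameter | default | rationale |
|---|---|---|
| aOC | uniform 0–5 mg/g | population mean ~2.5 mg/g, matching the concentration scale of global mineral-soil compilations |
| surface SOC | uniform 20–80 mg/g | mineral soils, below the 120 mg/g organic limit |
| SOC depth decline | e-folding 40 cm toward a 6 mg/g deep asymptote | keeps deep layers carbon-bearing so layer ratios stay < 1 |
| active-pool turnover | 50 yr (surface) → 5 kyr (2 m), log-linear in depth | mimics observed depth–age gradients |
| layer grid | 0–200 cm in 7 layers | typical pedon sampling |
| sampling years | 1990–2015 | database-era sampling |
| F¹⁴C noise SD | 0.02 | generous relative to AMS precision, stresses the fit |
| atmosphere | plateau 1.0, linear rise 1955→1964 to 1.8, e-folding 16 yr | bomb-spike shape and magnitude of the tropospheric record |

Setting `turnover_deep_yr == turnover_surface_yr` produces a single active
end-member per dataset — the regime where the mixing model is exactly
specified. Recovery tests use it: noise-free fits must recover true aOC to
1e−8 with R² = 1, and with 0.02 noise the median bias over 200 profiles
stays within the ±0.11 mg/g LOQ scale. The depth-increasing default
deliberately violates the single-end-member assumption the way real
profiles do; the R² screen then does real work. The flat-atmosphere option
(`atm_peak_f14c == atm_plateau`) makes normalization the identity, which the
exact-recovery tests exploit to isolate the regression from interpolation
error. A `loess_fraction` adds a glacial pool (default 2 mg/g, 18 kyr) to
that fraction of profiles.

What the generator does **not** emulate: covariances between soil group and
aOC (group labels are arbitrary tags for exercising the group-by
machinery), spatial structure, depth-varying aOC, non-steady-state inputs,
or realistic pre-bomb atmospheric variability. Passing recovery tests
therefore demonstrates correctness of the estimator under its own
assumptions, not the validity of those assumptions for field data.

## Numerical choices and limitations

- Equilibrium initialization and the 600-point log grid keep combined
  model/interpolation error ≲ 1e−4 fraction modern, well under measurement
  error.
- Inversion tie-break: largest turnover, flagged; saturation at 50 kyr.
- Degenerate fits (all SOC equal) raise; the pipeline records and skips
  them.
- Acceptance-script and test problem sizes (50 noise-free / 200 noisy
  profiles, 10 loess profiles, 10⁴ age-grid pairs, 500 mass-balance draws)
  were chosen to make sampling error negligible relative to the tolerances
  while keeping runs quick.
- The mixing model assumes one active end-member per profile; profiles with
  strong depth gradients in active-pool age violate it and are (correctly)
  rejected by the R² screen rather than corrected.
- No multi-pool unmixing beyond the loess three-source case; surficial and
  sedimentary deposits with mixed carbon sources would need a more complex
  model and site-specific end-member data.
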