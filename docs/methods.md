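# Methods

This note documents the model, the numerical choices, and the synthetic
study conditions the package uses, including the places where the design
was genuinely open and a choice had to be made.

## Microclimate reconstruction

A year is exactly 24 × 365 hours (no leap day), indexed in local solar time
(solar noon at hour 12); sites are modelled independently, so no longitude
or time-zone correction is applied.

**Monthly to daily.** Daily mean temperature interpolates linearly between
month midpoints (day 15 of each month, December wrapping to January);
Tmin/Tmax sit half a diurnal range below/above the mean. Calendar-month
averages of a piecewise-linear interpolant through midpoints deviate from
the knot values in proportion to the seasonal curvature — about
0.04 °C per °C of seasonal half-amplitude — which bounds the fidelity of
the reconstruction (≈0.26 °C at the default 7 °C half-amplitude).

**Diurnal cycle.** Daytime follows a lagged sine, Ta = Tmin +
(Tmax − Tmin)·sin(π(h − h_sr)/(DL + 2p)) with lag p = 1.5 h, so the peak
falls mid-afternoon; night cools exponentially (shape b = 2.5) from the
sunset value, normalised to reach Tmin exactly at the next sunrise so the
curve is continuous. This family of day/night interpolants has a known cool
bias in its daily mean (5–10% of the diurnal range, worse for short days);
`build_hourly_environment` therefore re-centres each day's 24 values by a
constant so the daily mean equals the interpolated target. The shift
preserves continuity, 24-h periodicity under constant forcing, and the
exact property that adding c to every monthly mean adds exactly c to every
hourly air temperature.

**Solar.** Declination δ = 23.45°·sin(2π(284 + doy)/365); sunrise from the
hour-angle formula with polar-day/night clamps (0 h and 12 h). Clear-sky
irradiance uses Beer-law beam attenuation, S₀ = 1361 W m⁻², broadband
transmittance τ = 0.70, optical air mass scaled by barometric pressure
(scale height 8200 m), plus a diffuse term restoring 30% of the beam loss.
Clouds are out of scope — the model is clear-sky by construction, which
overstates absolute radiative load but cancels in current-vs-future
comparisons because both scenarios share the same radiation.

**Longwave closure.** Effective sky temperature from a clear-sky
atmospheric emissivity ε_a = 0.72 + 0.005·Ta (clamped to (0, 1]);
substrate temperature = Ta + solar/50, i.e. a bare-ground excess of +20 °C
at 1000 W m⁻². Both coefficients are module constants. Wind is constant
(default 1.0 m s⁻¹); there is no soil heat diffusion, humidity, shade
mosaic or snow.

## Operative temperature

Te is the steady-state equilibrium temperature of a dead (behaviour-free)
animal: no shade-seeking, no retreat, no metabolic or evaporative terms,
no thermal inertia. The cylinder has volume m/ρ (default density
1000 kg m⁻³) and length:diameter ratio k = 10, giving
r = (V/(2kπ))^(1/3). End caps are ignored (<5% of area at k = 10). The
silhouette receiving direct solar is diameter × length, the sun assumed
normal to the body axis — an upper-bound posture. Half the lateral area
exchanges longwave with the sky, half with the substrate; ground conduction
is folded into the substrate longwave term because posture and contact
fraction are unknowable at this grain. Convection uses Nu = 0.615·Re^0.466
with ν = 1.5 × 10⁻⁵ m² s⁻¹ and k_air = 0.026 W m⁻¹ K⁻¹, floored at
h = 5 W m⁻² K⁻¹ for still air.

f(Te) is strictly decreasing (quartic emission plus linear convection, all
positive coefficients), so the root is unique. Bisection runs on
[Ta − 50, Ta + 100] °C — property-tested to bracket a sign change across
extreme environments — and stops when the worst energy residual across the
whole vectorized batch is below 10⁻⁶ W. A 0.001 °C brute-force grid scan
serves as an independent oracle in the tests (agreement within 0.01 °C).

Because the longwave/conduction closure is deliberately simple, absolute
Te values are not comparable to a full soil–atmosphere microclimate model;
every scientific claim the package makes is therefore relative
(current vs. future at the same site) or property-based (monotonicity,
energy conservation), never a match of absolute restriction hours.

## Restriction hours and comparisons

h_r counts hours with Te strictly above VTmax; ties count as available
time. Counting runs over all 24 h of all 365 days. Δh_r = future − current;
percent change is reported as missing (with a warning) when the current
h_r is zero rather than as infinity.

## Statistics

* Percentile summaries (median, 5th, 95th) use linear interpolation
  between order statistics.
* The Mann–Whitney test computes U from midranks; p is exact by full
  enumeration of all C(n₁+n₂, n₁) labelings when n₁+n₂ ≤ 16 and the pooled
  sample is tie-free, otherwise a tie-corrected normal approximation with
  continuity correction. The paired structure of current/future sites is
  deliberately ignored (an unpaired test is the convention this analysis
  follows).
* The spatial model is OLS of site-level Δh_r on latitude (°N) and
  elevation (m) with intercept; standard errors from the residual variance
  and (X'X)⁻¹, two-sided p from the t distribution with n − 3 df evaluated
  through the regularized incomplete beta function.
* Pooling: within one SSP analogue the three GCM analogues are pooled
  (stacked) for medians and rank-sum tests; the regression instead uses
  each site's mean Δh_r across the SSP's GCMs, one row per site per SSP.
  Both rules are echoed in the run manifest.

## Synthetic study conditions

The generator emulates a temperate-grassland viper study without external
data. Defaults (all overridable in `SyntheticConfig`):

| parameter | default | meaning |
|---|---|---|
| n_sites | 50 | occurrence grid cells |
| latitude_range | 36–50 °N | southern Balkans to central Europe |
| elevation_range | 0–1500 m | lowland steppe to subalpine grassland |
| sea_level_july_mean | 28 °C | July mean at (lat_min, 0 m) |
| seasonal_amplitude | 7 °C | half the annual range (14 °C peak-to-peak) |
| diurnal_range | 8 °C | constant across months |
| lapse_rate | −6.5 °C km⁻¹ | standard environmental lapse rate |
| lat_gradient | −0.35 °C °⁻¹ | summer-weighted meridional gradient |
| base warming | 1.5/1.8/2.1 and 3.9/4.4/4.9 °C | 3 GCM analogues per SSP analogue, end-of-century |
| warming_elev_coeff | 1.2 °C km⁻¹ | elevation-dependent warming amplification |
| warming_lat_coeff | 0.08 °C °⁻¹ | latitude amplification |
| noise_sd | 0.3 °C | site-level scatter on scenario offsets |
| seed | 20250623 | drives every random draw |

Monthly means follow July + amplitude·(cos(2π(m−7)/12) − 1) plus the
elevation and latitude terms, so July is the warm peak and equals the named
parameter at the envelope origin. Warming offsets are monthly-constant per
scenario, with one Gaussian noise draw per site × scenario applied on top
of the linear elevation/latitude structure; noise sits on the offsets, not
on the current climate, so current and future share each site's baseline
(delta-method logic). All realized coefficients are stored in a
`SyntheticTruth` sidecar sufficient to predict every noiseless offset
exactly, which is what the parameter-recovery tests exercise.

Taxa (default 5; VTmax uniform in 29.5–34.5 °C, mass 40–120 g) are
assigned to sites by climate matching: sites ranked by current July mean
are split into equal bands and the lowest-VTmax taxon occupies the coldest
band. This encodes local thermal adaptation — cool-adapted taxa live high
and north — and it is load-bearing: with random assignment the baseline
lapse-rate gradient dominates the response and the fitted elevation effect
on Δh_r turns *negative*, because cold high sites never approach their
(too-high) thresholds. With adaptation, every population sits at a
comparable thermal safety margin and the spatial pattern of Δh_r is driven
by the configured warming amplification, reproducing the qualitative
finding that elevation and latitude both positively influence restriction
change.

What the generator does **not** emulate: spatial autocorrelation,
precipitation/humidity, seasonal structure in warming, multi-taxon cells,
real GCM spread. Passing tests therefore demonstrate internal correctness
and recoverability of known gradients, not predictive skill on real
landscapes.

## Problem sizes

The test suite and acceptance script run the full pipeline at up to
200 sites × 7 scenarios (≈12.3 million hourly energy-balance solves),
which the vectorized bisection completes in well under a minute on one
CPU; the Monte-Carlo calibration of the regression uses 200 replicates of
300 sites. These sizes were chosen so that every stochastic check has
comfortable statistical power while the whole suite stays quick enough to
run habitually.

## Known limitations

* Absolute h_r values depend strongly on the simple longwave/substrate
  closure and the clear-sky assumption; use relative changes.
* The operative temperature ignores thermal inertia; for 40–120 g animals
  the hourly time step makes this mild, but sub-hourly extremes are
  invisible.
* Percent changes computed on sites with tiny current h_r are unstable;
  the cross-taxa medians reported in the headline are the robust summary.
* The CSV reader assumes complete 12-month records; raster ingestion is
  not provided.
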