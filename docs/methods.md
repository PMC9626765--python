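# Methods

## Problem setting

`grainrisk` implements the contaminant-risk workflow used in dietary
exposure surveys of staple grains from high-geological-background (karst)
terrain: per-sample fluorine (F) and cadmium (Cd) concentrations in rice,
corn and wheat grain are turned into (i) regulatory pollution indices and
grades, (ii) USEPA-style non-carcinogenic and carcinogenic risk
indicators for adult and child consumers, (iii) interpolated spatial
concentration surfaces, and (iv) correlation and population-comparison
statistics. The reference study region is the carbonate-rock area of
Guizhou province (roughly 103.5–109.5°E, 24.5–29.2°N), whose soils carry
naturally elevated F and Cd.

## Pollution index and category binning

The single-factor pollution index for Cd in a crop is

    Pi = Ci / Si

with `Ci` the crop's mean Cd concentration (mg/kg dry weight) and `Si`
the Chinese maximum level (GB 2762-2017: rice 0.2, corn 0.1, wheat
0.1 mg/kg). Grades: `Pi ≤ 0.7` excellent, `0.7 < Pi ≤ 1` safe,
`1 < Pi ≤ 2` slight pollution, `Pi > 2` pollution; every band is closed
on its upper cut.

Per-crop distribution tables bin Cd at the concentration equivalents of
the grade cuts — `(0.35, 0.7, 1, 2) × Si`, the excellent band split
equally in two — with right-closed intervals, and report the *observed*
min–max/median/mean inside each theoretical bin. A tiny relative nudge
(1e-12) on the cut values keeps a sample printed exactly at a cut in the
lower bin despite binary floating-point representation of `0.35·Si` and
`0.7·Si`. F has no current food limit, so its five categories are
equal-frequency (rank) quintiles: sort, slice at positions `⌊k·n/5⌋`,
sizes differ by at most one. Exceedance ratios use a strict `>` against
`Si`: a sample exactly at the maximum level is compliant.

## Exposure and risk model

Average daily intake for one grain and population:

    ADI = C · IR · EF · ED / (BW · AT)        [mg/(kg bw · d)]

with `C` the grain concentration, `IR` daily intake (kg/d), `EF`
exposure frequency (d/a), `ED` exposure duration (a), `BW` body weight
(kg) and `AT` the averaging time in days. Then

    THQ = ADI / RfD,   HI = Σ THQ,   R = SF · ADI

with oral reference doses `RfD` (Cd 0.001, F 0.06 mg/kg/d) and the Cd
carcinogenic slope factor `SF = 0.64 (mg/kg/d)⁻¹`. `THQ`/`HI` above 1
indicates potential non-carcinogenic concern; `R` is banded at `1e-6`
(negligible below) and `1e-4` (unacceptable above), the band between
being "cautionary" with both ends included.

Default population parameters: adults BW 59.10 kg, ED 70 a; children BW
24.90 kg, ED 9 a; EF 365 d/a; intakes (adult/child, kg/d) rice
0.389/0.198, corn 0.10/0.15, wheat 0.15/0.10.

**Averaging-time convention.** The default rule `ed_times_365` sets
`AT = ED × 365 d`, so with `EF = 365 d/a` the factor `EF·ED/AT` is 1 and
`ADI = C·IR/BW`. This is the convention under which the published
indicator values are mutually consistent for both risk types. USEPA
practice often uses a fixed 70-year averaging time for carcinogenic risk;
that is available as the config override `at_rule: lifetime_70y`, which
rescales ADI by `ED/70`.

All indicators are linear in concentration, so the risk evaluated at a
crop's mean concentration equals the mean of per-sample risks; both
entry points are provided. `R` is defined for Cd only — requesting it
for F raises an error rather than returning 0.

## Spatial interpolation

Surfaces are produced by inverse-distance weighting over the k nearest
samples: `ẑ(x) = Σ wᵢ zᵢ / Σ wᵢ`, `wᵢ = dᵢ⁻ᵖ`, with `d` the haversine
great-circle distance (the study area spans ~6° of longitude, so planar
degrees would distort east–west distances). Defaults `p = 2`, `k = 12`
follow common GIS desktop practice; both are exposed as CLI flags. A
query within 1 m of a sample returns that sample's value exactly (mean
over coincident ties), making the scheme an exact interpolator; every
prediction is a convex combination of sample values. Neighbour search
uses a ball tree on the sphere; the weighting itself is implemented here
and checked against a brute-force Σwz/Σw oracle in the tests.

Grids are node-centred regular lon/lat lattices (default 200×150 over
the study bounding box). ESRI ASCII grid export requires square cells,
so `GridSpec.square` takes the cell size from the longitude spacing and
grows the latitude extent to match; values are written north row first
at 6 significant digits, and a reader is provided for round-trip
verification. No masking to administrative boundaries is applied (no
boundary polygons are shipped).

## Statistics

Per crop, grain F is regressed on Cd by ordinary least squares; the
Pearson correlation's significance is the two-sided t-test
`t = r√((n−2)/(1−r²))` on `n−2` df. Adult-vs-child contrasts of
per-sample THQ/HI/R use the two-sided Mann–Whitney U test: exact (full
enumeration null) when the combined sample is ≤ 12 and tie-free,
otherwise the normal approximation with midrank tie correction and
continuity correction. Figure-style annotation: `*` for p < 0.05, `**`
for p < 0.01. No multiple-testing correction is applied, matching common
practice in this survey literature.

## Synthetic survey generator

The raw survey data are not publicly deposited, so the generator
produces sample sets that reproduce the *published* study conditions,
which are the packaged defaults:

| crop  | n   | F range (mg/kg) | Cd range (mg/kg) | target r | Cd exceedance |
|-------|-----|-----------------|------------------|----------|---------------|
| rice  | 113 | 0.825–5.193     | 0.000–0.463      | +0.3473  | 11.6 %        |
| corn  | 119 | 0.946–8.485     | 0.000–0.307      | −0.3003  | 13.5 %        |
| wheat | 102 | 0.271–9.143     | 0.012–0.537      | +0.3825  | 45.1 %        |

(The wheat count is printed both as 102 and 103 in the published
tables; 102 is used throughout.)

Mechanism: sampling sites are 65 % uniform over the bounding box and
35 % clustered at Gaussian hotspots whose placement follows the
published qualitative pattern (e.g. corn Cd in the east, corn F in the
west). Each element receives a latent score `z = h(x) + ε`, where `h` is
the centred kernel-sum hotspot field (amplitudes in noise-SD units) and
`ε` standard normal noise shared between elements through a correlation
`ρ`. Latent ranks are then mapped onto deterministic marginal quantile
curves (`lo + (hi−lo)·u^1.7`, right-skewed as concentration data
typically are), which pins the published range endpoints exactly and
places exactly `round(e·n)` Cd values strictly above `Si` (values up to
and including `Si` are compliant). Rice and corn Cd floors are exact
zeros, as published. Because the monotone rank map attenuates Pearson
correlation (strongly so for the kinked Cd marginal), `ρ` is not set to
the target directly: with all random draws fixed, the realized F–Cd
Pearson r is a monotone function of `ρ` and is inverted by bisection, so
each generated set hits its target r to ~1e-3. One seed drives
coordinates and concentrations through a single generator stream; equal
seeds give byte-identical CSV output.

What the generator does **not** emulate: true geostatistical covariance
(no variogram-specified random fields — kernel hotspots only), detection
limits and censoring, measurement error structure, or any real
spatial layout of the survey (hotspot placement is illustrative).
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its statistical machinery under survey-like marginals and
correlations, not agreement with the withheld field data. Because IDW is
an exact interpolator, a surface's maximum sits at the maximum-value
sample; with cluster scatter comparable to the hotspot radius that
sample can fall several grid cells from the hotspot centre, so spatial
recovery is asserted with a tight (30 km) test hotspot rather than the
broad defaults.

## Reproduction of published values

`grainrisk reproduce` (and `grainrisk.pipeline.reproduce_reference`)
recomputes Pi and all THQ/HI/R cells from the published per-crop mean
concentrations (rice F 1.993 / Cd 0.082; corn 2.866 / 0.043; wheat
4.053 / 0.135 mg/kg) with the default parameters. All cells agree with
the published indicators within 1.5 % — the residual is rounding of the
printed means — except corn THQ_Cd (1.7 % adult, 3.0 % child): the
published corn THQ_Cd values imply an unrounded mean of ≈ 0.0443 mg/kg
versus the printed 0.043, a discrepancy in the source that no
computation from the printed mean can close. Note also that the
published corn-adult carcinogenic risk (0.471 × 10⁻⁴) lies *below* the
1 × 10⁻⁴ threshold and therefore bands as "cautionary" under the stated
rule, although the source's narrative describes all six values as
unacceptable; the package reports the band implied by the number.

## Numerical choices and problem sizes

- Exceedance and bin cuts: strict `>` at limits; right-closed bins;
  1e-12 relative nudge at binary-inexact cut values.
- IDW coincidence radius 1 m; weights `d⁻ᵖ` computed in double
  precision; surfaces written at 6 significant digits.
- JSON reports serialize floats at 6 significant digits for byte-stable
  reruns.
- Default analysis grid 200×150 (full run ≈ 4 s); property tests use
  grids from 2×2 to 50×50 and synthetic sets of 100–500 samples, sizes
  chosen to exercise every code path while keeping the suite fast.
- Mann–Whitney exact/asymptotic switch at combined n = 12.

## Known limitations

- Only the ingestion route is modelled; dermal and inhalation exposure
  are out of scope, as is probabilistic (Monte-Carlo) risk.
- Single-factor index only; no Nemerow or other composite index.
- The regression is descriptive; no errors-in-variables treatment of
  measured concentrations.
- IDW surface parameters (power, neighbourhood, cell size) were not
  published for the reference maps, so surfaces are validated by
  mathematical properties, not pixel agreement.
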