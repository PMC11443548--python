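# Methods

This note records the models implemented in seabloom, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Data model

All gridded data live on regular lat/lon grids with cell-centre
registration, as `(time, lat, lon)` float arrays with NaN as the missing
value; longitudes are normalised to [−180, 180). Statistics are always
taken over the available cells — missing data are never zero-filled.
Area means default to cos-latitude weighting (the physically correct
area weight on a regular grid); an unweighted mode is provided because
some published regional averages do not state a weighting. I/O is
classic NetCDF (CF-style axes, `_FillValue` decoded to NaN) through
xarray's scipy backend, and CSV with ISO-8601 dates for series and
profiles.

The 8-day calendar follows the Level-3 ocean-colour convention: 46 fixed
steps per year starting 1 January, the last step absorbing the year-end
remainder. Day-of-year climatologies pool 29 February with 28 February
to avoid a four-times-undersampled period.

## Climatologies, anomalies, trends

A climatology is the per-period mean and standard deviation (ddof = 1)
over an explicit reference period; different observational records start
in different years, so the reference period is per-dataset
configuration. Periods with fewer than `min_samples` (default 5)
reference samples yield missing anomalies rather than unstable ones.
Relative anomalies are `100·(x − m)/m` and are missing wherever the
climatological mean is non-positive; standardized anomalies are
`(x − m)/s` and missing wherever `s` is zero or undersampled — never an
infinity.

Gap filling interpolates interior gaps linearly in time and extends edge
gaps with the nearest valid value (pure interpolation cannot extend);
the operation is idempotent. The phenology stage requires gap-free
input, which is why this policy exists.

Decadal trends are per-pixel OLS slopes against time in decades, with
the classical two-sided t-test on the slope and a mask at p ≥ 0.05. No
serial-autocorrelation correction is applied; monthly anomaly series are
appreciably autocorrelated in reality, so the masking rate on real data
is anti-conservative. This is deliberate: it is the simplest standard
reading of per-pixel trend masking, and the test suite characterises its
behaviour exactly on white noise (≈95% of flat pixels masked).

## Bloom phenology

The threshold criterion is `1.2 × median` of the entire multi-year
series — computed once, not per season, so that one anomalous year
cannot move its own baseline. The cumulative sum of `(x_t − threshold)`
rises exactly while the series is above threshold; the first difference
of that sum is the anomaly itself, so "gradient sign change of the
cumulative sum" and "threshold crossing" are algebraically the same
event. Both formulations are implemented and tested for equality.

Within each October–May season window (austral spring/summer, isolating
the summer bloom from any secondary winter growth period):

* initiation — first step with `x > threshold`;
* peak — first occurrence of the window maximum (ties broken earliest);
* termination — first step after the peak with `x < threshold`;
* duration — `termination − initiation` in 8-day steps.

Degenerate windows are reported, not raised: a window that never crosses
the threshold returns a `detected=False` result; a window entirely above
threshold starts at step 0 with a flag; a window that never drops below
threshold after the peak terminates at the window end with a flag.
Detection runs on *every* season and reports a detected flag, which
replaces any externally curated list of bloom years with a reproducible
rule.

The box scan slides a 5°×5° box in 1° strides across a domain, keeping
only fully contained positions. For the 15–40°S, 30–80°E domain this
yields (25−5+1)·(50−5+1) = 21·46 = 966 positions, the closed form the
implementation reports.

## Mesoscale eddies and EKE

Detection operates per SLA time slice. Candidate cores are local extrema
in a 5×5 window with |SLA| above the amplitude floor; same-sign
candidates closer than the window size are treated as noise sub-peaks of
a single core and only the strongest is kept (measurement noise
otherwise splits one eddy into two candidates whose mutual "second
extremum" vetoes destroy the detection). From each core, contour levels
are walked toward the background in fixed increments; a level is
accepted while a closed contour encloses the core, encloses no second
core, and stays under the area ceiling — so SLA changes monotonically
outward by construction. The outermost accepted contour is the edge;
amplitude is extremum minus edge level; anticyclones are SLA maxima and
cyclones minima (Southern Hemisphere convention). The centre is the
anomaly-weighted mass centre of the cells inside the innermost accepted
contour that spans at least `min_center_cells` (default 12) cells — on
the very innermost contour, which may cover only a cell or two, noise
dominates the centroid.

The numeric criteria are configuration, not physics: contour interval
1 cm, minimum amplitude 2 cm, edge area between 8 and 1000 grid cells —
values in the range conventional for ~25 km altimetry products. A
boolean shallow mask (e.g. ocean shallower than 200 m) discards
detections whose edge touches it; an eddy counts toward a regional
census only if its centre is inside the region.

EKE is `½(u² + v²)` elementwise, missing where either component is.
Whether `u, v` are absolute or anomaly currents is the caller's choice
of input; both are accepted. The synthetic geostrophic-current generator
uses `u = −(g/f)∂η/∂y`, `v = (g/f)∂η/∂x` with centred differences and
per-row metric `dx = a·cosφ·dλ`, flags the outermost cell ring, and
refuses equatorial grids (|lat| ≤ 5°, where f → 0). Note one metric
subtlety exercised by the tests: the Gaussian eddies are planted in the
tangent plane at the eddy's centre latitude, so their exact zonal
derivative on the sphere carries a factor cosφ₀/cosφ.

## Mixed layer and light

MLD uses the temperature-difference criterion: the shallowest depth
where T falls 0.2 °C below the reference temperature, linearly
interpolated between the bracketing samples. The reference is the
good-QC sample nearest 10 m within ±5 m, because profiles rarely sample
10 m exactly. Profiles that never meet the criterion return NaN with a
`deeper-than-profile` flag rather than a number. Pressure inputs are
converted hydrostatically (z = p·10⁴/(ρg), ρ = 1025 kg m⁻³); the
conversion is recorded in the profile metadata. Mixed-layer temperature
is the mean of good samples above the MLD; a helper flags values below
24 °C, the lower edge of the thermal optimum for nitrogen-fixing
phytoplankton.

The light chain is configuration-driven (`seabloom/data/optics.yaml`):
Kd(490) = 0.0166 + 0.0773·Chl^0.6715 m⁻¹ and
Kd(PAR) = 0.0665 + 0.874·Kd(490) − 0.00121/Kd(490) m⁻¹ (case-1
bio-optical relations from the Morel et al. ocean-colour consistency
work), and mixed-layer-averaged PAR
`PAR_ml = PAR₀(1 − e^{−Kz})/(Kz)`, the exact depth average of an
exponentially attenuated profile, with the z → 0 limit returning the
surface value. The closed form is verified against numerical quadrature
to 10⁻⁶ relative error.

## Fluorescence quantum yield

φf is fluorescence emission over absorbed radiation:
`φf = s · nFLH / (a_ph(Chl) · iPAR)` with the chlorophyll-specific
absorption a Bricaud-style power law `a_ph = A·Chl^E` and `s` a single
radiometric factor collecting band-to-broadband, steradian and quanta
conversions (Behrenfeld et al. formulation). All coefficients are
configuration: the source work states the combination but the absolute
scale cancels in the standardized anomaly Δφf, which is the quantity
used scientifically (iron stress raises φf; relief shows as a negative
Δφf). The operation is exactly linear in nFLH and monotonically
decreasing in iPAR — the properties the tests pin — and cells below the
validity floors (Chl ≤ 0.01 mg m⁻³, iPAR ≤ 1 µEin m⁻² s⁻¹) come back
missing with a reported count. Δφf delegates to the generic
standardized-anomaly machinery with no special-casing.

## Synthetic data: what it emulates, what it does not

Generators exist so every stage can be scored against planted truth:

* **Chlorophyll**: 46-step years, multiplicative lognormal noise
  (positive-definite, mean-one), missing-at-random gaps (or contiguous
  "blocked" runs emulating cloud), planted blooms as contiguous
  elevations with a unique peak. A bloom's `termination_index` is the
  first step back at baseline — the same event the detector calls
  termination — so recovery is scored index-for-index. The study-scale
  generator (`make_bloom_study_series`) uses a 0.1 mg m⁻³ summer
  baseline with a winter elevation to 0.14 (deep winter mixing sustains
  a secondary growth period in the real region), one November bloom per
  season of amplitude 0.2 and duration 9–14 steps, noise CV 0.1 and 20%
  gaps. The winter elevation matters: it holds the long-term median —
  and hence the threshold — above the summer baseline, exactly the
  configuration in which the October–May window makes sense.
* **SLA**: sums of Gaussian bumps `A·exp(−d²/2r²)` in the local tangent
  plane plus white Gaussian noise; recovery tests keep centres separated
  by more than 3(r_i + r_j).
* **Profiles**: isothermal layer over a tanh thermocline, positioned so
  the 0.2 °C criterion depth is exactly the planted MLD.
* **Events / trends**: daily step elevations; monthly
  `intercept + slope·t` plus white noise per pixel.

Not emulated: radiative-transfer realism, eddy advection or merging,
spatially correlated cloud masks, autocorrelated baseline variability,
and dust-transport dynamics. Consequently, passing recovery tests show
the algorithms are correct and noise-robust under these idealisations —
they do not certify performance on real records, where autocorrelation
(trends), coastal contamination (SLA) and seasonal cloud structure
(gaps) are harsher.

One pipeline-specific choice: the planted Δφf excursion is expressed in
SD units *of the reference climatology* with the excursion season
excluded from the reference. Planting against the generator's true SD
instead would convolve the test with the sampling error of an 18-year SD
estimate (≈18%), which no anomaly pipeline could undo.

## Numerical details

* Randomness: every generator takes one seed; identical seeds give
  bit-identical outputs. The acceptance script spawns independent
  substreams from a single seed.
* Degenerate OLS pixels: zero residual variance with nonzero slope gives
  p = 0; a perfectly constant pixel gives slope 0, p = 1 (masked).
* `(1 − e^{−x})/x` is evaluated with `expm1` and switches to the limit
  value 1 below x = 10⁻¹².
* Gap placement redraws (seeded) if a draw would mask an entire planted
  bloom window, so truth is never erased; the drawn gap count is exact.
* Problem sizes in the acceptance run — 100×24-year phenology records,
  50 SLA fields, 100 profiles, ≥2000 trend pixels, 8×8 (Kd, MLD) grid —
  were chosen to put binomial uncertainty on recovery rates near or
  below one percentage point while keeping the whole run under a minute
  on one CPU.

## Known limitations

* Trend p-values ignore serial autocorrelation (see above).
* The eddy detector has no multi-core eddies and no tracking across
  time steps; contours enclosing two cores stop the growth of both.
* No regridding: all co-registered inputs must share one grid.
* The 3,750-position figure sometimes quoted for a 5°×5° scan of the
  15–40°S, 30–80°E domain is not reproducible from that domain with a
  1° stride and full containment; the implementation reports its own
  closed-form count (966) and treats the discrepancy as unresolved.
* Relative anomalies are undefined for non-positive climatological
  means, which limits them to positive-definite variables (Chl, AOD,
  precipitation); use standardized anomalies for signed variables.
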