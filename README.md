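# seabloom

Satellite-era diagnostics of phytoplankton bloom phenology and its
physical drivers on gridded lat/lon fields, built for studies of episodic
open-ocean blooms such as the austral-summer bloom southeast of
Madagascar. The package is aimed at ocean-colour and air–sea interaction
researchers who need a tested, reproducible version of the standard
analysis chain — anomalies, trends, bloom timing, mesoscale eddies,
mixed-layer structure, underwater light, and an iron-stress proxy —
without hand-rolled one-off scripts.

## What it computes

**Bloom phenology** from 8-day chlorophyll-a series by the
threshold-referenced cumulative-sum-of-anomalies method. The threshold is
the long-term median of the full record raised by 20%:

    C* = 1.2 · median(Chl)

Anomalies `Chl_t − C*` are cumulatively summed; the sum rises exactly
while the series sits above threshold, so sign changes of its gradient
are threshold crossings. Within each October–May season window,
initiation is the first 8-day step with `Chl > C*`, the peak is the first
seasonal maximum, termination is the first step below `C*` after the
peak, and duration is `termination − initiation` in 8-day steps. A
sliding 5°×5° box scan repeats the analysis across a whole domain to
show independence from the averaging box.

**Climatologies and anomalies** per day-of-year, 8-day step or month over
explicit reference periods: relative anomalies `100·(x − m)/m` (%),
standardized anomalies `(x − m)/s` (SD units), linear gap filling,
centred moving means, per-pixel OLS decadal trends with two-sided t-test
p-values and masking at p ≥ 0.05, and five-bin dust wet-deposition
totals.

**Mesoscale eddies** from sea-level anomaly: closed-contour detection
(centre = mass centre of the innermost closed contour, edge = outermost
closed contour with SLA changing monotonically outward), cyclonic /
anticyclonic censuses over a region, and eddy kinetic energy
`EKE = ½(u² + v²)` from surface currents, with geostrophic currents
`u = −(g/f)∂η/∂y`, `v = (g/f)∂η/∂x` available for synthetic fields.

**Mixed layer and light**: mixed-layer depth by the ΔT = 0.2 °C criterion
against a 10 m reference, mixed-layer temperature (with the 24 °C
nitrogen-fixer threshold flag), Kd(490) from chlorophyll, Kd(PAR) from
Kd(490), and mixed-layer-averaged PAR
`PAR_ml = PAR₀(1 − e^{−K z})/(K z)`.

**Iron-stress proxy**: chlorophyll fluorescence quantum yield
`φf ∝ nFLH / (a_ph(Chl) · iPAR)` and its standardized anomaly Δφf.

A `synthetic` module generates every input with recorded ground truth
(planted blooms, Gaussian eddies, tanh thermoclines, linear trends), so
the whole pipeline is testable end to end without downloading any
satellite product.

## Worked example

```python
from seabloom import fill_gaps_linear, run_phenology
from seabloom.synthetic import make_bloom_study_series

series, truths = make_bloom_study_series(seed=42)   # 24 years, 8-day steps
threshold, metrics = run_phenology(fill_gaps_linear(series))
print(f"threshold: {threshold:.4f} mg m-3")
for m in metrics[:2]:
    print(f"{m.season}: init {m.initiation_date.date()}  "
          f"term {m.termination_date.date()}  duration {m.duration} x 8-day")
```

prints

```
threshold: 0.1452 mg m-3
1997/1998: init 1997-11-09  term 1998-02-18  duration 13 x 8-day
1998/1999: init 1998-11-17  term 1999-02-10  duration 11 x 8-day
```

The threshold is 1.2× the record's median (the winter secondary growth
keeps it above the 0.1 mg m⁻³ summer baseline). The 1997/1998 bloom was
planted with initiation 1997-11-09 and termination 1998-02-18 — both
recovered exactly despite 10% multiplicative noise and 20% cloud gaps.

A command-line interface wraps the main stages for file-based use:
`seabloom phenology`, `seabloom eddies`, `seabloom mld`, `seabloom mlpar`
and `seabloom phif` (see `seabloom --help`).

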