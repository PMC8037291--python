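# Methods

## Limit curves

The four shipped curves (`RL_B`, `LOW_AL_B`, `HIGH_AL_B`, `LIMB_AL_B`) are
row-for-row transcriptions of the magnetic-flux-density columns of the EU
limit tables: occupational action levels (Directive 2013/35/EU, 1 Hz–10 MHz)
and general-public reference levels (Recommendation 1999/519/EC, 0 Hz–300
GHz). Each row keeps its printed coefficient together with the frequency
unit in which `f` enters that row's formula (the RL table switches from Hz
to kHz to MHz down its range column), so `data/limit_curves.yaml` can be
audited against the official tables without reading code. Bands are
lower-inclusive / upper-exclusive; the terminal band is closed. Evaluation
outside a curve's domain is an error — regulatory limits are never
extrapolated. E-field, H-field and power-density columns are carried as
unparsed metadata only.

Two consequences of transcribing verbatim are worth knowing. First, the
RL B-column needs a `c·√f` row (400–2000 MHz) in addition to the constant,
`c/f` and `c/f²` shapes. Second, the printed RL table is *not* exactly
continuous everywhere: it has rounding steps of 1.9% at 150 kHz
(6.25 vs 0.92/0.15 μT) and 2.9% at 2 GHz. These are properties of the
official table, inherited deliberately; they sit far above the
gradient-field assessment band and do not affect any index computed here.
The AL curves are analytically continuous at every breakpoint, which the
test suite uses as a transcription check.

## Weighted-peak index

The weight applied to a component at frequency `f` has magnitude
`1/(√2·B_L(f))`. The √2 appears exactly once, here: the limit tables are
RMS while waveform samples are instantaneous, so a single tone with peak
amplitude `√2·B_L(f)` scores exactly 100%. A flag disables the factor for
instruments that pre-scale.

`phase_model` selects the weighting phase only:

* `zero_phase` (default) — all weighting phases zero. Reproducible and,
  for in-phase line sets, conservative.
* `first_order_cascade` — the phase of the minimum-phase first-order
  cascade realising `1/B_L(f)`: a zero of order `s₀` at the origin (`s₀` =
  log-log slope of `1/B_L` on the lowest band, contributing `s₀·π/2`) plus
  one `Δ·arctan(f/f_c)` term per breakpoint `(f_c, Δ)`. For the AL curves
  the orders sum to zero, so the phase returns to 0 well above 3 kHz.

Keeping the magnitude exact under both phase models makes the single-tone
closed form hold everywhere in the domain; the corner-rounded cascade
*magnitude* (3 dB at a corner, as analog weighting hardware exhibits) is
available separately via `magnitude_model="cascade"`, normalised so its
asymptotes coincide with the exact curve. No claim is made that either
realisation is bit-identical to any particular commercial instrument; probe
positioning, not phase realisation, dominated reproducibility in the field
data this package is built around.

The spectral backend maximises the weighted cosine sum over 10 periods of
the lowest line frequency, on a grid refined by doubling until a further
doubling changes the maximum by <0.1% relative. The time backend weights
FFT bins and inverse-transforms; bins outside the curve domain (and below
the optional low-cut high-pass, modelled as a first-order section, 30 Hz in
the emulated instruments) are attenuated or zeroed. The DC bin is weighted
by the RL's 0–1 Hz constant for the RL curve and zeroed for the AL curves,
whose domain starts at 1 Hz. Axes combine as instantaneous
root-sum-of-squares (triaxial-probe behaviour); a per-axis-max alternative
exists but is not the default. Records are assessed without windowing —
amplitude windows distort peak metrics — so periodic inputs should contain
an integer number of periods, which the synthetic generator guarantees by
snapping the sample grid. A warning is recorded when more than 1% of a
record's AC energy lies within 5% of the Nyquist edge.

## Synthetic signals

`gen_waveform` produces exactly periodic records: a reference cosine, a
trapezoidal lobe train (linear rise, plateau, linear fall, one lobe per
period) or a bipolar EPI-like train (antisymmetric half-periods). Defaults
— 500 Hz fundamental, 0.2 ms rise, 0.8 ms plateau, 100 μT peak at the
probe, 100 kHz sampling — give a waveform whose AC spectral energy lies
entirely above 300 Hz, the regime of clinical gradient sequences (spectral
content from hundreds of Hz to a few kHz). The generator is parameterised
by waveform geometry, not by scanner pulse-programs: no published gradient
amplitude/slew data exist for the surveyed sequences, so synthetic trains
emulate the *class* of signal, and waveform-level tests are property-based
(closed forms, Fourier-series oracles, backend agreement), never
comparisons to published absolute indices.

`gen_distance_profile` draws `I(d) = A(d+d₀)^(−n)·(1+ε)` with `ε`
zero-mean normal of relative sd `noise_sd`, seeded and reproducible.
The multiplicative noise emulates probe-positioning reproducibility error,
the dominant variation between repeated field measurements; it does not
emulate instrument frequency-response differences or ambient interference.
Passing recovery tests therefore demonstrates robustness to positioning
scatter, not to every error source of a real survey.

The published result tables of the three surveyed tomographs ship verbatim
as TSV fixtures (`data/table4.tsv` … `table8.tsv`). The absolute indices
encode instrument waveforms that were never published and cannot be
regenerated; they are used exclusively as *inputs* to the clearance and
zoning stages.

## Clearance fitting

Model: `I(d) = A·(d+d₀)^(−n)`, a single offset power law. The offset `d₀`
(cm) locates the effective source centre behind the gantry mouth — fitted
values for the surveyed closed-bore scanners land near 50 cm, a plausible
mouth-to-isocentre scale — and `n` is a near-field-like decay exponent
(fitted values ≈ 3, dipole-like). A plain two-point log-log interpolation
misses the published clearances, while this three-parameter model
reproduces them within their stated ±3 cm; multi-term multipole expansions
are out of scope.

Fitting minimises squared residuals of `log I` against `log(d+d₀)`,
unweighted over all points. For fixed `d₀` the problem is linear and solved
in closed form; `d₀` is profiled out by a bounded deterministic scalar
minimisation (`d₀ ∈ [10⁻², 10⁵]` cm, tolerance 10⁻¹³ in `log d₀`). With
three points this reduces to the exact interpolant; degenerate profiles
(non-decaying indices) are rejected. The fit is deterministic — identical
inputs give bit-identical reports.

The clearance is `d_clear = (A/threshold)^(1/n) − d₀` (threshold 100% by
default), clipped at 0 with a `compliant_everywhere` flag when the fitted
index is within the threshold already at the mouth. Compliance ties
(index = 100) resolve to compliant. The uncertainty half-width is the
half-range of leave-one-out refit crossings (≥4 points) or of crossings
under ±5% perturbation of each index in turn (3 points) — a convention of
this package; the underlying survey states ±3 cm without a recipe.
Crossings outside the sampled distance range are flagged as extrapolated.

One sensitivity worth recording: for the Magnetom Aera C2 profile
(2642/338/100/44.4% at 0/50/100/150 cm) the all-points fit crosses 100% at
100.9 cm, while excluding the 150 cm point pins the crossing to exactly
100.0 cm, because the printed 100 cm index is exactly 100%. The survey
reports 104 ± 3 cm for this geometry; that value is not recoverable from
the printed (rounded) table values by unweighted least squares in either
log or linear space, and the package reports what its documented estimator
computes. The two Ingenia geometries land at 91.3 cm and 82.1 cm against
reported 91 ± 3 and 83 ± 3.

## Zoning

`classify_zone` implements the EN 50499 ladder on the three indices of a
point: Zone 0 if RL ≤ 100%, else Zone 1a if low-AL ≤ 100%, else Zone 1b if
high-AL ≤ 100%, else Zone 2. Indices should be ordered RL ≥ low AL ≥ high
AL (the limits are ordered oppositely at every frequency); violations are
warned about rather than rejected, since measurement noise produces small
inversions. `zone_boundary_map` turns the per-curve clearances of one
measurement geometry into ordered boundary distances along the departure
line. The distances refer to that line only; the package does not
interpolate zones across the room area, which single-transect data cannot
support — reported zones are to be read as semicircular bands centred on
the bed axis, as is conventional for gantry surveys.

## Problem sizes and tolerances in the shipped tests

Synthetic records in the tests use 500–1000 Hz fundamentals sampled at
20–100 kHz for a handful of periods — enough for every index to converge
far below the asserted tolerances (0.5% for closed forms, 1% for
Fourier-series oracle agreement). The noisy-recovery study uses 100 seeded
4-point profiles at 5% relative noise, matching the positioning-error scale
of repeated field measurements, and asserts a median absolute clearance
error under 5% of the true crossing.

## Known limitations

* Electric-field assessment, static-field and RF exposure, and
  contact-current workflows are out of scope; only the B-field columns of
  the limit tables are evaluable (the limb-AL curve is stored and
  evaluable but has no dedicated workflow).
* The cascade phase model is a minimum-phase idealisation of hardware
  weighting, not a calibrated instrument model.
* The decay model is a single offset power law; very open geometries or
  multi-source rooms may need richer spatial models.
* Zone boundaries are one-dimensional (along the measured transect);
  full-room mapping requires denser spatial sampling than the packaged
  surveys provide.
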