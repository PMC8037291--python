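# gmfwp — weighted-peak assessment of MRI gradient magnetic fields

`gmfwp` is a toolkit for occupational and general-public exposure assessment
of the time-varying stray fields emitted by the gradient coils of MRI
tomographs (and of any other broadband low-frequency magnetic-field source).
It is aimed at health-physics and radiation-protection practitioners who need
to turn measured or simulated magnetic-flux-density waveforms into regulatory
compliance statements: exposure indices, clearance distances and EN 50499
workplace zones.

## What it computes

**Limit curves.** The magnetic-flux-density limit tables of Directive
2013/35/EU (occupational low, high and limb *action levels*, 1 Hz–10 MHz) and
Recommendation 1999/519/EC (general-public *reference levels*, 0 Hz–300 GHz)
are shipped as an auditable data file and evaluated as piecewise functions
B_L(f), RMS μT.

**Weighted-peak index.** For a waveform with spectral components
(A_i, f_i, φ_i), the index against a limit curve is

    WP% = 100 · max_t | Σ_i  A_i · |W(f_i)| · cos(2π f_i t + φ_i + arg W(f_i)) |

with weight magnitude |W(f)| = 1/(√2·B_L(f)) (the √2 converts the RMS limit
tables to the peak convention of instantaneous samples) and a selectable
phase model: zero phase, or the phase response of the first-order filter
cascade that hardware weighting instruments realise. WP ≤ 100% means
compliant. Both a spectral-line backend and an FFT time-domain backend (with
instantaneous root-sum-of-squares combination of the three probe axes) are
provided.

**Clearance distances.** Indices measured along a departure line from the
gantry mouth are fitted with an offset power law

    I(d) = A · (d + d₀)^(−n)

by unweighted least squares in log space, and the clearance distance is the
100% crossing, d_clear = (A/100)^(1/n) − d₀, reported with a half-width
uncertainty (leave-one-out refits, or ±5% index perturbation for 3-point
profiles).

**Zoning.** Each assessment point is classified per EN 50499: Zone 0
(complies with general-public RLs), Zone 1a (exceeds RLs, complies with low
ALs), Zone 1b (complies with high ALs only), Zone 2 (exceeds high ALs).

The package also includes a synthetic-signal module (trapezoidal and bipolar
gradient-lobe trains, seeded noisy decay profiles with known ground truth)
and, as packaged fixtures, the published measurement tables of three clinical
tomographs (1 T Philips Panorama, 1.5 T Philips Ingenia, 1.5 T Siemens
Magnetom Aera).

## Worked example

```python
>>> import gmfwp

# a 500 Hz trapezoidal gradient-lobe train, 20 uT peak at the probe
>>> ts = gmfwp.gen_waveform(gmfwp.SequenceSpec(fundamental=500.0,
...                                            amplitude_at_reference=20.0))
>>> for cid in ("RL_B", "LOW_AL_B", "HIGH_AL_B"):
...     r = gmfwp.wp_index_time(ts, gmfwp.WeightingSpec(curve=cid))
...     print(cid, round(r.index_percent, 1))
RL_B 96.7
LOW_AL_B 3.6
HIGH_AL_B 3.6
```

The train just complies with the general-public reference levels (96.7%) and
is far below the occupational action levels; the low- and high-AL indices
coincide because all the train's spectral energy lies above 300 Hz, where the
two AL curves are identical.

```python
# published Ingenia distance profile, sequence B2, probe 100 cm above floor
>>> fx = gmfwp.gen_measurement_fixture("B")
>>> prof = fx.profile("B2", height=100.0)      # RL indices at 0/40/100 cm
>>> fit = gmfwp.fit_decay(prof)
>>> print(f"A={fit.A:.3g} d0={fit.d0:.1f} n={fit.n:.2f}")
A=7.67e+08 d0=53.8 n=3.19
>>> print(gmfwp.clearance_distance(fit, profile=prof))
91 ± 2 cm (Zone 0 / Zone 1a)
```

The fitted index falls to 100% at 91 cm from the gantry mouth: members of the
general public should stay about a metre away, and that distance is the
boundary between Zone 0 and Zone 1a. At the mouth itself the point
(RL 2356%, low AL 76.0%, high AL 72.5%) classifies as Zone 1a:

```python
>>> gmfwp.classify_zone(2356.0, 76.0, 72.5)
<Zone.ZONE1A: 'Zone1a'>
```

The same workflow is available from the shell:

```sh
gmfwp simulate -c config.yaml -o out/       # synthetic waveform + profiles
gmfwp assess out/waveform.tsv -o out/indices.tsv
gmfwp clearance out/profiles.tsv -o out/report.tsv
gmfwp fixtures B -o out/                    # dump the packaged survey tables
```

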