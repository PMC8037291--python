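# Magnetic-flux-density exposure limit curves, transcribed row-for-row from
# the official EU tables.  All limits are RMS values in microtesla (uT).
#
# Each segment row stores the formula exactly as printed in its source table:
# `coefficient` and `form` reproduce the printed expression, and `freq_unit`
# is the unit in which the frequency enters that expression on that row
# (the 1999/519/EC table switches from Hz to kHz to MHz down its range
# column; the coefficients are NOT rescaled here, so they remain auditable
# against the printed tables).
#
# forms:  constant   -> c
#         c_over_f   -> c / f
#         c_over_f2  -> c / f^2
#         c_sqrt_f   -> c * sqrt(f)
#
# f_lo_hz / f_hi_hz give the band in Hz with a lower-inclusive /
# upper-exclusive convention; the terminal segment of a curve is closed
# at its upper edge.

version: "1.0"
curves:
  LOW_AL_B:
    source: "Directive 2013/35/EU, occupational action levels (ALs) for magnetic flux density, 1 Hz - 10 MHz; low-AL column (sensory-effect ELV related)"
    value_convention: RMS
    segments:
      - {f_lo_hz: 1.0,    f_hi_hz: 8.0,    form: c_over_f2, coefficient: 2.0e5, freq_unit: Hz}
      - {f_lo_hz: 8.0,    f_hi_hz: 25.0,   form: c_over_f,  coefficient: 2.5e4, freq_unit: Hz}
      - {f_lo_hz: 25.0,   f_hi_hz: 300.0,  form: constant,  coefficient: 1.0e3, freq_unit: Hz}
      - {f_lo_hz: 300.0,  f_hi_hz: 3.0e3,  form: c_over_f,  coefficient: 3.0e5, freq_unit: Hz}
      - {f_lo_hz: 3.0e3,  f_hi_hz: 1.0e7,  form: constant,  coefficient: 1.0e2, freq_unit: Hz}
  HIGH_AL_B:
    source: "Directive 2013/35/EU, occupational action levels (ALs) for magnetic flux density, 1 Hz - 10 MHz; high-AL column (health-effect ELV related)"
    value_convention: RMS
    segments:
      - {f_lo_hz: 1.0,    f_hi_hz: 8.0,    form: c_over_f,  coefficient: 3.0e5, freq_unit: Hz}
      - {f_lo_hz: 8.0,    f_hi_hz: 25.0,   form: c_over_f,  coefficient: 3.0e5, freq_unit: Hz}
      - {f_lo_hz: 25.0,   f_hi_hz: 300.0,  form: c_over_f,  coefficient: 3.0e5, freq_unit: Hz}
      - {f_lo_hz: 300.0,  f_hi_hz: 3.0e3,  form: c_over_f,  coefficient: 3.0e5, freq_unit: Hz}
      - {f_lo_hz: 3.0e3,  f_hi_hz: 1.0e7,  form: constant,  coefficient: 1.0e2, freq_unit: Hz}
  LIMB_AL_B:
    source: "Directive 2013/35/EU, occupational action levels (ALs) for exposure of limbs to a localised magnetic field, 1 Hz - 10 MHz"
    value_convention: RMS
    segments:
      - {f_lo_hz: 1.0,    f_hi_hz: 8.0,    form: c_over_f,  coefficient: 9.0e5, freq_unit: Hz}
      - {f_lo_hz: 8.0,    f_hi_hz: 25.0,   form: c_over_f,  coefficient: 9.0e5, freq_unit: Hz}
      - {f_lo_hz: 25.0,   f_hi_hz: 300.0,  form: c_over_f,  coefficient: 9.0e5, freq_unit: Hz}
      - {f_lo_hz: 300.0,  f_hi_hz: 3.0e3,  form: c_over_f,  coefficient: 9.0e5, freq_unit: Hz}
      - {f_lo_hz: 3.0e3,  f_hi_hz: 1.0e7,  form: constant,  coefficient: 3.0e2, freq_unit: Hz}
  RL_B:
    source: "Recommendation 1999/519/EC, reference levels (RLs) for the general public, B-field column, 0 Hz - 300 GHz (unperturbed RMS)"
    value_convention: RMS
    segments:
      # E-field, H-field and plane-wave power-density columns are kept as
      # unparsed metadata strings; only the B column is evaluable.
      - {f_lo_hz: 0.0,    f_hi_hz: 1.0,    form: constant,  coefficient: 4.0e4,  freq_unit: Hz,
         metadata: {e_field_v_per_m: "-", h_field_a_per_m: "3.2e4", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 1.0,    f_hi_hz: 8.0,    form: c_over_f2, coefficient: 4.0e4,  freq_unit: Hz,
         metadata: {e_field_v_per_m: "10000", h_field_a_per_m: "3.2e4/f", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 8.0,    f_hi_hz: 25.0,   form: c_over_f,  coefficient: 5000.0, freq_unit: Hz,
         metadata: {e_field_v_per_m: "10000", h_field_a_per_m: "4000/f", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 25.0,   f_hi_hz: 800.0,  form: c_over_f,  coefficient: 5.0,    freq_unit: kHz,
         metadata: {e_field_v_per_m: "250/f", h_field_a_per_m: "4/f", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 800.0,  f_hi_hz: 3.0e3,  form: constant,  coefficient: 6.25,   freq_unit: kHz,
         metadata: {e_field_v_per_m: "250/f", h_field_a_per_m: "5", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 3.0e3,  f_hi_hz: 1.5e5,  form: constant,  coefficient: 6.25,   freq_unit: kHz,
         metadata: {e_field_v_per_m: "87", h_field_a_per_m: "5", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 1.5e5,  f_hi_hz: 1.0e6,  form: c_over_f,  coefficient: 0.92,   freq_unit: MHz,
         metadata: {e_field_v_per_m: "87", h_field_a_per_m: "0.73/f", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 1.0e6,  f_hi_hz: 1.0e7,  form: c_over_f,  coefficient: 0.92,   freq_unit: MHz,
         metadata: {e_field_v_per_m: "87/f^1/2", h_field_a_per_m: "0.73/f", s_eq_w_per_m2: "-"}}
      - {f_lo_hz: 1.0e7,  f_hi_hz: 4.0e8,  form: constant,  coefficient: 0.092,  freq_unit: MHz,
         metadata: {e_field_v_per_m: "28", h_field_a_per_m: "0.073", s_eq_w_per_m2: "2"}}
      - {f_lo_hz: 4.0e8,  f_hi_hz: 2.0e9,  form: c_sqrt_f,  coefficient: 0.0046, freq_unit: MHz,
         metadata: {e_field_v_per_m: "1.375 f^1/2", h_field_a_per_m: "0.0037 f^1/2", s_eq_w_per_m2: "f/200"}}
      - {f_lo_hz: 2.0e9,  f_hi_hz: 3.0e11, form: constant,  coefficient: 0.20,   freq_unit: GHz,
         metadata: {e_field_v_per_m: "61", h_field_a_per_m: "0.16", s_eq_w_per_m2: "10"}}
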