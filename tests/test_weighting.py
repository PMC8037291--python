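"""Weighted-peak index: weighting filter, spectral and time backends."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gmfwp as g
from gmfwp.limits import FrequencyDomainError
from gmfwp.weighting import weight_array

SQRT2 = np.sqrt(2.0)


def tone_record(f, amplitude, fs_factor=64, reps=3):
    return g.gen_waveform(
        g.SequenceSpec(kind="tone", fundamental=f, sample_rate=fs_factor * f,
                       amplitude_at_reference=amplitude, repetitions=reps)
    )


# ---------------------------------------------------------------------------
# complex weight


def test_weight_magnitude_is_reciprocal_rms_limit():
    w = g.complex_weight(g.WeightingSpec(curve="RL_B"), 2000.0)
    assert abs(w) == pytest.approx(1.0 / (SQRT2 * 6.25), rel=1e-12)
    assert np.angle(w) == 0.0


def test_weight_constant_across_constant_segment():
    spec = g.WeightingSpec(curve="LOW_AL_B")
    mags = [abs(g.complex_weight(spec, f)) for f in (25.0, 60.0, 150.0, 299.0)]
    assert np.ptp(mags) == 0.0


def test_rms_to_peak_flag_removes_sqrt2():
    spec = g.WeightingSpec(curve="RL_B", rms_to_peak=False)
    assert abs(g.complex_weight(spec, 2000.0)) == pytest.approx(1.0 / 6.25, rel=1e-12)


def test_weight_zero_outside_assessment_band():
    spec = g.WeightingSpec(curve="LOW_AL_B")
    assert g.complex_weight(spec, 0.5) == 0.0
    assert weight_array(spec, np.array([0.0, 2.0e7]))[1] == 0.0


def test_cascade_phase_vanishes_far_above_top_corner():
    # the cascade orders of the AL curve sum to zero, so the phase returns to 0
    spec = g.WeightingSpec(curve="LOW_AL_B", phase_model="first_order_cascade")
    for f in (3.0e5, 1.0e6, 5.0e6):
        assert abs(np.angle(g.complex_weight(spec, f))) < 0.01


def test_cascade_phase_model_rejects_nonpositive_frequency():
    spec = g.WeightingSpec(curve="RL_B", phase_model="first_order_cascade")
    with pytest.raises(FrequencyDomainError):
        g.complex_weight(spec, 0.0)


def test_cascade_magnitude_matches_exact_on_plateaus_far_from_corners():
    # hardware-emulation magnitude: corner rounding < 5% a decade away
    exact = g.WeightingSpec(curve="LOW_AL_B")
    casc = g.WeightingSpec(curve="LOW_AL_B", phase_model="first_order_cascade",
                           magnitude_model="cascade")
    for f in (3.0e4, 1.0e5, 1.0e6):
        assert abs(g.complex_weight(casc, f)) == pytest.approx(
            abs(g.complex_weight(exact, f)), rel=0.05
        )


def test_low_cut_is_first_order_high_pass():
    base = g.WeightingSpec(curve="RL_B")
    cut = g.WeightingSpec(curve="RL_B", low_cut=30.0)
    x = 10.0 / 30.0
    expected = x / np.sqrt(1 + x * x)
    ratio = abs(g.complex_weight(cut, 10.0)) / abs(g.complex_weight(base, 10.0))
    assert ratio == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# single-tone closed form, both backends


@pytest.mark.parametrize("phase_model", ["zero_phase", "first_order_cascade"])
def test_single_tone_closed_form_spectral(phase_model):
    rng = np.random.default_rng(7)
    for _ in range(10):
        f = float(10 ** rng.uniform(0.5, 3.6))
        A = float(10 ** rng.uniform(0.0, 3.0))
        spec = g.WeightingSpec(curve="RL_B", phase_model=phase_model)
        res = g.wp_index_spectral([g.SpectralLine(f, A)], spec)
        expected = 100.0 * A / (SQRT2 * g.limit_value("RL_B", f))
        assert res.index_percent == pytest.approx(expected, rel=5e-3)


@pytest.mark.parametrize("phase_model", ["zero_phase", "first_order_cascade"])
def test_single_tone_closed_form_time(phase_model):
    rng = np.random.default_rng(11)
    for _ in range(10):
        f = float(10 ** rng.uniform(0.7, 3.3))
        A = float(10 ** rng.uniform(0.0, 3.0))
        ts = tone_record(f, A)
        spec = g.WeightingSpec(curve="LOW_AL_B", phase_model=phase_model)
        res = g.wp_index_time(ts, spec)
        expected = 100.0 * A / (SQRT2 * g.limit_value("LOW_AL_B", ts.sample_rate / 64))
        assert res.index_percent == pytest.approx(expected, rel=5e-3)


def test_tone_at_sqrt2_limit_amplitude_scores_100(tone_record):
    res = g.wp_index_time(tone_record, g.WeightingSpec(curve="RL_B"))
    assert res.index_percent == pytest.approx(100.0, rel=5e-3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(k=st.floats(0.05, 50.0))
def test_homogeneity_scaling_waveform_scales_index(k):
    lines = [g.SpectralLine(500.0, 10.0), g.SpectralLine(1500.0, 4.0, 1.1)]
    spec = g.WeightingSpec(curve="RL_B")
    base = g.wp_index_spectral(lines, spec).index_percent
    scaled = g.wp_index_spectral(
        [g.SpectralLine(l.f, l.amplitude * k, l.phase) for l in lines], spec
    ).index_percent
    assert scaled == pytest.approx(k * base, rel=1e-3)


def test_doubling_single_line_doubles_index():
    spec = g.WeightingSpec(curve="RL_B")
    a = g.wp_index_spectral([g.SpectralLine(1000.0, 5.0)], spec).index_percent
    b = g.wp_index_spectral([g.SpectralLine(1000.0, 10.0)], spec).index_percent
    assert b == pytest.approx(2 * a, rel=1e-3)


def test_two_commensurate_lines_match_bruteforce_and_analytic_max():
    # lines (f, A) and (3f, A/3) on the constant 1000 uT plateau;
    # max of cos(x) + cos(3x)/3 is 4/3 at x = 0 (independent dense scan below)
    f, A = 50.0, 30.0
    x = np.linspace(0.0, 2 * np.pi, 1_000_001)
    brute = np.max(np.abs(np.cos(x) + np.cos(3 * x) / 3.0))
    assert brute == pytest.approx(4.0 / 3.0, rel=1e-9)
    spec = g.WeightingSpec(curve="LOW_AL_B")
    res = g.wp_index_spectral([g.SpectralLine(f, A), g.SpectralLine(3 * f, A / 3)], spec)
    expected = 100.0 * brute * A / (SQRT2 * 1000.0)
    assert res.index_percent == pytest.approx(expected, rel=5e-3)


# ---------------------------------------------------------------------------
# time backend: triaxial combination, backend agreement


def test_rss_combination_of_duplicated_axis_gains_sqrt2(tone_record):
    single = g.wp_index_time(tone_record, g.WeightingSpec(curve="RL_B"))
    tri = g.TimeSeriesRecord(
        tone_record.sample_rate,
        np.vstack([tone_record.samples[0], tone_record.samples[0],
                   np.zeros_like(tone_record.samples[0])]),
    )
    res = g.wp_index_time(tri, g.WeightingSpec(curve="RL_B"))
    assert res.index_percent == pytest.approx(SQRT2 * single.index_percent, rel=1e-6)
    assert len(res.per_axis_index) == 3
    assert res.per_axis_index[2] == pytest.approx(0.0, abs=1e-9)


def test_combined_max_not_below_largest_axis_max(tone_record):
    rng = np.random.default_rng(3)
    tri = g.TimeSeriesRecord(
        tone_record.sample_rate,
        np.vstack([tone_record.samples[0],
                   np.roll(tone_record.samples[0], 7),
                   0.5 * rng.standard_normal(tone_record.n_samples)]),
    )
    res = g.wp_index_time(tri, g.WeightingSpec(curve="RL_B"))
    assert res.index_percent >= max(res.per_axis_index) - 1e-9


def test_spectral_and_time_backends_agree_on_periodic_input():
    lines = [g.SpectralLine(500.0, 20.0, 0.0),
             g.SpectralLine(1500.0, 10.0, 0.7),
             g.SpectralLine(2500.0, 4.0, -1.2)]
    fs, T = 50_000.0, 10 / 500.0
    t = np.arange(int(fs * T)) / fs
    x = sum(l.amplitude * np.cos(2 * np.pi * l.f * t + l.phase) for l in lines)
    for phase_model in ("zero_phase", "first_order_cascade"):
        spec = g.WeightingSpec(curve="RL_B", phase_model=phase_model)
        a = g.wp_index_spectral(lines, spec).index_percent
        b = g.wp_index_time(g.TimeSeriesRecord(fs, x), spec).index_percent
        assert b == pytest.approx(a, rel=5e-3)


def _trapezoid_fourier_lines(spec, nyquist):
    """Analytic Fourier series of the trapezoid train (independent oracle)."""
    A, T = spec.amplitude_at_reference, spec.period
    r, p = spec.rise_time, spec.plateau
    t_c = (2 * r + p) / 2.0
    lines = []
    k = 1
    while k * spec.fundamental < nyquist:
        fk = k * spec.fundamental
        ck = (A * (p + r) / T) * np.sinc(fk * (p + r)) * np.sinc(fk * r) * np.exp(-2j * np.pi * fk * t_c)
        if abs(ck) > 1e-12 * A:
            lines.append(g.SpectralLine(fk, 2 * abs(ck), float(np.angle(ck))))
        k += 1
    return lines


def test_trapezoid_train_matches_fourier_series_oracle():
    seq = g.SequenceSpec()  # 500 Hz trapezoid train
    ts = g.gen_waveform(seq)
    lines = _trapezoid_fourier_lines(seq, ts.sample_rate / 2)
    spec = g.WeightingSpec(curve="RL_B")
    time_idx = g.wp_index_time(ts, spec).index_percent
    spec_idx = g.wp_index_spectral(lines, spec).index_percent
    assert time_idx == pytest.approx(spec_idx, rel=1e-2)


def test_monotone_limit_dominance():
    for ts in (g.gen_waveform(g.SequenceSpec()), tone_record(50.0, 100.0)):
        idx = {}
        for cid in ("RL_B", "LOW_AL_B", "HIGH_AL_B"):
            idx[cid] = g.wp_index_time(ts, g.WeightingSpec(curve=cid)).index_percent
        assert idx["RL_B"] >= idx["LOW_AL_B"] >= idx["HIGH_AL_B"]


# ---------------------------------------------------------------------------
# low/high AL pairing


def test_al_pair_identical_for_1_khz_tone():
    low, high = g.index_pair_lowal_highal(tone_record(1000.0, 200.0))
    assert low.index_percent == pytest.approx(high.index_percent, rel=1e-9)


def test_al_pair_ratio_six_for_50_hz_tone():
    low, high = g.index_pair_lowal_highal(tone_record(50.0, 200.0))
    assert low.index_percent / high.index_percent == pytest.approx(6.0, rel=1e-3)


def test_al_pair_close_for_gradient_like_train():
    ts = g.gen_waveform(g.SequenceSpec(fundamental=500.0))
    assert g.spectral_energy_fraction(ts, 300.0) >= 0.95
    low, high = g.index_pair_lowal_highal(ts)
    assert low.index_percent == pytest.approx(high.index_percent, rel=0.10)


# ---------------------------------------------------------------------------
# validation and warnings


def test_nan_samples_rejected():
    x = np.ones(64)
    x[10] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        g.wp_index_time(g.TimeSeriesRecord(1000.0, x), g.WeightingSpec(curve="RL_B"))


def test_empty_line_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        g.wp_index_spectral([], g.WeightingSpec(curve="RL_B"))


def test_undersampled_content_triggers_warning():
    rec = g.gen_waveform(g.SequenceSpec(kind="tone", fundamental=1000.0,
                                        sample_rate=21_000.0,
                                        amplitude_at_reference=10.0, repetitions=4))
    res = g.wp_index_time(rec, g.WeightingSpec(curve="RL_B"))
    assert not res.warnings  # 1 kHz tone at 21 kHz: comfortably sampled
    t = np.arange(256) / 1000.0
    hot = np.cos(2 * np.pi * 490.0 * t)  # content at 98% of Nyquist
    res2 = g.wp_index_time(g.TimeSeriesRecord(1000.0, hot), g.WeightingSpec(curve="RL_B"))
    assert res2.warnings


def test_invalid_channel_count_rejected():
    with pytest.raises(ValueError, match="channels"):
        g.TimeSeriesRecord(1000.0, np.zeros((2, 32)))
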