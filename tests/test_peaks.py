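"""Peak expansion, baselines, power fractions and the action measure."""

import numpy as np
import pytest

from _oracles import (
    expand_peak_bruteforce,
    local_maxima,
    power_fraction_trapezoid,
    random_psd,
)
from tremorkit import (
    AlgorithmParams,
    SpectralPeak,
    SyntheticScenario,
    action_measure,
    analyze_recording,
    best_peak_in_band,
    detect_peaks,
    power_fraction,
    simulate_recording,
)
from tremorkit.peaks import ACCEL, GYRO, attach_power_fractions


def _grid(df=0.25, n=65):
    return np.arange(n) * df


def test_monotone_psd_has_no_peaks():
    f = _grid()
    assert detect_peaks(f, np.linspace(1.0, 0.1, f.size), 2.0) == []
    assert detect_peaks(f, np.linspace(0.1, 1.0, f.size), 2.0) == []


def test_triangular_peak_bounds_sit_at_its_feet():
    f = _grid()
    p = np.full(f.size, 0.05)
    apex, half = 24, 4  # feet at indices 20 and 28
    for j in range(-half, half + 1):
        p[apex + j] += (half - abs(j)) / half
    peaks = detect_peaks(f, p, 5.0)
    assert len(peaks) == 1
    assert (peaks[0].i_b, peaks[0].i_peak, peaks[0].i_e) == (20, 24, 28)


def test_width_cap_truncates_adjacent_gaussians():
    f = np.arange(0, 16, 0.1)
    p = (
        0.02
        + np.exp(-0.5 * ((f - 5.0) / 0.3) ** 2)
        + 0.8 * np.exp(-0.5 * ((f - 6.0) / 0.3) ** 2)
    )
    peaks = detect_peaks(f, p, 0.8)
    tall = [pk for pk in peaks if p[pk.i_peak] > 0.5]
    assert len(tall) == 2
    for pk in tall:
        assert pk.f_e - pk.f_b <= 0.8 + 1e-9
        assert pk.f_e - pk.f_b >= 0.7  # expansion used almost the full budget


def test_detect_peaks_matches_bruteforce_oracle_on_random_psds():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(8, 65))
        f, p = random_psd(rng, n)
        width = float(rng.uniform(0.5, 4.0))
        got = {(pk.i_b, pk.i_peak, pk.i_e) for pk in detect_peaks(f, p, width)}
        want = set()
        for k in local_maxima(p):
            b, e = expand_peak_bruteforce(f, p, k, width)
            want.add((b, k, e))
        assert got == want


def test_power_fraction_matches_trapezoid_oracle_on_random_psds(quiet_params):
    rng = np.random.default_rng(7)
    for _ in range(300):
        f, p = random_psd(rng, int(rng.integers(16, 65)))
        for pk in detect_peaks(f, p, 3.0):
            rho = power_fraction(pk, f, p, quiet_params)
            want = power_fraction_trapezoid(
                f, p, pk.i_b, pk.i_e, quiet_params.f_tremor_min, quiet_params.p_min_accel
            )
            assert rho == pytest.approx(want, abs=1e-9)
            assert rho >= 0.0
            if pk.f_b > quiet_params.f_tremor_min:
                # above the tremor floor the peak's own power is part of the
                # denominator, so the fraction cannot exceed one
                assert rho <= 1.0


def test_degenerate_peak_on_flat_psd_has_zero_power_fraction(quiet_params):
    f = _grid()
    p = np.full(f.size, 0.3)
    pk = SpectralPeak(f_peak=5.0, f_b=4.0, f_e=6.0, baseline_b=0.3, baseline_e=0.3,
                      i_peak=20, i_b=16, i_e=24)
    assert power_fraction(pk, f, p, quiet_params) == 0.0


def test_pure_sinusoid_power_fraction_approaches_one(quiet_params):
    fs = 128.0
    t = np.arange(int(10 * fs)) / fs
    from tremorkit import compute_spectrogram

    spec = compute_spectrogram(np.sin(2 * np.pi * 5.0 * t), fs, 5.0, 1.0)
    peaks = detect_peaks(spec.freqs, spec.psd[0], 3.0)
    attach_power_fractions(peaks, spec.freqs, spec.psd[0], quiet_params)
    assert max(pk.rho for pk in peaks) >= 0.95


def test_triangle_on_flat_background_gives_exact_power_ratio(quiet_params):
    # triangle of area 0.3 on a flat background of area 0.7 above the floor
    f = _grid(0.25, 65)  # 0 .. 16 Hz
    tail = f > quiet_params.f_tremor_min
    span = f[-1] - f[tail][0]
    level = 0.7 / span
    p = np.full(f.size, level)
    apex, half = 24, 4  # feet at 5.0 and 7.0 Hz, width 2 Hz
    height = 0.3  # area = height * half-width-in-Hz = 0.3 * 1.0
    for j in range(-half, half + 1):
        p[apex + j] += height * (half - abs(j)) / half
    peaks = detect_peaks(f, p, 5.0)
    attach_power_fractions(peaks, f, p, quiet_params)
    assert len(peaks) == 1
    assert peaks[0].rho == pytest.approx(0.30, abs=1e-9)


def test_power_fraction_scale_invariant_and_background_monotone(quiet_params):
    f = _grid(0.25, 65)
    p = 0.05 + np.exp(-0.5 * ((f - 6.0) / 0.4) ** 2)
    (pk,) = [q for q in detect_peaks(f, p, 3.0) if abs(q.f_peak - 6.0) < 0.5]
    rho = power_fraction(pk, f, p, quiet_params)
    # scaling the whole PSD leaves rho unchanged in the power-dominated regime
    (pk_scaled,) = [q for q in detect_peaks(f, 10 * p, 3.0) if abs(q.f_peak - 6.0) < 0.5]
    assert power_fraction(pk_scaled, f, 10 * p, quiet_params) == pytest.approx(rho, rel=1e-12)
    # extra broadband power strictly dilutes the peak
    (pk_bg,) = [q for q in detect_peaks(f, p + 0.2, 3.0) if abs(q.f_peak - 6.0) < 0.5]
    assert power_fraction(pk_bg, f, p + 0.2, quiet_params) < rho


def test_small_peaks_suppressed_by_minimum_power_floor():
    params = AlgorithmParams()  # clinical floors active
    f = _grid(0.25, 65)
    p = 1e-9 * (0.05 + np.exp(-0.5 * ((f - 6.0) / 0.4) ** 2))
    peaks = detect_peaks(f, p, 3.0)
    attach_power_fractions(peaks, f, p, params)
    assert all(pk.rho < 1e-6 for pk in peaks)


def test_best_peak_prefers_largest_power_fraction_across_sources():
    acc = SpectralPeak(5.0, 4.5, 5.5, 0, 0, rho=0.2, source=ACCEL)
    gyr = SpectralPeak(5.5, 5.0, 6.0, 0, 0, rho=0.6, source=GYRO)
    assert best_peak_in_band([acc, gyr], 4.0, 12.0) is gyr
    assert best_peak_in_band([acc, gyr], 6.5, 12.0) is None


def test_best_peak_tie_breaks_to_lower_frequency():
    lo = SpectralPeak(5.0, 4.5, 5.5, 0, 0, rho=0.4, source=ACCEL)
    hi = SpectralPeak(7.0, 6.5, 7.5, 0, 0, rho=0.4, source=GYRO)
    assert best_peak_in_band([hi, lo], 4.0, 12.0) is lo


def test_action_measure_recovers_reaching_movement_rms(params):
    # 1 Hz "reaching" of 3 cm RMS -> action RMS ~ 3 cm, detected
    scn = SyntheticScenario(confound_rms_cm=3.0, confound_freq=1.0, seed=9, duration=20.0)
    rec, _ = simulate_recording(scn)
    an = analyze_recording(rec, params)
    rms = [action_measure(an.pos_spec.freqs, an.pos_spec.psd[i], params).p_a_rms_cm
           for i in range(an.pos_spec.n_segments)]
    assert np.median(rms) == pytest.approx(3.0, rel=0.10)
    assert action_measure(an.pos_spec.freqs, an.pos_spec.psd[0], params).action_detected


def test_action_measure_ignores_tremor_band_and_static_rest(params):
    static = SyntheticScenario(seed=10)
    rec, _ = simulate_recording(static)
    an = analyze_recording(rec, params)
    act = action_measure(an.pos_spec.freqs, an.pos_spec.psd[0], params)
    assert act.p_a_rms_cm < 0.1
    assert not act.action_detected

    tremor = SyntheticScenario(pos_amp_cm=2.0, pos_freq=5.0, seed=13)
    rec, _ = simulate_recording(tremor)
    an = analyze_recording(rec, params)
    act = action_measure(an.pos_spec.freqs, an.pos_spec.psd[0], params)
    assert not act.action_detected
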