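"""Second-pass detection and amplitude estimation in physical units."""

import numpy as np
import pytest

from _oracles import rotation_amplitude_time_domain
from tremorkit import (
    ActionMeasure,
    RecordingTooShortError,
    StageOrderError,
    SyntheticScenario,
    population_fallback,
    quantify_segment,
    run_subject,
    simulate_recording,
)
from conftest import run_scenario


def _empty_slices():
    f = np.linspace(0.0, 64.0, 129)
    return (f, np.zeros_like(f)), (f, np.zeros_like(f))


def test_no_qualifying_peak_yields_no_detection(params):
    accel_slice, gyro_slice = _empty_slices()
    est = quantify_segment(
        [], accel_slice, gyro_slice,
        ActionMeasure(0.0, False), population_fallback(params), params,
    )
    assert not est.detected
    assert est.a_r_deg == 0.0 and est.a_p_cm == 0.0
    assert est.rho == 0.0 and est.source == ""


def test_missing_bounds_is_a_stage_ordering_violation(params):
    accel_slice, gyro_slice = _empty_slices()
    with pytest.raises(StageOrderError):
        quantify_segment([], accel_slice, gyro_slice, ActionMeasure(0.0, False), None, params)


def test_rotational_amplitude_recovered_within_five_hundredths_degree(rotation_run):
    _, _, _, rec_report, report = rotation_run
    assert rec_report.n_detected == len(rec_report.estimates)
    assert abs(rec_report.median_a_r_deg - 1.0) < 0.05
    assert report.bounds.f_l <= 5.0 <= report.bounds.f_u


def test_translational_amplitude_recovered_within_two_hundredths_cm(translation_run):
    _, _, _, rec_report, report = translation_run
    assert rec_report.n_detected == len(rec_report.estimates)
    assert abs(rec_report.median_a_p_cm - 0.5) < 0.02


def test_amplitude_estimate_is_linear_in_true_amplitude():
    for freq in (4.0, 6.4):
        _, _, _, r1, _ = run_scenario(rot_amp_deg=1.0, rot_freq=freq, seed=21)
        _, _, _, r2, _ = run_scenario(rot_amp_deg=2.0, rot_freq=freq, seed=21)
        assert r2.median_a_r_deg / r1.median_a_r_deg == pytest.approx(2.0, rel=0.02)


def test_estimated_frequency_within_one_grid_bin():
    for f0 in (4.3, 5.57, 6.21):
        _, _, _, rec_report, report = run_scenario(rot_amp_deg=1.0, rot_freq=f0, seed=22)
        freqs = [e.tremor_freq for e in rec_report.estimates if e.detected]
        bin_hz = 0.0625
        assert abs(np.median(freqs) - f0) < bin_hz


def test_voluntary_movement_confounder_changes_rotation_by_under_ten_percent():
    _, _, _, clean, _ = run_scenario(rot_amp_deg=1.0, rot_freq=5.0, seed=23)
    _, _, _, conf, _ = run_scenario(
        rot_amp_deg=1.0, rot_freq=5.0, seed=23, confound_rms_cm=5.0, confound_freq=1.0
    )
    assert abs(conf.median_a_r_deg - clean.median_a_r_deg) / clean.median_a_r_deg < 0.10
    # the confounder itself is flagged as action
    assert any(e.action_detected for e in conf.estimates)
    assert not any(e.action_detected for e in clean.estimates)


def test_pipeline_matches_time_domain_envelope_oracle():
    """Spectral amplitudes agree with band-pass + integrate + Hilbert-envelope."""
    rng = np.random.default_rng(99)
    rel_errs = []
    for _ in range(100):
        amp = float(rng.uniform(0.3, 5.0))
        f0 = float(rng.uniform(4.2, 7.0))
        scn = SyntheticScenario(
            rot_amp_deg=amp, rot_freq=f0, duration=10.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        rec, _ = simulate_recording(scn)
        report = run_subject([rec])
        est = report.recordings[0].median_a_r_deg
        oracle = rotation_amplitude_time_domain(rec, f0 - 1.5, f0 + 1.5)
        rel_errs.append(abs(est - oracle) / oracle)
    assert np.max(rel_errs) < 0.05


def test_session_pools_tasks_into_one_band():
    recs = []
    for task, seed in (("postural", 31), ("kinetic", 32), ("wingbeat", 33)):
        scn = SyntheticScenario(rot_amp_deg=2.0, rot_freq=5.2, seed=seed, task=task)
        rec, _ = simulate_recording(scn)
        recs.append(rec)
    report = run_subject(recs, subject="sim-01")
    assert report.bounds.f_l <= 5.2 <= report.bounds.f_u
    assert not report.bounds.is_fallback
    for r in report.recordings:
        assert abs(r.median_a_r_deg - 2.0) < 0.05
    assert report.any_tremor
    # summary statistics are recomputable from the segment lists
    r0 = report.recordings[0]
    vals = [e.a_r_deg for e in r0.estimates if e.a_r_deg > 0]
    assert r0.median_a_r_deg == pytest.approx(float(np.median(vals)))
    assert r0.max_a_r_deg == pytest.approx(float(np.max(vals)))


def test_tremor_free_session_reports_no_tremor():
    recs = [simulate_recording(SyntheticScenario(seed=s))[0] for s in (41, 42)]
    report = run_subject(recs)
    assert report.bounds.is_fallback
    assert not report.any_tremor
    assert all(e.a_r_deg == 0.0 and e.a_p_cm == 0.0
               for r in report.recordings for e in r.estimates)


def test_slow_rhythmic_movement_alone_triggers_nothing():
    """A 2 Hz voluntary oscillation is below the tremor band: no detections."""
    recs = [
        simulate_recording(
            SyntheticScenario(confound_rms_cm=5.0, confound_freq=2.0, seed=s)
        )[0]
        for s in (51, 52)
    ]
    report = run_subject(recs)
    assert not report.any_tremor
    # but it does register as action
    assert any(e.action_detected for r in report.recordings for e in r.estimates)


def test_all_recordings_too_short_is_unusable():
    rec, _ = simulate_recording(SyntheticScenario(duration=3.0, seed=61))
    with pytest.raises(RecordingTooShortError):
        run_subject([rec])


def test_zero_summaries_included_when_exclusion_disabled():
    from tremorkit import AlgorithmParams

    rec, _ = simulate_recording(SyntheticScenario(seed=62))  # tremor-free
    report = run_subject([rec], AlgorithmParams(exclude_undetected=False))
    r = report.recordings[0]
    assert r.median_a_r_deg == 0.0 and r.max_a_r_deg == 0.0


def test_report_serialises_to_json_and_frame(tmp_path, rotation_run):
    import json

    *_, report = rotation_run
    path = tmp_path / "report.json"
    report.to_json(path)
    data = json.loads(path.read_text())
    assert set(data) == {"subject", "any_tremor", "frequency_bounds", "recordings", "params"}
    seg = data["recordings"][0]["segments"][0]
    assert {"time_s", "detected", "tremor_freq_hz", "a_r_deg", "a_p_cm",
            "rho", "source", "action_detected", "action_rms_cm"} <= set(seg)
    frame = report.to_frame()
    assert len(frame) == sum(len(r.estimates) for r in report.recordings)
    assert frame["detected"].all()


def test_per_location_bands_estimated_independently():
    from tremorkit import AlgorithmParams

    recs = []
    for loc, f0, seed in (("left-hand", 4.5, 91), ("right-hand", 7.5, 92)):
        scn = SyntheticScenario(rot_amp_deg=2.0, rot_freq=f0, seed=seed, location=loc)
        recs.append(simulate_recording(scn)[0])
    report = run_subject(recs, AlgorithmParams(per_location_bounds=True))
    # each location is quantified against its own band, so both recover
    # their tremor despite the pooled IQR spanning both frequencies
    for r, f0 in zip(report.recordings, (4.5, 7.5)):
        assert r.n_detected == len(r.estimates)
        assert abs(r.median_a_r_deg - 2.0) < 0.05
        freqs = [e.tremor_freq for e in r.estimates if e.detected]
        assert abs(np.median(freqs) - f0) < 0.1
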