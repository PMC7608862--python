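"""Second-pass tremor detection and amplitude estimation in physical units.

For each windowed segment, the spectral peak with the largest power
fraction inside the subject band [f_l, f_u] is the tremor candidate; when
its power fraction exceeds the detection threshold ``rho_d`` tremor is
declared.  Modelling the above-baseline peak power as a sinusoid of
amplitude ``a`` (power a^2/2), the amplitude is

    a = sqrt(2 * integral over [f_b, f_e] of (p(f) - b(f)) df)

and is converted to physical units by frequency-domain integration at the
peak frequency: translational displacement a_p = a / (2 pi f)^2 (m -> cm)
for an acceleration-source peak, rotation angle a_r = a / (2 pi f)
(rad -> degrees) for a rotational-velocity-source peak.  Amplitudes are
half peak-to-peak by this sinusoid convention.  When both spectra hold a
qualifying peak, both amplitudes are reported, each at its own frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bounds import FrequencyBounds, estimate_frequency_bounds, population_fallback
from .errors import (
    NoTremorEvidenceError,
    RecordingTooShortError,
    StageOrderError,
    TremorkitError,
)
from .orientation import estimate_orientation, to_earth_frame
from .params import AlgorithmParams
from .peaks import (
    ACCEL,
    GYRO,
    ActionMeasure,
    SpectralPeak,
    action_measure,
    attach_power_fractions,
    best_peak_in_band,
    detect_peaks,
)
from .records import ImuRecording
from .spectral import Spectrogram, acceleration_to_position_psd, compute_spectrogram


@dataclass
class TremorEstimate:
    """Per-segment tremor detection flag and amplitudes."""

    time: float  # segment start, s
    detected: bool
    tremor_freq: float  # Hz; nan when not detected
    a_r_deg: float  # rotational amplitude, degrees (0 when no gyro peak)
    a_p_cm: float  # translational amplitude, cm (0 when no accel peak)
    rho: float  # power fraction of the winning peak (0 when none)
    source: str  # spectrum the winning peak came from ("" when none)
    action_detected: bool
    action_rms_cm: float


@dataclass
class RecordingAnalysis:
    """Stage-1 products for one recording, reused by the second pass."""

    location: str
    task: str
    accel_spec: Spectrogram
    gyro_spec: Spectrogram
    pos_spec: Spectrogram
    peaks: list[list[SpectralPeak]]  # per segment, both sources pooled
    nyquist: float


@dataclass
class RecordingReport:
    location: str
    task: str
    estimates: list[TremorEstimate]
    median_a_r_deg: float | None = None
    max_a_r_deg: float | None = None
    median_a_p_cm: float | None = None
    max_a_p_cm: float | None = None
    n_detected: int = 0


@dataclass
class SubjectReport:
    """Full output of the two-pass pipeline for one subject session."""

    bounds: FrequencyBounds
    recordings: list[RecordingReport]
    params: dict = field(default_factory=dict)
    subject: str = "unknown"

    @property
    def any_tremor(self) -> bool:
        return any(r.n_detected > 0 for r in self.recordings)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-segment table (one row per windowed segment)."""
        rows = []
        for rec in self.recordings:
            for est in rec.estimates:
                rows.append(
                    {
                        "location": rec.location,
                        "task": rec.task,
                        "time_s": est.time,
                        "detected": est.detected,
                        "tremor_freq_hz": est.tremor_freq,
                        "a_r_deg": est.a_r_deg,
                        "a_p_cm": est.a_p_cm,
                        "rho": est.rho,
                        "source": est.source,
                        "action_detected": est.action_detected,
                        "action_rms_cm": est.action_rms_cm,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "any_tremor": self.any_tremor,
            "frequency_bounds": {
                "f_l_hz": self.bounds.f_l,
                "f_u_hz": self.bounds.f_u,
                "j25_freq_hz": _none_if_nan(self.bounds.j25_freq),
                "j75_freq_hz": _none_if_nan(self.bounds.j75_freq),
                "n_peaks_used": self.bounds.n_peaks_used,
                "is_population_fallback": self.bounds.is_fallback,
            },
            "recordings": [
                {
                    "location": r.location,
                    "task": r.task,
                    "n_segments": len(r.estimates),
                    "n_detected": r.n_detected,
                    "median_a_r_deg": r.median_a_r_deg,
                    "max_a_r_deg": r.max_a_r_deg,
                    "median_a_p_cm": r.median_a_p_cm,
                    "max_a_p_cm": r.max_a_p_cm,
                    "segments": [
                        {
                            "time_s": e.time,
                            "detected": e.detected,
                            "tremor_freq_hz": _none_if_nan(e.tremor_freq),
                            "a_r_deg": e.a_r_deg,
                            "a_p_cm": e.a_p_cm,
                            "rho": e.rho,
                            "source": e.source,
                            "action_detected": e.action_detected,
                            "action_rms_cm": e.action_rms_cm,
                        }
                        for e in r.estimates
                    ],
                }
                for r in self.recordings
            ],
            "params": self.params,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------- Stage 1


def analyze_recording(rec: ImuRecording, params: AlgorithmParams) -> RecordingAnalysis:
    """Stage 1 for one recording: orientation, spectra and candidate peaks."""
    n_trim = min(int(round(params.trim_s * rec.sample_rate)), rec.n_samples - 1)
    if rec.duration - n_trim / rec.sample_rate < params.window_s:
        raise RecordingTooShortError(
            f"{rec.duration:.1f} s leaves less than one {params.window_s} s window after trimming"
        )
    # the attitude filter settles during the trimmed lead-in
    q = estimate_orientation(rec, tau_s=params.ahrs_tau_s, accel_gate=params.ahrs_accel_gate)
    accel_earth = to_earth_frame(rec, q)[n_trim:]
    trimmed = rec.trimmed(params.trim_s)

    common = dict(
        sample_rate=trimmed.sample_rate,
        window_s=params.window_s,
        hop_s=params.hop_s,
        lag_fraction=params.lag_fraction,
        max_bin_hz=params.max_bin_hz,
        t0=float(trimmed.time[0]),
    )
    accel_spec = compute_spectrogram(accel_earth, kind=ACCEL, **common)
    gyro_spec = compute_spectrogram(trimmed.gyro, kind=GYRO, **common)
    # the action measure needs resolution down to ~0.3 Hz: its own, longer
    # window (clipped to the recording), converted to a position PSD
    act_common = dict(common, window_s=min(params.action_window_s, trimmed.duration))
    pos_spec = acceleration_to_position_psd(
        compute_spectrogram(accel_earth, kind=ACCEL, **act_common),
        f_pos_min=params.f_pos_min,
    )

    seg_peaks: list[list[SpectralPeak]] = []
    for i in range(accel_spec.n_segments):
        pk = detect_peaks(accel_spec.freqs, accel_spec.psd[i], params.max_peak_width, ACCEL, i)
        attach_power_fractions(pk, accel_spec.freqs, accel_spec.psd[i], params)
        pg = detect_peaks(gyro_spec.freqs, gyro_spec.psd[i], params.max_peak_width, GYRO, i)
        attach_power_fractions(pg, gyro_spec.freqs, gyro_spec.psd[i], params)
        seg_peaks.append(pk + pg)

    return RecordingAnalysis(
        location=rec.location,
        task=rec.task,
        accel_spec=accel_spec,
        gyro_spec=gyro_spec,
        pos_spec=pos_spec,
        peaks=seg_peaks,
        nyquist=trimmed.sample_rate / 2.0,
    )


# --------------------------------------------------------------- Stage 3


def peak_amplitude(
    peak: SpectralPeak, freqs: np.ndarray, psd: np.ndarray
) -> tuple[float, float]:
    """Sinusoid amplitude (signal units) and refined frequency of a peak.

    The amplitude is sqrt(2x) the trapezoid integral of the baseline-clipped
    PSD over the peak; the frequency is the power-weighted centroid of the
    same mass, which locates the underlying sinusoid far below the grid
    spacing (the spectral window is symmetric about the true frequency).
    """
    freqs = np.asarray(freqs, float)
    p = np.asarray(psd, float)
    sl = slice(peak.i_b, peak.i_e + 1)
    above = np.clip(p[sl] - peak.baseline(freqs[sl]), 0.0, None)
    area = float(np.trapezoid(above, freqs[sl]))
    if area <= 0.0:
        return 0.0, peak.f_peak
    f_hat = float(np.trapezoid(freqs[sl] * above, freqs[sl]) / area)
    return math.sqrt(2.0 * area), f_hat


def quantify_segment(
    peaks: list[SpectralPeak],
    accel_slice: tuple[np.ndarray, np.ndarray],
    gyro_slice: tuple[np.ndarray, np.ndarray],
    action: ActionMeasure,
    bounds: FrequencyBounds,
    params: AlgorithmParams,
    time: float = 0.0,
) -> TremorEstimate:
    """Quantify one windowed segment against the subject band.

    ``accel_slice`` / ``gyro_slice`` are (freqs, psd) of this segment for
    each spectrum, needed to re-integrate the winning peaks.
    """
    if bounds is None:
        raise StageOrderError("subject frequency bounds must be estimated before Stage 3")
    best = best_peak_in_band(peaks, bounds.f_l, bounds.f_u)
    detected = best is not None and best.rho > params.rho_d
    a_r = a_p = 0.0
    freq = float("nan")
    rho = 0.0
    source = ""
    if detected:
        rho = best.rho
        source = best.source
        accel_best = best_peak_in_band(
            [p for p in peaks if p.source == ACCEL], bounds.f_l, bounds.f_u
        )
        gyro_best = best_peak_in_band(
            [p for p in peaks if p.source == GYRO], bounds.f_l, bounds.f_u
        )
        if accel_best is not None and accel_best.rho > params.rho_d:
            a, f_hat = peak_amplitude(accel_best, *accel_slice)
            _check_freq(f_hat, params)
            a_p = 100.0 * a / (2.0 * math.pi * f_hat) ** 2
            if best.source == ACCEL:
                freq = f_hat
        if gyro_best is not None and gyro_best.rho > params.rho_d:
            a, f_hat = peak_amplitude(gyro_best, *gyro_slice)
            _check_freq(f_hat, params)
            a_r = math.degrees(a / (2.0 * math.pi * f_hat))
            if best.source == GYRO:
                freq = f_hat
    return TremorEstimate(
        time=time,
        detected=detected,
        tremor_freq=freq,
        a_r_deg=a_r,
        a_p_cm=a_p,
        rho=rho,
        source=source,
        action_detected=action.action_detected,
        action_rms_cm=action.p_a_rms_cm,
    )


def _check_freq(f_hat: float, params: AlgorithmParams) -> None:
    if not f_hat > params.f_tremor_min:
        raise TremorkitError(
            f"peak frequency {f_hat:.2f} Hz at or below the tremor floor; "
            "band gating should make this impossible"
        )


def quantify_analysis(
    analysis: RecordingAnalysis, bounds: FrequencyBounds, params: AlgorithmParams
) -> RecordingReport:
    """Stage 3 over every segment of one analysed recording."""
    estimates = []
    seg_centers = analysis.accel_spec.seg_times + analysis.accel_spec.window_s / 2.0
    act_centers = analysis.pos_spec.seg_times + analysis.pos_spec.window_s / 2.0
    for i in range(analysis.accel_spec.n_segments):
        j = int(np.argmin(np.abs(act_centers - seg_centers[i])))
        act = action_measure(analysis.pos_spec.freqs, analysis.pos_spec.psd[j], params)
        est = quantify_segment(
            analysis.peaks[i],
            (analysis.accel_spec.freqs, analysis.accel_spec.psd[i]),
            (analysis.gyro_spec.freqs, analysis.gyro_spec.psd[i]),
            act,
            bounds,
            params,
            time=float(analysis.accel_spec.seg_times[i]),
        )
        estimates.append(est)
    report = RecordingReport(
        location=analysis.location, task=analysis.task, estimates=estimates
    )
    _summarise(report, params)
    return report


def _summarise(report: RecordingReport, params: AlgorithmParams) -> None:
    report.n_detected = sum(e.detected for e in report.estimates)
    for attr, key in (("a_r_deg", "a_r_deg"), ("a_p_cm", "a_p_cm")):
        values = [getattr(e, attr) for e in report.estimates if getattr(e, attr) > 0.0]
        if not params.exclude_undetected:
            values = [getattr(e, attr) for e in report.estimates]
        if values:
            setattr(report, f"median_{key}", float(np.median(values)))
            setattr(report, f"max_{key}", float(np.max(values)))


# ------------------------------------------------------------- full pipeline


def run_subject(
    recordings: list[ImuRecording],
    params: AlgorithmParams | None = None,
    subject: str = "unknown",
) -> SubjectReport:
    """Run the full two-pass pipeline on a subject's session.

    Stage 1 analyses every recording (orientation, spectra, candidate peaks
    with power fractions, population-band gate); Stage 2 pools all peaks to
    estimate the subject band; Stage 3 re-scans every segment against that
    band and reports detection flags and amplitudes.  Deterministic given
    inputs and parameters.
    """
    if params is None:
        params = AlgorithmParams()
    if not recordings:
        raise TremorkitError("need at least one recording")
    analyses = []
    for rec in recordings:
        try:
            analyses.append(analyze_recording(rec, params))
        except RecordingTooShortError:
            continue
    if not analyses:
        raise RecordingTooShortError("every recording is shorter than one analysis window")

    pooled = [pk for an in analyses for seg in an.peaks for pk in seg]
    nyquist = min(an.nyquist for an in analyses)
    try:
        bnds = estimate_frequency_bounds(pooled, params, nyquist=nyquist)
    except NoTremorEvidenceError:
        bnds = population_fallback(params)

    if params.per_location_bounds:
        # optional variant: each sensor location votes only for itself;
        # the report header still carries the subject-wide band
        per_loc: dict[str, FrequencyBounds] = {}
        for an in analyses:
            if an.location not in per_loc:
                loc_peaks = [
                    pk
                    for other in analyses
                    if other.location == an.location
                    for seg in other.peaks
                    for pk in seg
                ]
                try:
                    per_loc[an.location] = estimate_frequency_bounds(
                        loc_peaks, params, nyquist=nyquist
                    )
                except NoTremorEvidenceError:
                    per_loc[an.location] = population_fallback(params)
        reports = [quantify_analysis(an, per_loc[an.location], params) for an in analyses]
    else:
        reports = [quantify_analysis(an, bnds, params) for an in analyses]
    return SubjectReport(
        bounds=bnds, recordings=reports, params=params.to_dict(), subject=subject
    )


def _none_if_nan(x: float):
    return None if x != x else x
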