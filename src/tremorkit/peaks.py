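"""Spectral-peak detection, baselines, power fractions and action detection.

A candidate peak is seeded at every interior local maximum of a PSD slice
and its bounds are expanded outward, one bin at a time (the side with the
higher adjacent PSD first), until the first of three stopping criteria:

1. the maximum allowed peak width is reached;
2. both ends have reached their local minima;
3. the PSD drops below the straight line connecting the current endpoint
   values (the chord), indicating the expansion has crossed into a
   neighbouring structure.

The straight line through the final endpoints is the peak's baseline
``b(f)``: it models broadband, non-tremor activity concurrent with the
peak, and only power above it is attributed to the peak.  The power
fraction ``rho`` normalises that above-baseline power by the larger of the
total power above the tremor floor and a minimum-significant-movement
floor, so negligible peaks score ~0 even in quiet recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AlgorithmParams

ACCEL = "acceleration"
GYRO = "rotational-velocity"


@dataclass
class SpectralPeak:
    """One detected spectral peak in a single PSD segment."""

    f_peak: float  # Hz, location of the local maximum
    f_b: float  # Hz, peak start
    f_e: float  # Hz, peak end
    baseline_b: float  # PSD value at f_b (baseline endpoint)
    baseline_e: float  # PSD value at f_e
    rho: float = 0.0  # power fraction, dimensionless
    source: str = ACCEL
    segment: int = 0
    i_peak: int = 0  # grid indices, for exact re-integration downstream
    i_b: int = 0
    i_e: int = 0

    def baseline(self, f: np.ndarray) -> np.ndarray:
        """Straight-line baseline b(f) evaluated on ``f``."""
        return np.interp(f, [self.f_b, self.f_e], [self.baseline_b, self.baseline_e])


def detect_peaks(
    freqs: np.ndarray,
    psd: np.ndarray,
    max_peak_width: float,
    source: str = ACCEL,
    segment: int = 0,
) -> list[SpectralPeak]:
    """Detect all spectral peaks in one PSD slice.

    Every strict interior local maximum spawns a candidate whose bounds are
    expanded per the three stopping criteria above.  Peaks at all
    frequencies are returned; band filtering happens downstream.
    """
    freqs = np.asarray(freqs, float)
    p = np.asarray(psd, float)
    n = p.size
    peaks: list[SpectralPeak] = []
    for k in range(1, n - 1):
        if not (p[k - 1] < p[k] and p[k] > p[k + 1]):
            continue
        b, e = _expand_bounds(freqs, p, k, max_peak_width)
        peaks.append(
            SpectralPeak(
                f_peak=float(freqs[k]),
                f_b=float(freqs[b]),
                f_e=float(freqs[e]),
                baseline_b=float(p[b]),
                baseline_e=float(p[e]),
                source=source,
                segment=segment,
                i_peak=k,
                i_b=b,
                i_e=e,
            )
        )
    return peaks


def _expand_bounds(freqs: np.ndarray, p: np.ndarray, k: int, max_width: float) -> tuple[int, int]:
    """Expand [b, e] outward from local maximum ``k`` until a stop criterion."""
    n = p.size
    b = e = k
    while True:
        can_left = b > 0 and p[b - 1] < p[b]  # still descending leftward
        can_right = e < n - 1 and p[e + 1] < p[e]
        if not can_left and not can_right:
            return b, e  # criterion 2: both ends at local minima
        if can_left and can_right:
            go_left = p[b - 1] >= p[e + 1]
        else:
            go_left = can_left
        nb, ne = (b - 1, e) if go_left else (b, e + 1)
        if freqs[ne] - freqs[nb] > max_width:
            return b, e  # criterion 1: width limit
        if _dips_below_chord(freqs, p, nb, ne):
            return b, e  # criterion 3: PSD falls under the endpoint chord
        b, e = nb, ne


def _dips_below_chord(freqs: np.ndarray, p: np.ndarray, b: int, e: int) -> bool:
    if e - b < 2:
        return False
    inner = slice(b + 1, e)
    chord = p[b] + (p[e] - p[b]) * (freqs[inner] - freqs[b]) / (freqs[e] - freqs[b])
    return bool(np.any(p[inner] < chord))


def power_fraction(
    peak: SpectralPeak,
    freqs: np.ndarray,
    psd: np.ndarray,
    params: AlgorithmParams,
) -> float:
    """Power fraction rho of a peak within its PSD slice.

    rho = integral over [f_b, f_e] of (p - b)+  /  max(p_min, integral of p
    over f > f_tremor_min); trapezoid integrals on the grid, numerator
    clipped at zero where the baseline exceeds the PSD.  The denominator
    floor ``p_min`` is taken for the peak's own source spectrum.
    """
    freqs = np.asarray(freqs, float)
    p = np.asarray(psd, float)
    sl = slice(peak.i_b, peak.i_e + 1)
    above = np.clip(p[sl] - peak.baseline(freqs[sl]), 0.0, None)
    numerator = float(np.trapezoid(above, freqs[sl]))
    tail = freqs > params.f_tremor_min
    total = float(np.trapezoid(p[tail], freqs[tail])) if np.count_nonzero(tail) >= 2 else 0.0
    p_min = params.p_min_gyro if peak.source == GYRO else params.p_min_accel
    return numerator / max(p_min, total)


def attach_power_fractions(
    peaks: list[SpectralPeak],
    freqs: np.ndarray,
    psd: np.ndarray,
    params: AlgorithmParams,
) -> list[SpectralPeak]:
    """Compute and store rho on each peak; returns the same list."""
    for pk in peaks:
        pk.rho = power_fraction(pk, freqs, psd, params)
    return peaks


def best_peak_in_band(
    peaks: list[SpectralPeak], f_l: float, f_u: float
) -> SpectralPeak | None:
    """Peak with the largest power fraction whose apex lies in [f_l, f_u].

    Candidates may come from either the acceleration or the
    rotational-velocity spectrum.  Ties break toward the lower frequency
    (less likely to be a harmonic).
    """
    in_band = [p for p in peaks if f_l <= p.f_peak <= f_u]
    if not in_band:
        return None
    return min(in_band, key=lambda p: (-p.rho, p.f_peak))


@dataclass
class ActionMeasure:
    """RMS displacement in the action band and the detection flag."""

    p_a_rms_cm: float
    action_detected: bool


def action_measure(
    freqs: np.ndarray, position_psd: np.ndarray, params: AlgorithmParams
) -> ActionMeasure:
    """Detect non-tremor activity from the position PSD of one segment.

    The RMS displacement is the square root of the position-PSD integral
    over the action band [f_action_min, f_action_max]; action is declared
    when it exceeds ``action_threshold_cm``.
    """
    freqs = np.asarray(freqs, float)
    p = np.asarray(position_psd, float)
    band = (freqs >= params.f_action_min) & (freqs <= params.f_action_max)
    power_m2 = float(np.trapezoid(p[band], freqs[band])) if np.count_nonzero(band) >= 2 else 0.0
    rms_cm = 100.0 * float(np.sqrt(power_m2))
    return ActionMeasure(p_a_rms_cm=rms_cm, action_detected=rms_cm > params.action_threshold_cm)
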