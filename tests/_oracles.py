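"""Independent reference implementations used only by the test suite.

These deliberately re-derive results by the most naive route available —
explicit Python loops, time-domain signal processing — so that agreement
with the package is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.integrate import cumulative_trapezoid


def expand_peak_bruteforce(freqs, p, k, max_width):
    """Step-by-step peak-bound expansion with explicit loops.

    Mirrors the three stopping rules: width cap, both ends at local
    minima, and any interior sample falling under the endpoint chord.
    """
    b = e = k
    n = len(p)
    while True:
        left_ok = b > 0 and p[b - 1] < p[b]
        right_ok = e < n - 1 and p[e + 1] < p[e]
        if not left_ok and not right_ok:
            return b, e
        if left_ok and right_ok:
            side = "L" if p[b - 1] >= p[e + 1] else "R"
        else:
            side = "L" if left_ok else "R"
        cb, ce = (b - 1, e) if side == "L" else (b, e + 1)
        if freqs[ce] - freqs[cb] > max_width:
            return b, e
        dips = False
        for j in range(cb + 1, ce):
            chord = p[cb] + (p[ce] - p[cb]) * (freqs[j] - freqs[cb]) / (freqs[ce] - freqs[cb])
            if p[j] < chord:
                dips = True
        if dips:
            return b, e
        b, e = cb, ce


def local_maxima(p):
    """Indices of strict interior local maxima, by explicit comparison."""
    return [k for k in range(1, len(p) - 1) if p[k - 1] < p[k] > p[k + 1]]


def power_fraction_trapezoid(freqs, p, i_b, i_e, f_tremor_min, p_min):
    """Direct trapezoid evaluation of the power-fraction definition."""
    f_seg = freqs[i_b : i_e + 1]
    chord = np.interp(f_seg, [freqs[i_b], freqs[i_e]], [p[i_b], p[i_e]])
    numerator = np.trapezoid(np.clip(p[i_b : i_e + 1] - chord, 0.0, None), f_seg)
    tail = freqs > f_tremor_min
    total = np.trapezoid(p[tail], freqs[tail])
    return numerator / max(p_min, total)


def rotation_amplitude_time_domain(rec, f_lo, f_hi, edge_s=2.0):
    """Rotational tremor amplitude (degrees) estimated in the time domain.

    Band-pass the gyroscope, project onto its principal axis, integrate to
    angle, and take the median Hilbert envelope away from filter edges.
    """
    fs = rec.sample_rate
    sos = butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    g = sosfiltfilt(sos, rec.gyro, axis=0)
    _, _, vt = np.linalg.svd(g - g.mean(axis=0), full_matrices=False)
    w = g @ vt[0]
    theta = cumulative_trapezoid(w, dx=1.0 / fs, initial=0.0)
    theta -= theta.mean()
    env = np.abs(hilbert(theta))
    k = int(edge_s * fs)
    return float(np.degrees(np.median(env[k:-k])))


def random_psd(rng, n):
    """A rough random PSD slice: broadband floor plus a few random bumps."""
    f = np.arange(n) * 0.25
    p = rng.uniform(0.05, 0.5, size=n)
    for _ in range(rng.integers(0, 4)):
        f0 = rng.uniform(f[1], f[-2])
        width = rng.uniform(0.3, 2.0)
        height = rng.uniform(0.5, 5.0)
        p += height * np.exp(-0.5 * ((f - f0) / width) ** 2)
    return f, p
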