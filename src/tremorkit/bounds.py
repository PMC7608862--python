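"""Subject-specific tremor frequency band from pooled spectral peaks.

All candidate peaks from all of a subject's recordings, segments and
sensors (acceleration and rotational-velocity spectra pooled) vote for the
subject's tremor band through a power-fraction-weighted interquartile
range: peaks are sorted by frequency, their power fractions cumulated and
normalised, and the frequencies where the cumulative weight crosses 25%
and 75% — padded outward by ``delta_f`` — become the subject band
[f_l, f_u].  The weighted IQR makes the band insensitive to occasional
spurious detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoTremorEvidenceError
from .params import AlgorithmParams
from .peaks import SpectralPeak


@dataclass
class FrequencyBounds:
    """Subject tremor band [f_l, f_u] and the quartile frequencies behind it."""

    f_l: float
    f_u: float
    j25_freq: float
    j75_freq: float
    n_peaks_used: int
    is_fallback: bool = False  # True when the population band was substituted


def estimate_frequency_bounds(
    all_peaks: list[SpectralPeak],
    params: AlgorithmParams,
    nyquist: float | None = None,
) -> FrequencyBounds:
    """Estimate the subject tremor band from pooled candidate peaks.

    Peaks are kept when rho > rho_min and the apex lies inside the
    population band [f_lo_pop, f_hi_pop].  With weights w_j the normalised
    cumulative power fractions in order of increasing frequency, the 25th
    percentile index is the largest j with w_j < 0.25 (the first peak when
    none qualifies) and the 75th the smallest j with w_j > 0.75 (the last
    peak when none qualifies).  The band is the corresponding frequencies
    padded by delta_f, clipped to [f_tremor_min, Nyquist].

    Raises
    ------
    NoTremorEvidenceError
        When no peak qualifies; callers fall back to the population band.
    """
    kept = [
        p
        for p in all_peaks
        if p.rho > params.rho_min and params.f_lo_pop <= p.f_peak <= params.f_hi_pop
    ]
    if not kept:
        raise NoTremorEvidenceError(
            "no spectral peak exceeds rho_min inside the population band"
        )
    order = sorted(kept, key=lambda p: p.f_peak)
    f = np.array([p.f_peak for p in order])
    rho = np.array([p.rho for p in order])
    w = np.cumsum(rho) / rho.sum()

    # strict inequalities, with an epsilon so that a weight landing exactly
    # on a quartile (up to rounding) is treated as "not beyond" it
    below = np.nonzero(w < 0.25 - 1e-9)[0]
    j25 = int(below[-1]) if below.size else 0
    above = np.nonzero(w > 0.75 + 1e-9)[0]
    j75 = int(above[0]) if above.size else len(w) - 1

    f_l = f[j25] - params.delta_f
    f_u = f[j75] + params.delta_f
    f_l = max(f_l, params.f_tremor_min)
    if nyquist is not None:
        f_u = min(f_u, nyquist)
    return FrequencyBounds(
        f_l=float(f_l),
        f_u=float(f_u),
        j25_freq=float(f[j25]),
        j75_freq=float(f[j75]),
        n_peaks_used=len(order),
    )


def population_fallback(params: AlgorithmParams) -> FrequencyBounds:
    """Population-band bounds used when a subject shows no tremor evidence."""
    return FrequencyBounds(
        f_l=params.f_lo_pop,
        f_u=params.f_hi_pop,
        j25_freq=float("nan"),
        j75_freq=float("nan"),
        n_peaks_used=0,
        is_fallback=True,
    )
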