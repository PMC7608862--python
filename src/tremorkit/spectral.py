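"""Sliding-window channel-summed Blackman-Tukey spectrograms.

Each window of the 3-channel signal is mean-removed, tapered with a
Blackman window, and its biased autocorrelation is re-tapered with a
Blackman lag window before Fourier transforming — the classic
Blackman-Tukey (correlogram) PSD estimate.  Per-channel PSDs are summed:
the sum of channel autocorrelations is the trace of the autocorrelation
matrix, which is invariant under any fixed rotation of the channels, so
the summed PSD does not depend on how the sensor is oriented on the body.

Frequency-domain integration converts the acceleration PSD to a position
PSD by dividing by (2 pi f)^4 (two integrations, squared because these are
power densities); bins below a configurable floor are zeroed to avoid the
f -> 0 singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal.windows import blackman

from .errors import RecordingTooShortError, TremorkitError


@dataclass
class Spectrogram:
    """Channel-summed PSD slices of one signal.

    Attributes
    ----------
    seg_times : ndarray (n_seg,)
        Start time of each window, seconds.
    freqs : ndarray (n_f,)
        Uniform frequency grid from 0 to Nyquist, Hz.
    psd : ndarray (n_seg, n_f)
        One-sided PSD per segment, signal-units^2/Hz, non-negative;
        integrating a segment over frequency recovers its variance.
    kind : str
        ``"acceleration"``, ``"rotational-velocity"`` or ``"position"``.
    window_s, hop_s : float
        Analysis window length and hop, seconds.
    """

    seg_times: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray
    kind: str
    window_s: float
    hop_s: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_segments(self) -> int:
        return self.psd.shape[0]

    def to_frame(self):
        """Long-format DataFrame (segment, frequency, psd) for debugging."""
        import pandas as pd

        n_seg, n_f = self.psd.shape
        return pd.DataFrame(
            {
                "segment_time_s": np.repeat(self.seg_times, n_f),
                "frequency_hz": np.tile(self.freqs, n_seg),
                "psd": self.psd.ravel(),
            }
        )


def compute_spectrogram(
    signal: np.ndarray,
    sample_rate: float,
    window_s: float = 5.0,
    hop_s: float = 1.0,
    kind: str = "acceleration",
    lag_fraction: float = 1.0,
    max_bin_hz: float = 0.0625,
    t0: float = 0.0,
) -> Spectrogram:
    """Sliding-window channel-summed Blackman-Tukey PSD of a multichannel signal.

    Parameters
    ----------
    signal : ndarray (n,) or (n, c)
        Time series; channels are summed in the PSD domain.
    sample_rate : float
        Hz.
    window_s, hop_s : float
        Window length and hop in seconds.
    lag_fraction : float
        Length of the Blackman lag window as a fraction of the segment;
        1.0 tapers over all lags (least smoothing), smaller values smooth
        the estimate at the cost of resolution.
    max_bin_hz : float
        The FFT is zero-padded to the next power of two giving a grid no
        coarser than this.
    t0 : float
        Time of the first sample (stamps segment start times).
    """
    x = np.asarray(signal, float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    nwin = int(round(window_s * sample_rate))
    nhop = max(int(round(hop_s * sample_rate)), 1)
    if nwin < 8:
        raise TremorkitError(f"window of {nwin} samples is too short to taper")
    if n < nwin:
        raise RecordingTooShortError(
            f"recording of {n} samples shorter than one {nwin}-sample window"
        )

    dt = 1.0 / sample_rate
    taper = blackman(nwin, sym=False)
    u_power = float(np.mean(taper**2))  # taper power normalisation
    m_lag = max(int(round(lag_fraction * nwin)) - 1, 4)
    m_lag = min(m_lag, nwin - 1)
    lag_win = blackman(2 * m_lag + 1, sym=True)[m_lag:]  # half window, lag_win[0] = 1

    # the grid must be fine enough AND hold the full two-sided lag sequence
    nfft = 1
    while nfft < 2 * m_lag + 2 or sample_rate / nfft > max_bin_hz:
        nfft *= 2
    nfft_ac = 1
    while nfft_ac < 2 * nwin:
        nfft_ac *= 2

    starts = np.arange(0, n - nwin + 1, nhop)
    freqs = np.fft.rfftfreq(nfft, dt)
    psd = np.zeros((len(starts), freqs.size))

    for i, s in enumerate(starts):
        seg = x[s : s + nwin]
        seg = seg - seg.mean(axis=0)
        y = seg * taper[:, None]
        # biased autocorrelation summed over channels (trace form)
        spec = np.fft.rfft(y, nfft_ac, axis=0)
        r = np.fft.irfft((spec * np.conj(spec)).real.sum(axis=1), nfft_ac)[: m_lag + 1] / nwin
        rw = r * lag_win
        # symmetric extension -> real, even correlation sequence
        c = np.zeros(nfft)
        c[: m_lag + 1] = rw
        c[-m_lag:] = rw[1:][::-1]
        s_two = np.fft.rfft(c).real * dt / u_power
        s_one = s_two.copy()
        s_one[1:] *= 2.0
        if nfft % 2 == 0:
            s_one[-1] /= 2.0
        psd[i] = np.maximum(s_one, 0.0)

    return Spectrogram(
        seg_times=t0 + starts * dt,
        freqs=freqs,
        psd=psd,
        kind=kind,
        window_s=nwin * dt,
        hop_s=nhop * dt,
    )


def acceleration_to_position_psd(spec: Spectrogram, f_pos_min: float = 0.25) -> Spectrogram:
    """Convert an acceleration PSD to a position PSD: p_p = p_a / (2 pi f)^4.

    Bins below ``f_pos_min`` (and f = 0) are zeroed — double integration
    diverges as f -> 0 and tremor carries no power there.
    """
    if spec.kind != "acceleration":
        raise TremorkitError(f"expected an acceleration spectrogram, got kind={spec.kind!r}")
    f = spec.freqs
    scale = np.zeros_like(f)
    ok = f >= f_pos_min
    scale[ok] = 1.0 / (2.0 * np.pi * f[ok]) ** 4
    return replace(spec, psd=spec.psd * scale[None, :], kind="position")
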