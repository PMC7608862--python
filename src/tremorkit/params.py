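"""Algorithm parameters and YAML configuration.

All tunables of the two-pass pipeline live in one dataclass so that a run
is fully described by (recordings, params).  Power floors are configured in
physical-amplitude terms (cm of displacement, degrees of rotation at a
reference frequency) because those are the units clinicians reason in; the
equivalent PSD-integral floors are derived properties.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class AlgorithmParams:
    """Key parameters of the tremor-quantification pipeline.

    Spectral estimation
    -------------------
    window_s, hop_s : float
        Sliding-window length and hop, seconds.  5 s gives >= 20 tremor
        cycles at 4 Hz; spectral-peak estimation needs on the order of ten
        oscillations per segment, and the longer window keeps the smeared
        peak narrow enough for accurate amplitude integration.
    lag_fraction : float
        Blackman-Tukey lag-window length as a fraction of the segment
        length.  1.0 applies the lag taper over every available lag, the
        least-smoothed estimate; smaller values trade frequency resolution
        for variance reduction.
    max_bin_hz : float
        Upper bound on frequency-grid spacing; the FFT length is the next
        power of two achieving it.

    Peak detection and power fraction
    ---------------------------------
    f_tremor_min : float
        Smallest frequency (Hz) at which tremor may contain power (the
        ``f_T`` threshold of the power-fraction denominator).
    f_lo_pop, f_hi_pop : float
        Population tremor band used as the first-pass gate (4-12 Hz for
        essential tremor).
    max_peak_width : float
        Maximum allowed spectral-peak width, Hz.  Must exceed the spectral
        width of a pure sinusoid under the chosen window (about 2 x 0.9 Hz
        at the 5 s default) or peak power is truncated.
    p_min_pos_cm, p_min_rot_deg, p_min_ref_hz : float
        Smallest RMS displacement (cm) / rotation (deg) counted as
        significant movement; converted to PSD-integral floors at the
        reference frequency.
    rho_min : float
        Minimum power fraction for a peak to enter subject-band pooling.
    rho_d : float
        Power-fraction detection threshold for declaring tremor.

    Subject band
    ------------
    delta_f : float
        Padding (Hz) added outside the power-fraction-weighted
        interquartile range of peak frequencies.

    Action detection
    ----------------
    f_action_min, f_action_max : float
        Band (Hz) in which voluntary movement dominates.
    action_threshold_cm : float
        RMS displacement above which action is declared.
    f_pos_min : float
        Position-PSD bins below this frequency are zeroed to avoid the
        1/(2 pi f)^4 singularity of frequency-domain double integration.
    action_window_s : float
        Window length (s) of the position spectrogram behind the action
        measure; longer than the tremor window because the action band
        reaches down to ~0.3 Hz and the spectral window must stay narrow
        relative to those frequencies (10 s ~ 3 cycles at 0.3 Hz).
        Clipped to the recording length.

    Orientation
    -----------
    ahrs_tau_s : float
        Time constant (s) of the complementary attitude filter's
        accelerometer tilt correction.
    ahrs_accel_gate : float
        Fractional specific-force-norm window around 1 g inside which the
        tilt correction is trusted; vigorous movement falls outside and is
        ignored by the correction.
    trim_s : float
        Seconds trimmed from the start of each recording to discard the
        attitude filter's settling transient.
    """

    # spectral estimation
    window_s: float = 5.0
    hop_s: float = 1.0
    lag_fraction: float = 1.0
    max_bin_hz: float = 0.0625
    # peak detection / power fraction
    f_tremor_min: float = 1.5
    f_lo_pop: float = 4.0
    f_hi_pop: float = 12.0
    max_peak_width: float = 3.0
    p_min_pos_cm: float = 0.05
    p_min_rot_deg: float = 0.05
    p_min_ref_hz: float = 5.0
    rho_min: float = 0.1
    rho_d: float = 0.2
    # subject band
    delta_f: float = 1.0
    per_location_bounds: bool = False
    # action detection
    f_action_min: float = 0.3
    f_action_max: float = 3.0
    action_threshold_cm: float = 2.0
    f_pos_min: float = 0.25
    action_window_s: float = 10.0
    # orientation
    ahrs_tau_s: float = 2.0
    ahrs_accel_gate: float = 0.3
    trim_s: float = 1.0
    # reporting: drop undetected segments from amplitude summaries instead
    # of counting them as zeros
    exclude_undetected: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.f_tremor_min < self.f_lo_pop < self.f_hi_pop):
            raise ValueError(
                "require 0 < f_tremor_min < f_lo_pop < f_hi_pop, got "
                f"{self.f_tremor_min}, {self.f_lo_pop}, {self.f_hi_pop}"
            )
        if not (0.0 <= self.rho_min <= self.rho_d <= 1.0):
            raise ValueError(f"require 0 <= rho_min <= rho_d <= 1, got {self.rho_min}, {self.rho_d}")
        if self.delta_f < 0:
            raise ValueError("delta_f must be >= 0")
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ValueError("window_s and hop_s must be positive")
        if not (0.0 < self.lag_fraction <= 1.0):
            raise ValueError("lag_fraction must be in (0, 1]")
        if self.max_peak_width <= 0:
            raise ValueError("max_peak_width must be positive")
        if not (0.0 < self.f_action_min < self.f_action_max):
            raise ValueError("require 0 < f_action_min < f_action_max")
        if self.action_window_s <= 0:
            raise ValueError("action_window_s must be positive")

    # -------------------------------------------------- derived power floors

    @property
    def p_min_accel(self) -> float:
        """PSD-integral floor for the acceleration spectrum, (m/s^2)^2.

        Power of a sinusoidal displacement with RMS ``p_min_pos_cm`` at the
        reference frequency, expressed as acceleration.
        """
        x_rms_m = self.p_min_pos_cm / 100.0
        return (2.0 * math.pi * self.p_min_ref_hz) ** 4 * x_rms_m**2

    @property
    def p_min_gyro(self) -> float:
        """PSD-integral floor for the rotational-velocity spectrum, (rad/s)^2."""
        theta_rms_rad = math.radians(self.p_min_rot_deg)
        return (2.0 * math.pi * self.p_min_ref_hz) ** 2 * theta_rms_rad**2

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AlgorithmParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlgorithmParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
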