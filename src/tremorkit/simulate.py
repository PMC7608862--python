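"""Virtual robot-arm generator for technical validation.

Emulates an industrial arm executing prescribed sinusoidal "tremor": a
rotation of known angular amplitude about a fixed axis and/or a translation
of known displacement amplitude along a fixed Earth axis, with the IMU
rigidly attached.  The emitted :class:`~tremorkit.records.ImuRecording`
contains exactly what an ideal strapdown IMU would measure — body-frame
angular velocity and specific force including gravity as seen from the
rotating sensor — plus additive wideband Gaussian sensor noise, and comes
with the exact orientation and displacement trajectories as ground truth.

A low-frequency sinusoidal displacement confounder emulates voluntary
movement superposed on the tremor.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._quat import from_axis_angle, qconj, qrotate
from .errors import DegenerateInputError
from .records import GRAVITY, ImuRecording

_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class SyntheticScenario:
    """Prescription for one simulated recording.

    Amplitudes follow the package's reporting convention: a sinusoid's
    half peak-to-peak amplitude.  ``confound_rms_cm`` is the RMS (not peak)
    displacement of the voluntary-movement confounder, matching how gross
    movement magnitude is usually quoted.
    """

    duration: float = 15.0
    sample_rate: float = 128.0
    rot_amp_deg: float = 0.0
    rot_freq: float = 5.0
    pos_amp_cm: float = 0.0
    pos_freq: float = 5.0
    freq_drift: float = 0.0  # Hz/s, linear drift of both tremor frequencies
    noise_accel: float = 0.02  # m/s^2 RMS per channel
    noise_gyro: float = 0.002  # rad/s RMS per channel
    confound_freq: float = 1.0
    confound_rms_cm: float = 0.0
    base_orientation: tuple = (1.0, 0.0, 0.0, 0.0)  # sensor->earth, (w,x,y,z)
    rot_axis: tuple = (1.0, 0.0, 0.0)  # body frame
    pos_axis: tuple = (0.0, 1.0, 0.0)  # earth frame
    confound_axis: tuple = (1.0, 0.0, 0.0)  # earth frame
    location: str = "right-hand"
    task: str = "robot"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rot_amp_deg < 0 or self.pos_amp_cm < 0 or self.confound_rms_cm < 0:
            raise DegenerateInputError("amplitudes must be non-negative")
        nyq = self.sample_rate / 2.0
        for f, amp in (
            (self.rot_freq, self.rot_amp_deg),
            (self.pos_freq, self.pos_amp_cm),
            (self.confound_freq, self.confound_rms_cm),
        ):
            if amp > 0 and not (0.0 < f < nyq):
                raise DegenerateInputError(
                    f"active component frequency {f} Hz outside (0, Nyquist={nyq} Hz)"
                )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Exact trajectories realised by the virtual arm."""

    orientation: np.ndarray  # (n, 4) sensor->earth quaternions, scalar first
    displacement: np.ndarray  # (n, 3) earth-frame position of the sensor, m
    angle_deg: np.ndarray  # (n,) signed rotation angle about the axis
    scenario: SyntheticScenario

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario.to_dict(),
            "orientation_wxyz": self.orientation.tolist(),
            "displacement_m": self.displacement.tolist(),
            "angle_deg": self.angle_deg.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def simulate_recording(scn: SyntheticScenario) -> tuple[ImuRecording, GroundTruth]:
    """Synthesise the IMU recording and exact ground truth for a scenario.

    The rotation is ``theta(t) = A_r sin(2 pi phi_r(t))`` about a fixed body
    axis starting from ``base_orientation``; translation is
    ``x(t) = A_p sin(2 pi phi_p(t))`` along a fixed Earth axis.  With a
    linear frequency drift ``d``, the phase is ``phi(t) = f0 t + d t^2 / 2``
    and the instantaneous frequency ``f0 + d t``.

    Returns the recording (with noise applied) and the noise-free ground
    truth.
    """
    n = int(round(scn.duration * scn.sample_rate))
    if n < 2:
        raise DegenerateInputError("scenario too short")
    dt = 1.0 / scn.sample_rate
    t = np.arange(n) * dt
    rng = np.random.default_rng(scn.seed)

    axis_r = np.asarray(scn.rot_axis, float)
    axis_r = axis_r / np.linalg.norm(axis_r)
    axis_p = np.asarray(scn.pos_axis, float)
    axis_p = axis_p / np.linalg.norm(axis_p)
    axis_c = np.asarray(scn.confound_axis, float)
    axis_c = axis_c / np.linalg.norm(axis_c)
    q_base = np.asarray(scn.base_orientation, float)
    q_base = q_base / np.linalg.norm(q_base)

    # rotation: angle and exact angular rate about the body-fixed axis
    amp_r = math.radians(scn.rot_amp_deg)
    phase_r = scn.rot_freq * t + 0.5 * scn.freq_drift * t**2
    inst_fr = scn.rot_freq + scn.freq_drift * t
    theta = amp_r * np.sin(2.0 * np.pi * phase_r)
    theta_dot = amp_r * 2.0 * np.pi * inst_fr * np.cos(2.0 * np.pi * phase_r)

    q_gt = _compose(q_base, from_axis_angle(axis_r, theta))

    # translation: displacement and exact acceleration in the earth frame
    amp_p = scn.pos_amp_cm / 100.0
    phase_p = scn.pos_freq * t + 0.5 * scn.freq_drift * t**2
    inst_fp = scn.pos_freq + scn.freq_drift * t
    disp = amp_p * np.sin(2.0 * np.pi * phase_p)[:, None] * axis_p
    acc_e = -amp_p * (2.0 * np.pi * inst_fp) ** 2 * np.sin(2.0 * np.pi * phase_p)
    acc_earth = acc_e[:, None] * axis_p

    if scn.confound_rms_cm > 0:
        amp_c = scn.confound_rms_cm * math.sqrt(2.0) / 100.0
        wc = 2.0 * np.pi * scn.confound_freq
        disp = disp + amp_c * np.sin(wc * t)[:, None] * axis_c
        acc_earth = acc_earth - amp_c * wc**2 * np.sin(wc * t)[:, None] * axis_c

    # ideal strapdown measurements
    gyro = theta_dot[:, None] * axis_r  # body rates: rotation about a body-fixed axis
    specific_force_earth = acc_earth + GRAVITY * _UP
    accel = qrotate(qconj(q_gt), specific_force_earth)

    accel_noisy = accel + rng.normal(0.0, scn.noise_accel, size=accel.shape)
    gyro_noisy = gyro + rng.normal(0.0, scn.noise_gyro, size=gyro.shape)

    rec = ImuRecording(
        time=t,
        accel=accel_noisy,
        gyro=gyro_noisy,
        sample_rate=scn.sample_rate,
        location=scn.location,
        task=scn.task,
    )
    gt = GroundTruth(
        orientation=q_gt,
        displacement=disp,
        angle_deg=np.degrees(theta),
        scenario=scn,
    )
    return rec, gt


def generate_validation_grid(
    freqs: list[float],
    rot_amps_deg: list[float] = (),
    pos_amps_cm: list[float] = (),
    seed: int = 0,
    **overrides,
) -> list[SyntheticScenario]:
    """Cartesian validation grid of pure-rotation and pure-translation runs.

    Mirrors a prescribed-movement bench protocol: every frequency is paired
    with every rotational amplitude (translation off) and every
    translational amplitude (rotation off).  Per-scenario seeds are derived
    deterministically from ``seed`` so the grid is reproducible as a whole.
    """
    if not freqs or (not rot_amps_deg and not pos_amps_cm):
        raise DegenerateInputError("need at least one frequency and one amplitude")
    scenarios: list[SyntheticScenario] = []
    idx = 0
    for f, a in itertools.product(freqs, rot_amps_deg):
        scenarios.append(
            SyntheticScenario(
                rot_amp_deg=a, rot_freq=f, pos_amp_cm=0.0,
                seed=(seed * 7919 + idx) % (2**31 - 1), **overrides,
            )
        )
        idx += 1
    for f, a in itertools.product(freqs, pos_amps_cm):
        scenarios.append(
            SyntheticScenario(
                rot_amp_deg=0.0, pos_amp_cm=a, pos_freq=f,
                seed=(seed * 7919 + idx) % (2**31 - 1), **overrides,
            )
        )
        idx += 1
    return scenarios


def _compose(q_base: np.ndarray, q_series: np.ndarray) -> np.ndarray:
    from ._quat import qmul

    return qmul(q_base[None, :], q_series)
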