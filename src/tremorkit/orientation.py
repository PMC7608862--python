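"""Sensor orientation and gravity-subtracted Earth-frame acceleration.

The attitude filter is a quaternion complementary filter: body rates from
the gyroscope are integrated forward and the tilt component is continuously
nudged toward the direction of the measured specific force, which equals
"up" on average because translational acceleration is zero-mean while
gravity is not.  The correction acts only on tilt (its rotation axis is
horizontal), so yaw is whatever gyro integration yields — arbitrary but
consistent within a recording, which is all the downstream channel-summed
spectra require.  With no magnetometer, North is arbitrary-but-fixed per
recording (right-handed North-West-Up frame).
"""

from __future__ import annotations

import numpy as np

from ._quat import from_rotvec, qmul, qnormalize, qrotate, to_scipy
from .errors import DegenerateInputError, InconsistentInputError
from .records import GRAVITY, ImuRecording

_UP = np.array([0.0, 0.0, 1.0])


def estimate_orientation(
    rec: ImuRecording, tau_s: float = 2.0, accel_gate: float = 0.3
) -> np.ndarray:
    """Estimate the sensor->earth orientation series of a recording.

    Parameters
    ----------
    rec : ImuRecording
    tau_s : float
        Time constant of the accelerometer tilt correction, seconds.  Short
        constants track slow tilt changes aggressively but let high-g
        movement corrupt the estimate; 2 s attenuates tremor-band (>= 4 Hz)
        accelerations by >~ 50x while still absorbing gyro drift.
    accel_gate : float
        The tilt correction is applied only when the specific-force norm is
        within this fraction of gravity — during vigorous movement the
        accelerometer does not point "up" and would drag the estimate away
        (set >= 1e6 to disable the gate).

    Returns
    -------
    ndarray, shape (n, 4)
        Unit quaternions (w, x, y, z), one per sample.
    """
    accel = rec.accel
    gyro = rec.gyro
    n = rec.n_samples
    if n < 2 or rec.duration < 1.0:
        raise DegenerateInputError("need at least 1 s of data to estimate orientation")
    norms = np.linalg.norm(accel, axis=1)
    if not np.any(norms > 1e-6):
        raise DegenerateInputError("all-zero accelerometer input: gravity direction unresolvable")
    dt = rec.dt
    gain = min(dt / tau_s, 1.0)
    lo, hi = GRAVITY * (1.0 - accel_gate), GRAVITY * (1.0 + accel_gate)

    q = _tilt_from_accel(_init_gravity_estimate(accel, norms, int(round(2.0 / dt)), lo, hi))
    out = np.empty((n, 4))
    out[0] = q
    for k in range(1, n):
        # strapdown integration of body rates
        q = qmul(q, from_rotvec(gyro[k] * dt))
        # tilt correction: rotate measured "up" toward earth z.  Confidence
        # fades linearly to zero as the specific-force norm departs from
        # 1 g, so high-acceleration phases cannot drag the tilt estimate.
        na = norms[k]
        if lo < na < hi:
            weight = 1.0 - abs(na - GRAVITY) / (GRAVITY - lo)
            up_meas = qrotate(q, accel[k] / na)
            err = np.cross(up_meas, _UP)  # horizontal axis, |err| = sin(tilt error)
            q = qmul(from_rotvec(gain * weight * err), q)
        q = q / np.linalg.norm(q)
        out[k] = q
    return out


def to_earth_frame(rec: ImuRecording, q: np.ndarray) -> np.ndarray:
    """Rotate specific force into the Earth frame and subtract gravity.

    Returns the translational acceleration (n, 3) in m/s^2; for a static
    recording this is zero up to sensor noise and attitude error.
    """
    q = np.asarray(q, float)
    if q.shape != (rec.n_samples, 4):
        raise InconsistentInputError(
            f"orientation series {q.shape} does not match recording of {rec.n_samples} samples"
        )
    return to_scipy(q).apply(rec.accel) - GRAVITY * _UP


def _tilt_from_accel(a: np.ndarray) -> np.ndarray:
    """Minimal-angle quaternion taking the measured gravity direction to +z."""
    a_hat = a / np.linalg.norm(a)
    axis = np.cross(a_hat, _UP)
    s = np.linalg.norm(axis)
    c = float(np.dot(a_hat, _UP))
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # upside down: 180 degrees about North
        return np.array([0.0, 1.0, 0.0, 0.0])
    angle = np.arctan2(s, c)
    return qnormalize(from_rotvec(axis / s * angle))


def _init_gravity_estimate(
    accel: np.ndarray, norms: np.ndarray, k: int, lo: float, hi: float
) -> np.ndarray:
    """Initial gravity direction from the first ~2 s of accelerometer data.

    Prefers samples whose specific-force norm is close to 1 g: during
    oscillatory movement those are the zero-crossings of the motion
    acceleration, where the accelerometer points exactly up.
    """
    head = accel[: max(k, 1)]
    head_norms = norms[: max(k, 1)]
    in_gate = (head_norms > lo) & (head_norms < hi)
    if np.count_nonzero(in_gate) >= 5:
        return head[in_gate].mean(axis=0)
    valid = head_norms > 1e-6
    if np.any(valid):
        return head[valid].mean(axis=0)
    idx = int(np.argmax(norms > 1e-6))
    return accel[idx]
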