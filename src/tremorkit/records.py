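"""Raw inertial-sensor recordings and their on-disk formats.

An :class:`ImuRecording` holds synchronous triaxial accelerometer (specific
force, m/s^2, sensor frame) and gyroscope (angular velocity, rad/s, sensor
frame) time series at a fixed sample rate, together with the body location
and task labels used downstream to pool evidence per subject.

Two interchange formats are supported:

* columnar CSV (``time,ax,ay,az,gx,gy,gz``) with a YAML sidecar declaring
  units, sample rate and labels — readers refuse unit-less files rather
  than guessing;
* an HDF5 container with one group per sensor location holding ``time``,
  ``accel`` ``[N x 3]`` and ``gyro`` ``[N x 3]`` datasets and metadata
  attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateInputError, InconsistentInputError

#: Standard gravity used throughout the package (m/s^2).
GRAVITY = 9.80665

_CSV_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class ImuRecording:
    """One continuous 6-DOF inertial recording.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Specific force in the sensor frame, m/s^2.  A sensor resting with
        its z axis up reads approximately ``(0, 0, 9.80665)``.
    gyro : ndarray, shape (n, 3)
        Angular velocity in the sensor frame, rad/s.
    sample_rate : float
        Nominal sampling rate in Hz.
    location : str
        Body placement label, e.g. ``"left-hand"``, ``"lumbar"``.
    task : str
        Task label, e.g. ``"postural"``, ``"wingbeat"``.
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float
    location: str = "unknown"
    task: str = "unknown"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.accel.shape != self.gyro.shape or self.accel.shape[1] != 3:
            raise InconsistentInputError(
                f"accel {self.accel.shape} and gyro {self.gyro.shape} must both be (n, 3)"
            )
        if self.time.shape[0] != self.accel.shape[0]:
            raise InconsistentInputError(
                f"time has {self.time.shape[0]} samples, accel has {self.accel.shape[0]}"
            )
        if not self.sample_rate > 0:
            raise DegenerateInputError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise InconsistentInputError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / sample_rate)."""
        return self.n_samples / self.sample_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def trimmed(self, trim_s: float) -> "ImuRecording":
        """Return a copy with the first ``trim_s`` seconds removed.

        Used to discard the attitude filter's settling transient.  Never
        trims below one sample.
        """
        k = min(int(round(trim_s * self.sample_rate)), self.n_samples - 1)
        if k <= 0:
            return self
        return replace(self, time=self.time[k:], accel=self.accel[k:], gyro=self.gyro[k:])

    # ------------------------------------------------------------------ CSV

    def to_csv(self, path: str | Path) -> None:
        """Write ``time,ax,ay,az,gx,gy,gz`` CSV plus a YAML metadata sidecar."""
        path = Path(path)
        df = pd.DataFrame(
            np.column_stack([self.time, self.accel, self.gyro]), columns=_CSV_COLUMNS
        )
        df.to_csv(path, index=False)
        meta = {
            "sample_rate_hz": float(self.sample_rate),
            "accel_unit": "m/s^2",
            "gyro_unit": "rad/s",
            "location": self.location,
            "task": self.task,
        }
        sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "ImuRecording":
        """Read a CSV recording; metadata comes from the sidecar unless given.

        Gyroscope columns declared as ``deg/s`` are converted to rad/s.
        """
        path = Path(path)
        if meta is None:
            sc = sidecar_path(path)
            if not sc.exists():
                raise DegenerateInputError(
                    f"no metadata sidecar {sc.name}: units and sample rate must be declared"
                )
            meta = yaml.safe_load(sc.read_text())
        for key in ("sample_rate_hz", "accel_unit", "gyro_unit"):
            if key not in meta:
                raise DegenerateInputError(f"recording metadata missing required key {key!r}")
        df = pd.read_csv(path)
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise InconsistentInputError(f"CSV missing columns {sorted(missing)}")
        gyro = df[["gx", "gy", "gz"]].to_numpy(float)
        gyro = _gyro_to_rad_s(gyro, meta["gyro_unit"])
        if meta["accel_unit"] not in ("m/s^2", "m/s2"):
            raise DegenerateInputError(f"unsupported accel unit {meta['accel_unit']!r}")
        return cls(
            time=df["time"].to_numpy(float),
            accel=df[["ax", "ay", "az"]].to_numpy(float),
            gyro=gyro,
            sample_rate=float(meta["sample_rate_hz"]),
            location=str(meta.get("location", "unknown")),
            task=str(meta.get("task", "unknown")),
        )

    # ----------------------------------------------------------------- HDF5

    def to_hdf5(self, path: str | Path, group: str | None = None) -> None:
        """Append this recording to an HDF5 container (one group per recording)."""
        name = group or f"{self.location}/{self.task}"
        with h5py.File(path, "a") as f:
            g = f.require_group(name)
            for key in ("time", "accel", "gyro"):
                if key in g:
                    del g[key]
            g.create_dataset("time", data=self.time)
            g.create_dataset("accel", data=self.accel)
            g.create_dataset("gyro", data=self.gyro)
            g.attrs["sample_rate_hz"] = float(self.sample_rate)
            g.attrs["accel_unit"] = "m/s^2"
            g.attrs["gyro_unit"] = "rad/s"
            g.attrs["location"] = self.location
            g.attrs["task"] = self.task

    @classmethod
    def from_hdf5(cls, path: str | Path, group: str) -> "ImuRecording":
        with h5py.File(path, "r") as f:
            g = f[group]
            for key in ("sample_rate_hz", "gyro_unit"):
                if key not in g.attrs:
                    raise DegenerateInputError(f"HDF5 group {group!r} missing attribute {key!r}")
            gyro = _gyro_to_rad_s(np.asarray(g["gyro"]), str(g.attrs["gyro_unit"]))
            return cls(
                time=np.asarray(g["time"]),
                accel=np.asarray(g["accel"]),
                gyro=gyro,
                sample_rate=float(g.attrs["sample_rate_hz"]),
                location=str(g.attrs.get("location", "unknown")),
                task=str(g.attrs.get("task", "unknown")),
            )


def load_hdf5_session(path: str | Path) -> list[ImuRecording]:
    """Load every recording group in an HDF5 container."""
    out: list[ImuRecording] = []
    groups: list[str] = []

    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "accel" in obj:
                groups.append(name)
        f.visititems(visit)
    for g in sorted(groups):
        out.append(ImuRecording.from_hdf5(path, g))
    return out


def sidecar_path(csv_path: str | Path) -> Path:
    """Metadata sidecar path for a CSV recording (``<file>.meta.yaml``)."""
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".meta.yaml")


def _gyro_to_rad_s(gyro: np.ndarray, unit: str) -> np.ndarray:
    if unit in ("rad/s", "rad_s"):
        return gyro
    if unit in ("deg/s", "dps", "°/s"):
        return np.deg2rad(gyro)
    raise DegenerateInputError(f"unsupported gyro unit {unit!r}")


@dataclass
class SessionManifest:
    """List of recording files making up one subject session.

    Each entry maps a CSV file to its sensor location / task labels; the
    manifest is the unit Stage 2 pools over.
    """

    subject: str
    entries: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionManifest":
        data = yaml.safe_load(Path(path).read_text())
        if "subject" not in data or "recordings" not in data:
            raise DegenerateInputError("manifest must define 'subject' and 'recordings'")
        return cls(subject=str(data["subject"]), entries=list(data["recordings"]))

    def load(self, base_dir: str | Path | None = None) -> list[ImuRecording]:
        base = Path(base_dir) if base_dir is not None else Path(".")
        recs = []
        for entry in self.entries:
            p = base / entry["path"]
            if not p.exists():
                raise DegenerateInputError(f"manifest entry not found: {p}")
            rec = ImuRecording.from_csv(p)
            rec.location = str(entry.get("location", rec.location))
            rec.task = str(entry.get("task", rec.task))
            recs.append(rec)
        return recs
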