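"""In-memory containers for mobile-EEG sessions and their HDF5/JSON fixture format.

A session couples a multichannel EEG :class:`Recording` (µV, 500 Hz by
default) with zero or more inertial :class:`MotionTrace` objects (deg/s and g,
120 Hz) and an event list.  The on-disk fixture is a single HDF5 container for
the numeric matrices plus a JSON sidecar for events and configuration, so that
fixtures stay inspectable with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Event", "Recording", "MotionTrace", "save_session", "load_session",
           "load_raw"]


@dataclass(frozen=True)
class Event:
    """A point event on the recording's sample clock."""

    sample: int
    label: str

    @property
    def as_tuple(self) -> tuple[int, str]:
        return (self.sample, self.label)


@dataclass
class Recording:
    """Channels × samples EEG matrix with channel metadata and events.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    channel_labels : list of str
        10%-system names (e.g. ``AFz``, ``O1``); unique.
    channel_roles : list of str
        One of ``{"eeg", "eog", "ref"}`` per channel.
    fs : float
        Sampling rate in Hz.
    events : list of Event
        Point events (burst onsets, condition boundaries).
    """

    data: np.ndarray
    channel_labels: list[str]
    channel_roles: list[str]
    fs: float
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_roles) != n_ch:
            raise ValueError("channel metadata length does not match data")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        bad = set(self.channel_roles) - {"eeg", "eog", "ref"}
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        n = self.n_samples
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event {ev} outside [0, {n})")

    # -- convenience ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def picks(self, role: str | None = None, labels: list[str] | None = None) -> np.ndarray:
        """Indices of channels by role and/or explicit label list."""
        idx = np.arange(self.n_channels)
        if role is not None:
            idx = idx[[self.channel_roles[i] == role for i in idx]]
        if labels is not None:
            wanted = [self.channel_index(l) for l in labels]
            idx = np.array([i for i in wanted if i in set(idx.tolist())], dtype=int)
        return idx

    def get(self, labels: list[str]) -> np.ndarray:
        """Data for the given labels, preserving the requested order."""
        return self.data[[self.channel_index(l) for l in labels]]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=float),
                       events=list(self.events), meta=dict(self.meta))


@dataclass
class MotionTrace:
    """3-axis gyroscope + accelerometer trace from one inertial sensor.

    ``gyro`` rows are (roll, pitch, yaw) angular velocity in deg/s; by package
    convention a left turn produces a *positive* yaw rate (right-hand rule
    about the vertical axis), flippable via configuration upstream.
    """

    gyro: np.ndarray
    accel: np.ndarray
    fs: float
    sensor: str = "waist"
    meta: dict = field(default_factory=dict)

    YAW_AXIS = 2

    def __post_init__(self) -> None:
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        if self.gyro.shape[0] != 3 or self.accel.shape[0] != 3:
            raise ValueError("gyro and accel must be 3 × samples")
        if not (np.isfinite(self.gyro).all() and np.isfinite(self.accel).all()):
            raise ValueError("motion data contains non-finite values")
        if self.sensor not in {"left_ankle", "right_ankle", "waist"}:
            raise ValueError(f"unknown sensor {self.sensor!r}")

    @property
    def yaw(self) -> np.ndarray:
        return self.gyro[self.YAW_AXIS]

    @property
    def n_samples(self) -> int:
        return self.gyro.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# fixture container: HDF5 for matrices, JSON sidecar for events/config
# ---------------------------------------------------------------------------

def save_session(path: str | Path, rec: Recording,
                 motions: list[MotionTrace] | None = None,
                 config: dict | None = None) -> Path:
    """Write a session fixture: ``<path>`` (HDF5) + ``<path>.json`` sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("eeg")
        g.create_dataset("data", data=rec.data)
        g.attrs["fs"] = rec.fs
        g.attrs["labels"] = json.dumps(rec.channel_labels)
        g.attrs["roles"] = json.dumps(rec.channel_roles)
        for i, m in enumerate(motions or []):
            gm = f.create_group(f"motion/{i}")
            gm.create_dataset("gyro", data=m.gyro)
            gm.create_dataset("accel", data=m.accel)
            gm.attrs["fs"] = m.fs
            gm.attrs["sensor"] = m.sensor
    sidecar = {
        "events": [[ev.sample, ev.label] for ev in rec.events],
        "meta": rec.meta,
        "config": config or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def load_raw(path: str | Path, eog_prefix: str = "EOG",
             ref_labels: tuple[str, str] = ("A1", "A2")) -> Recording:
    """Import an EDF or BrainVision recording through mne into a Recording.

    Channel roles are assigned by name: labels starting with ``eog_prefix``
    become EOG, ``ref_labels`` become references, everything else EEG.
    Annotations are carried over as events.  Data are converted to µV.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix!r}")
    labels = list(raw.ch_names)
    roles = ["eog" if l.upper().startswith(eog_prefix.upper())
             else "ref" if l in ref_labels else "eeg" for l in labels]
    events = [Event(int(round(on * raw.info["sfreq"])), desc)
              for on, desc in zip(raw.annotations.onset,
                                  raw.annotations.description)]
    return Recording(data=raw.get_data() * 1e6, channel_labels=labels,
                     channel_roles=roles, fs=float(raw.info["sfreq"]),
                     events=events, meta={"source": str(path)})


def load_session(path: str | Path) -> tuple[Recording, list[MotionTrace], dict]:
    """Read a session fixture written by :func:`save_session`."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    with h5py.File(path, "r") as f:
        g = f["eeg"]
        rec = Recording(
            data=g["data"][()],
            channel_labels=json.loads(g.attrs["labels"]),
            channel_roles=json.loads(g.attrs["roles"]),
            fs=float(g.attrs["fs"]),
            events=[Event(int(s), str(l)) for s, l in sidecar.get("events", [])],
            meta=sidecar.get("meta", {}),
        )
        motions = []
        if "motion" in f:
            for key in sorted(f["motion"], key=int):
                gm = f["motion"][key]
                motions.append(MotionTrace(gyro=gm["gyro"][()], accel=gm["accel"][()],
                                           fs=float(gm.attrs["fs"]),
                                           sensor=str(gm.attrs["sensor"])))
    return rec, motions, sidecar.get("config", {})
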