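"""Turn extraction from gyroscope traces and event-locked epoching.

The turn apex — the peak of the low-pass-filtered yaw-rate trace — marks the
midpoint of a walking turn and is the 0 time point of turn-locked trials
(apex ± 2 s, i.e. 4 s trials).  By package convention a left turn produces a
positive yaw rate (flippable).  The gyroscope low-pass default is 0.3 Hz:
comfortably above the turn fundamental (~1/12 Hz) and far below the ~2 Hz
gait ripple.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .recording import MotionTrace, Recording

__all__ = ["TurnEvent", "EpochSet", "lowpass_yaw", "detect_turns",
           "epoch_by_events"]


@dataclass(frozen=True)
class TurnEvent:
    """A detected turn: apex sample/time on the motion clock, direction,
    duration (span where |yaw| exceeds half the apex magnitude), and the apex
    yaw-rate magnitude."""

    apex_sample: int
    apex_time_s: float
    direction: str           # "left" | "right"
    duration_s: float
    peak_magnitude: float


@dataclass
class EpochSet:
    """Trials × channels × time array time-locked to events.

    The time axis is in seconds with t = 0 at the lock sample; trials are
    ``2·round(half_width·fs)+1`` samples long.  Events whose window would
    cross the recording bounds are dropped and counted in ``n_dropped``.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    lock: str
    trial_ids: list[int] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def mean(self) -> np.ndarray:
        """Trial average, channels × time."""
        return self.data.mean(axis=0)


def lowpass_yaw(motion: MotionTrace, cutoff_hz: float = 0.3,
                order: int = 4) -> MotionTrace:
    """Zero-phase low-pass of the yaw channel; other channels pass through."""
    if not 0 < cutoff_hz < motion.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = signal.butter(order, cutoff_hz, "lowpass", fs=motion.fs, output="sos")
    gyro = motion.gyro.copy()
    gyro[MotionTrace.YAW_AXIS] = signal.sosfiltfilt(sos, motion.yaw)
    out = replace(motion, gyro=gyro, meta=dict(motion.meta))
    out.meta["yaw_lowpass_hz"] = cutoff_hz
    return out


def _merge_close(idx: np.ndarray, mags: np.ndarray, min_sep: int) -> list[int]:
    """Greedy merge of peaks closer than ``min_sep`` samples, keeping the
    larger magnitude."""
    keep: list[int] = []
    for i in np.argsort(-mags):
        if all(abs(idx[i] - idx[j]) >= min_sep for j in keep):
            keep.append(i)
    return sorted(idx[i] for i in keep)


def detect_turns(filtered: MotionTrace, min_separation_s: float = 3.0,
                 magnitude_threshold: float | None = None,
                 left_positive_yaw: bool = True,
                 edge_guard_s: float = 1.0) -> list[TurnEvent]:
    """Find turn apices in a low-pass-filtered yaw trace.

    Positive local maxima above the threshold become left turns, negative
    minima below −threshold right turns (convention flippable).  When
    ``magnitude_threshold`` is None it is calibrated as half the median
    absolute peak magnitude of an unthresholded pass; if that pass finds no
    peaks the list is empty.
    """
    yaw = filtered.yaw if left_positive_yaw else -filtered.yaw
    fs = filtered.fs
    min_sep = max(1, int(round(min_separation_s * fs)))

    def peaks(x: np.ndarray, thr: float) -> tuple[np.ndarray, np.ndarray]:
        idx, _ = signal.find_peaks(x, height=thr, distance=1)
        return idx, x[idx]

    if magnitude_threshold is None:
        cal_idx, _ = signal.find_peaks(np.abs(yaw), distance=min_sep)
        if len(cal_idx) == 0:
            return []
        magnitude_threshold = 0.5 * float(np.median(np.abs(yaw[cal_idx])))

    # zero-phase filtering is unreliable within ~a filter warm-up of the edges
    guard = max(1, int(round(edge_guard_s * fs)))
    events: list[TurnEvent] = []
    for sign, direction in ((1.0, "left"), (-1.0, "right")):
        x = sign * yaw
        idx, mags = peaks(x, magnitude_threshold)
        inside = (idx >= guard) & (idx < len(yaw) - guard)
        idx, mags = idx[inside], mags[inside]
        if len(idx) == 0:
            continue
        for i in _merge_close(idx, mags, min_sep):
            mag = x[i]
            half = mag / 2
            l = i
            while l > 0 and x[l - 1] > half:
                l -= 1
            r = i
            while r < len(x) - 1 and x[r + 1] > half:
                r += 1
            events.append(TurnEvent(
                apex_sample=int(i), apex_time_s=i / fs, direction=direction,
                duration_s=(r - l + 1) / fs, peak_magnitude=float(mag)))
    events.sort(key=lambda e: e.apex_sample)
    return events


def epoch_by_events(rec: Recording, times_s: list[float],
                    half_width_s: float = 2.0, lock: str = "event",
                    channel_labels: list[str] | None = None) -> EpochSet:
    """Cut ±``half_width_s`` trials around event times given in seconds.

    Event times may originate on another clock (e.g. the 120 Hz motion clock);
    they are mapped to the recording clock by rounding ``t · fs`` to the
    nearest sample, so round-trip error is below one sample.  Out-of-bounds
    windows are dropped and counted.
    """
    if channel_labels is not None:
        data = rec.get(channel_labels)
        labels = list(channel_labels)
    else:
        data = rec.data
        labels = list(rec.channel_labels)
    fs = rec.fs
    hw = int(round(half_width_s * fs))
    n = data.shape[1]
    trials, ids = [], []
    dropped = 0
    for tid, t in enumerate(times_s):
        c = int(round(t * fs))
        if c - hw < 0 or c + hw >= n:
            dropped += 1
            continue
        trials.append(data[:, c - hw:c + hw + 1])
        ids.append(tid)
    if not trials:
        raise ValueError("no usable events after boundary dropping")
    return EpochSet(data=np.stack(trials), times=np.arange(-hw, hw + 1) / fs,
                    fs=fs, lock=lock, trial_ids=ids, channel_labels=labels,
                    n_dropped=dropped)
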