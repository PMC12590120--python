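"""Time-resolved ASSR power, lateralization index, and burst perturbation.

Time-resolved power at an amplitude-modulation rate is the squared magnitude
of the analytic signal of the ±0.5 Hz band-passed trace, computed on the
continuous block *before* epoching.  The lateralization index

    LI(t) = (P39(t) − P41(t)) / (P39(t) + P41(t))

is positive when the left-ear (39 Hz) input is preferred.  Burst-evoked
perturbation is the trial-averaged power expressed in dB against the
[−400, 0] ms pre-burst baseline, summarized as the mean over (0, 700] ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .motion import EpochSet, TurnEvent, epoch_by_events
from .recording import Recording
from .synth import FRONTOCENTRAL

__all__ = ["PowerSeries", "LateralizationSeries", "PerturbationResult",
           "timeresolved_power", "lateralization_index", "turn_locked_contrast",
           "control_frequencies", "perturbation_response", "group_bursts_by_turn"]


@dataclass
class PowerSeries:
    """Instantaneous narrow-band power (µV²) over time on the EEG clock."""

    center_hz: float
    values: np.ndarray
    fs: float
    bandwidth_hz: float = 0.5
    edge_trim_s: float = 0.5    # samples inside this margin are unreliable

    @property
    def valid(self) -> slice:
        k = int(round(self.edge_trim_s * self.fs))
        return slice(k, len(self.values) - k)


@dataclass
class LateralizationSeries:
    """LI(t) ∈ [−1, 1]; samples where P39 + P41 = 0 are NaN and flagged."""

    values: np.ndarray
    fs: float
    undefined: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    constituents: tuple[float, float] = (39.0, 41.0)
    edge_trim_s: float = 0.5


@dataclass
class PerturbationResult:
    """Mean log-ratio (dB) response in the post-burst window per condition."""

    value_db: float
    series_db: np.ndarray
    times: np.ndarray
    n_trials: int
    center_hz: float
    condition: dict = field(default_factory=dict)
    baseline_s: tuple[float, float] = (-0.4, 0.0)
    response_s: tuple[float, float] = (0.0, 0.7)


# ---------------------------------------------------------------------------

def _bandpass_fir(x: np.ndarray, fs: float, center: float, bw: float,
                  transition_hz: float = 1.0) -> np.ndarray:
    """Zero-phase FIR band-pass, passband center ± bw."""
    if center + bw + transition_hz >= fs / 2:
        raise ValueError("band outside Nyquist range")
    numtaps = int(round(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd
    taps = signal.firwin(numtaps, [center - bw, center + bw],
                         pass_zero=False, fs=fs, window="hamming")
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=min(x.shape[-1] - 1,
                                                               3 * numtaps))


def timeresolved_power(rec_or_trace: Recording | np.ndarray, center_hz: float,
                       bw: float = 0.5, fs: float | None = None,
                       channel_labels: list[str] | None = None,
                       edge_trim_s: float = 0.5) -> PowerSeries:
    """Squared analytic-signal magnitude of the ±bw band around ``center_hz``.

    Accepts a Recording (the trace is the mean over ``channel_labels``,
    default frontocentral) or a raw 1-D trace with explicit ``fs``.  Computed
    on the continuous data; epoch afterwards.
    """
    if isinstance(rec_or_trace, Recording):
        labels = channel_labels or FRONTOCENTRAL
        x = rec_or_trace.get(labels).mean(axis=0)
        fs = rec_or_trace.fs
    else:
        if fs is None:
            raise ValueError("fs required for a raw trace")
        x = np.asarray(rec_or_trace, dtype=float)
    xb = _bandpass_fir(x, fs, center_hz, bw)
    power = np.abs(signal.hilbert(xb)) ** 2
    return PowerSeries(center_hz=center_hz, values=power, fs=fs,
                       bandwidth_hz=bw, edge_trim_s=edge_trim_s)


def lateralization_index(p39: PowerSeries, p41: PowerSeries) -> LateralizationSeries:
    """Elementwise (P39 − P41)/(P39 + P41); zero-power samples become NaN."""
    if len(p39.values) != len(p41.values) or p39.fs != p41.fs:
        raise ValueError("power series are misaligned")
    total = p39.values + p41.values
    undefined = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(undefined, np.nan, (p39.values - p41.values) / total)
    return LateralizationSeries(values=li, fs=p39.fs, undefined=undefined,
                                constituents=(p39.center_hz, p41.center_hz),
                                edge_trim_s=max(p39.edge_trim_s, p41.edge_trim_s))


# ---------------------------------------------------------------------------

def _series_recording(values: np.ndarray, fs: float) -> Recording:
    return Recording(data=values[None, :], channel_labels=["series"],
                     channel_roles=["eeg"], fs=fs)


def turn_locked_contrast(lat: LateralizationSeries, turns: list[TurnEvent],
                         half_width_s: float = 2.0,
                         ) -> dict[str, np.ndarray | EpochSet]:
    """Epoch LI(t) by turn apices per direction, ready for the cluster test.

    Returns ``{"left": trials × time, "right": trials × time, "times": ...}``.
    Apex times are taken from the TurnEvents' own (motion) clock in seconds
    and mapped onto the LI sample clock.
    """
    by_dir: dict[str, list[float]] = {"left": [], "right": []}
    for ev in turns:
        by_dir[ev.direction].append(ev.apex_time_s)
    for d, ts in by_dir.items():
        if len(ts) < 2:
            raise ValueError(f"need at least 2 {d}-turn trials, have {len(ts)}")
    rec = _series_recording(np.nan_to_num(lat.values, nan=0.0), lat.fs)
    out: dict[str, np.ndarray | EpochSet | np.ndarray] = {}
    for d, ts in by_dir.items():
        es = epoch_by_events(rec, ts, half_width_s=half_width_s, lock=f"turn_{d}")
        out[d] = es.data[:, 0, :]
        out["times"] = es.times
        out[f"{d}_ids"] = es.trial_ids
    return out


def control_frequencies(rec: Recording, turns: list[TurnEvent],
                        freqs: tuple[float, float] = (37.0, 44.0),
                        channel_labels: list[str] | None = None,
                        half_width_s: float = 2.0) -> dict:
    """The turn-locked lateralization contrast at neighbouring control
    frequencies (same contract as the 39/41 Hz pipeline)."""
    p_lo = timeresolved_power(rec, freqs[0], channel_labels=channel_labels)
    p_hi = timeresolved_power(rec, freqs[1], channel_labels=channel_labels)
    lat = lateralization_index(p_lo, p_hi)
    return turn_locked_contrast(lat, turns, half_width_s=half_width_s)


# ---------------------------------------------------------------------------

def perturbation_response(power_epochs: EpochSet, center_hz: float,
                          baseline_s: tuple[float, float] = (-0.4, 0.0),
                          response_s: tuple[float, float] = (0.0, 0.7),
                          condition: dict | None = None) -> PerturbationResult:
    """Burst-evoked power change in dB against the pre-burst baseline.

    Trials (epochs of a time-resolved power series, locked to burst onset)
    are averaged first; then value(t) = 10·log10(P(t)/mean P over baseline),
    and the response is the mean over ``response_s``.
    """
    if power_epochs.n_trials == 0:
        raise ValueError("empty condition cell")
    mean_power = power_epochs.data.mean(axis=0)
    if mean_power.ndim == 2:          # channels × time → average channels
        mean_power = mean_power.mean(axis=0)
    t = power_epochs.times
    base = mean_power[(t >= baseline_s[0]) & (t < baseline_s[1])].mean()
    if base <= 0:
        raise ValueError("non-positive baseline power")
    series_db = 10.0 * np.log10(mean_power / base)
    resp = float(series_db[(t > response_s[0]) & (t <= response_s[1])].mean())
    return PerturbationResult(value_db=resp, series_db=series_db, times=t,
                              n_trials=power_epochs.n_trials,
                              center_hz=center_hz, condition=condition or {},
                              baseline_s=baseline_s, response_s=response_s)


def group_bursts_by_turn(burst_times_s: list[float], turns: list[TurnEvent],
                         mode: str = "direction", half_width_s: float = 2.0,
                         ) -> list[str]:
    """Label each burst by the turn context it occurred in.

    mode="direction": bursts within apex ± half_width get that turn's
    direction.  mode="entrainment_phase": each turn window splits at the apex
    into the half where the turn-side ear is preferred (pre-apex) and the half
    where the opposite ear is preferred (post-apex); labels are
    "prefer_left"/"prefer_right".  A burst exactly at an apex belongs to the
    post-apex half.  Bursts outside any window are "unassigned".
    """
    if mode not in {"direction", "entrainment_phase"}:
        raise ValueError(f"unknown mode {mode!r}")
    labels = []
    for t in burst_times_s:
        label = "unassigned"
        for ev in turns:
            dt = t - ev.apex_time_s
            if -half_width_s <= dt < half_width_s:
                if mode == "direction":
                    label = ev.direction
                else:
                    pre = dt < 0
                    turn_side = ev.direction
                    other = "right" if turn_side == "left" else "left"
                    label = f"prefer_{turn_side if pre else other}"
                break
        labels.append(label)
    return labels
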