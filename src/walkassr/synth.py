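"""Synthetic mobile-EEG session generator.

Emulates the statistical structure the downstream analyses assume, so every
stage of the pipeline can be validated by parameter recovery:

* two auditory steady-state (ASSR) cortical sources — sinusoids at the left-
  and right-ear amplitude-modulation rates (39 and 41 Hz) with a frontocentral
  scalp topography, whose amplitudes depend on movement state and, during
  walking, on the phase of the current turn (antisymmetric left/right gain);
* an occipital alpha source (8–14 Hz band-limited noise) whose power depends
  on movement state;
* a 1/f aperiodic background per channel, plus white sensor noise;
* burst-evoked perturbations: a multiplicative ASSR amplitude dip with
  exponential recovery, and additive P1/P2 evoked-potential templates;
* a waist gyroscope trace for an 8-shaped walking path with alternating
  left/right turns (~12 s laps), 2 Hz gait ripple and sensor noise.

All randomness is driven by a single integer seed; identical configurations
and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .recording import Event, MotionTrace, Recording

__all__ = [
    "StimulusConfig", "BurstSchedule", "SessionConfig",
    "generate_am_tone", "schedule_bursts", "simulate_gyro", "simulate_eeg",
    "turn_apex_times", "SCALP_CHANNELS", "FRONTOCENTRAL", "OCCIPITAL",
]

# ---------------------------------------------------------------------------
# montage: 18 scalp channels (10% system), 2 earlobe references, 6 EOG
# ---------------------------------------------------------------------------

#: schematic 2-D scalp positions (x: left→right, y: back→front), unit disc
SCALP_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.95), "Fp2": (0.30, 0.95), "AFz": (0.00, 0.85),
    "F3": (-0.45, 0.60), "Fz": (0.00, 0.60), "F4": (0.45, 0.60),
    "T7": (-0.95, 0.00), "C3": (-0.50, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.50, 0.00), "T8": (0.95, 0.00), "CPz": (0.00, -0.30),
    "P3": (-0.45, -0.60), "Pz": (0.00, -0.60), "P4": (0.45, -0.60),
    "POz": (0.00, -0.80),
    "O1": (-0.30, -0.95), "O2": (0.30, -0.95),
}

SCALP_CHANNELS = list(SCALP_POSITIONS)
REF_CHANNELS = ["A1", "A2"]
EOG_CHANNELS = [f"EOG{i}" for i in range(1, 7)]
FRONTOCENTRAL = ["AFz", "Fz", "F3", "F4", "Cz"]
OCCIPITAL = ["O1", "O2"]

#: Gaussian topography centres/widths for the forward model.  The alpha
#: topography is centred on POz so that the occipital-maximum selection rule
#: holds by construction in the ground truth.
_ASSR_CENTER, _ASSR_SIGMA = (0.0, 0.35), 0.65
_ALPHA_CENTER, _ALPHA_SIGMA = (0.0, -0.88), 0.35


def _gaussian_topography(center: tuple[float, float], sigma: float) -> np.ndarray:
    """Weights over SCALP_CHANNELS from a Gaussian on the schematic disc."""
    pos = np.array([SCALP_POSITIONS[ch] for ch in SCALP_CHANNELS])
    d2 = ((pos - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * sigma ** 2))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusConfig:
    """Dichotic amplitude-modulated tone parameters (left 39 Hz, right 41 Hz)."""

    carrier_hz: float = 1000.0
    mod_left_hz: float = 39.0
    mod_right_hz: float = 41.0
    depth: float = 1.0
    audio_fs: float = 44100.0

    def __post_init__(self) -> None:
        if self.mod_left_hz == self.mod_right_hz:
            raise ValueError("left and right modulation rates must differ")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")
        if self.audio_fs <= 2 * self.carrier_hz:
            raise ValueError("audio_fs must exceed twice the carrier frequency")

    def mod_hz(self, side: str) -> float:
        if side == "left":
            return self.mod_left_hz
        if side == "right":
            return self.mod_right_hz
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass(frozen=True)
class BurstSchedule:
    """White-noise burst onsets (100 ms) per kind, gaps uniform in 3–7 s."""

    events: tuple[tuple[float, str], ...]
    burst_dur_s: float = 0.1
    interval_range_s: tuple[float, float] = (3.0, 7.0)

    def onsets(self, kind: str | None = None) -> list[float]:
        return [t for t, k in self.events if kind is None or k == kind]

    @property
    def kinds(self) -> list[str]:
        return sorted({k for _, k in self.events})


BURST_KINDS = ("left", "right", "central")


@dataclass
class SessionConfig:
    """Ground-truth parameters for one simulated block.

    Amplitudes are source amplitudes in µV at the topography maximum;
    ``assr_amp`` maps movement state → {39: amp, 41: amp} (sinusoid amplitude),
    ``alpha_amp`` maps state → RMS of the 8–14 Hz source.  ``lateral_gain`` g
    multiplies the turn-side ASSR amplitude before the apex (and divides it
    after), antisymmetrically between the 39/41 Hz sources; g = 1 disables the
    modulation.
    """

    movement_state: str = "walk"
    assr_amp: dict = field(default_factory=lambda: {
        "stand": {39.0: 0.5, 41.0: 0.5},
        "step": {39.0: 0.7, 41.0: 0.7},
        "walk": {39.0: 1.0, 41.0: 1.0},
    })
    alpha_amp: dict = field(default_factory=lambda: {
        "stand": 2.0, "step": 1.8, "walk": 1.0})
    aperiodic: tuple[float, float] = (0.5, 1.5)   # (offset, exponent), log10 µV²/Hz
    lateral_gain: float = 1.0
    erp_p1_uv: float = 1.0        # P1 template peak (µV), 165 ms, σ = 15 ms
    erp_p2_uv: float = 0.8        # P2 template peak (µV), 325 ms, σ = 20 ms
    burst_dip: tuple[float, float, float] = (0.5, 0.3, 0.15)  # depth, hold s, tau s
    lap_duration_s: float = 12.0
    turn_duration_s: float = 6.4
    lead_in_s: float = 6.0        # straight walking before/after the 8-path laps
    n_laps: int = 40              # 480 s walking block at 12 s per lap
    eeg_fs: float = 500.0
    motion_fs: float = 120.0
    noise_uv: float = 0.5         # white sensor noise RMS (µV)
    gyro_peak_dps: float = 50.0   # yaw-rate amplitude at turn apex (deg/s)
    gyro_ripple_dps: float = 8.0  # 2 Hz gait ripple on the gyro channels
    gyro_noise_dps: float = 3.0
    left_positive_yaw: bool = True
    seed: int = 0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)

    def __post_init__(self) -> None:
        if self.movement_state not in {"stand", "step", "walk"}:
            raise ValueError(f"unknown movement_state {self.movement_state!r}")
        if self.eeg_fs != 500.0 or self.motion_fs != 120.0:
            raise ValueError("eeg_fs must be 500 Hz and motion_fs 120 Hz")
        if self.lap_duration_s <= 4.0:
            raise ValueError("lap_duration_s must exceed the 4 s epoch window")
        for state, amps in self.assr_amp.items():
            if any(a < 0 for a in amps.values()):
                raise ValueError("ASSR amplitudes must be nonnegative")
        if any(a < 0 for a in self.alpha_amp.values()):
            raise ValueError("alpha amplitudes must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.n_laps * self.lap_duration_s + 2 * self.lead_in_s


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def generate_am_tone(cfg: StimulusConfig, side: str, duration: float) -> np.ndarray:
    """Sinusoidal amplitude-modulated tone for one ear.

    Returns ``(1 + depth · sin(2π f_mod t)) · sin(2π f_carrier t)`` sampled at
    ``cfg.audio_fs``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    f_mod = cfg.mod_hz(side)
    n = int(round(duration * cfg.audio_fs))
    t = np.arange(n) / cfg.audio_fs
    return (1.0 + cfg.depth * np.sin(2 * np.pi * f_mod * t)) * np.sin(
        2 * np.pi * cfg.carrier_hz * t)


def schedule_bursts(duration: float, n_per_kind: int,
                    interval_range: tuple[float, float] = (3.0, 7.0),
                    seed: int = 0, kinds: tuple[str, ...] = BURST_KINDS,
                    ) -> BurstSchedule:
    """Draw burst onsets per kind with consecutive gaps uniform in 3–7 s.

    Each kind's onset train is an independent renewal process; the first onset
    is a gap from the block start.  Deterministic given ``seed``.
    """
    if n_per_kind < 1:
        raise ValueError("n_per_kind must be at least 1")
    lo, hi = interval_range
    if not 0 < lo <= hi:
        raise ValueError("invalid interval range")
    if duration < n_per_kind * lo + 1.0:
        raise ValueError(
            f"duration {duration} s cannot fit {n_per_kind} bursts "
            f"at the {lo} s minimum interval")
    rng = np.random.default_rng(seed)
    events: list[tuple[float, str]] = []
    for kind in kinds:
        for _ in range(1000):
            gaps = rng.uniform(lo, hi, size=n_per_kind)
            onsets = np.cumsum(gaps)
            if onsets[-1] <= duration - 0.5:
                break
        else:
            raise ValueError("could not fit burst schedule inside duration")
        events.extend((float(t), kind) for t in onsets)
    events.sort()
    return BurstSchedule(events=tuple(events), interval_range_s=(lo, hi))


# ---------------------------------------------------------------------------
# walking path / gyroscope
# ---------------------------------------------------------------------------

def turn_apex_times(cfg: SessionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Analytic apex times of the simulated 8-path: (left_times, right_times).

    The yaw-rate profile is ``A · tanh(k sin(2πt/T)) / tanh(k)``; its extrema
    sit exactly at the quarter-lap points regardless of the shaping factor k,
    so one left apex at T/4 and one right apex at 3T/4 per lap.
    """
    T = cfg.lap_duration_s
    laps = np.arange(cfg.n_laps)
    left = cfg.lead_in_s + laps * T + T / 4
    right = cfg.lead_in_s + laps * T + 3 * T / 4
    return left, right


#: max tanh shaping: beyond this the 3rd harmonic exceeds ~1/9 of the
#: fundamental after the 0.3 Hz low-pass and the apex splits into twin ripples
_MAX_SHAPE_K = 1.5


def _turn_shape_factor(cfg: SessionConfig) -> float:
    """Solve the tanh shaping factor k so the span where |yaw| exceeds half
    the apex magnitude approaches the configured turn duration.

    k is clamped to ``_MAX_SHAPE_K`` so that the low-pass-filtered profile
    keeps a single central maximum per turn; the achievable half-peak span is
    therefore at most ~0.39·lap_duration (≈4.7 s for 12 s laps).  Longer
    configured durations saturate the clamp — measured turn durations on
    smoothed data come out broader anyway.
    """
    T = cfg.lap_duration_s

    def span(k: float) -> float:
        # |tanh(k sin θ)| > tanh(k)/2 ⇔ sin θ > atanh(tanh(k)/2)/k
        thr = math.atanh(math.tanh(k) / 2) / k
        return (math.pi - 2 * math.asin(thr)) / (2 * math.pi) * T

    target = min(cfg.turn_duration_s, 0.999 * span(_MAX_SHAPE_K))
    if target <= span(1e-6) + 1e-9:
        return 1e-6
    return brentq(lambda k: span(k) - target, 1e-6, _MAX_SHAPE_K)


def simulate_gyro(cfg: SessionConfig) -> MotionTrace:
    """Waist gyroscope/accelerometer trace for the configured movement state.

    Walking yields one smooth positive (left-turn) and one negative
    (right-turn) yaw excursion per lap with apices half a lap apart, plus a
    2 Hz gait ripple and white noise.  Standing/stepping have no turn
    structure.
    """
    if cfg.n_laps < 1:
        raise ValueError("n_laps must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6A61]))
    n = int(round(cfg.duration_s * cfg.motion_fs))
    t = np.arange(n) / cfg.motion_fs
    yaw = np.zeros(n)
    if cfg.movement_state == "walk":
        k = _turn_shape_factor(cfg)
        tt = t - cfg.lead_in_s
        base = np.sin(2 * np.pi * tt / cfg.lap_duration_s)
        base[(tt < 0) | (tt >= cfg.n_laps * cfg.lap_duration_s)] = 0.0
        yaw = cfg.gyro_peak_dps * np.tanh(k * base) / math.tanh(k)
        if not cfg.left_positive_yaw:
            yaw = -yaw
    ripple = 0.0
    if cfg.movement_state in {"walk", "step"}:
        ripple = cfg.gyro_ripple_dps * np.sin(2 * np.pi * 2.0 * t)
    gyro = np.vstack([
        ripple + cfg.gyro_noise_dps * rng.standard_normal(n),
        ripple + cfg.gyro_noise_dps * rng.standard_normal(n),
        yaw + ripple + cfg.gyro_noise_dps * rng.standard_normal(n),
    ])
    accel = 0.05 * rng.standard_normal((3, n))
    accel[2] += 1.0  # gravity, g
    if cfg.movement_state in {"walk", "step"}:
        accel += 0.1 * np.sin(2 * np.pi * 2.0 * t)
    return MotionTrace(gyro=gyro, accel=accel, fs=cfg.motion_fs, sensor="waist",
                       meta={"movement_state": cfg.movement_state})


# ---------------------------------------------------------------------------
# EEG forward model
# ---------------------------------------------------------------------------

def _aperiodic_noise(rng: np.random.Generator, n: int, fs: float,
                     offset: float, exponent: float) -> np.ndarray:
    """Gaussian noise whose one-sided PSD follows 10^offset · f^−exponent."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    psd = np.zeros_like(freqs)
    nz = freqs > 0
    psd[nz] = 10.0 ** offset * freqs[nz] ** (-exponent)
    psd[0] = psd[1] if n > 1 else 0.0
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec *= np.sqrt(psd * fs * n) / 2  # scale so welch density matches psd
    spec[0] = spec[0].real * math.sqrt(2)
    if n % 2 == 0:
        spec[-1] = spec[-1].real * math.sqrt(2)
    return np.fft.irfft(spec, n=n)


def _alpha_source(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """8–14 Hz band-limited Gaussian noise scaled to the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    sos = signal.butter(4, [8.0, 14.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return rms * x / np.sqrt(np.mean(x ** 2))


def _lateral_exponent(t: np.ndarray, cfg: SessionConfig, half_width: float = 2.0,
                      ) -> np.ndarray:
    """Turn-phase profile p(t) ∈ [−1, 1] for the 39 Hz source gain g^p.

    For a left turn the left-ear (39 Hz) source is preferred before the apex:
    p = −sin(π (t − apex)/half_width) inside apex ± half_width, so p = +1 one
    second before the apex, 0 at the apex and window edges, −1 after.  Right
    turns flip the sign.  The 41 Hz source uses −p (antisymmetric).
    """
    p = np.zeros_like(t)
    left, right = turn_apex_times(cfg)
    for apex_list, s in ((left, 1.0), (right, -1.0)):
        for apex in apex_list:
            m = (t >= apex - half_width) & (t < apex + half_width)
            p[m] = -s * np.sin(np.pi * (t[m] - apex) / half_width)
    return p


def _dip_envelope(t: np.ndarray, onsets: list[float],
                  dip: tuple[float, float, float]) -> np.ndarray:
    """Multiplicative ASSR amplitude envelope: drop by ``depth`` for ``hold``
    seconds after each onset, then exponential recovery with ``tau``."""
    depth, hold, tau = dip
    env = np.ones_like(t)
    for t0 in onsets:
        m = t >= t0
        dt = t[m] - t0
        drop = np.where(dt <= hold, depth, depth * np.exp(-(dt - hold) / tau))
        env[m] = np.minimum(env[m], 1.0 - drop)
    return env


def _erp_template(t_epoch: np.ndarray, p1_uv: float, p2_uv: float) -> np.ndarray:
    """Additive evoked waveform: Gaussian P1 (165 ms, σ 15 ms) and P2
    (325 ms, σ 20 ms) bumps."""
    return (p1_uv * np.exp(-0.5 * ((t_epoch - 0.165) / 0.015) ** 2)
            + p2_uv * np.exp(-0.5 * ((t_epoch - 0.325) / 0.020) ** 2))


def simulate_eeg(cfg: SessionConfig, schedule: BurstSchedule | None = None,
                 motion: MotionTrace | None = None,
                 seed: int | None = None) -> Recording:
    """Forward-mix the configured sources into a 26-channel recording.

    Channels: 18 scalp EEG (10% system), A1/A2 earlobe references, 6 EOG
    (noise only).  Ground truth (apex times, source amplitudes, topographies)
    is embedded in ``Recording.meta["truth"]`` for parameter-recovery tests.
    """
    if cfg.lateral_gain != 1.0 and cfg.movement_state == "walk" and motion is None:
        raise ValueError("turn-phase lateralization requires a motion trace")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEE6]))
    fs = cfg.eeg_fs
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    if schedule is not None:
        late = [on for on, _ in schedule.events if on >= cfg.duration_s]
        if late:
            raise ValueError(f"{len(late)} scheduled bursts exceed the duration")

    f39 = cfg.stimulus.mod_left_hz
    f41 = cfg.stimulus.mod_right_hz
    amps = cfg.assr_amp[cfg.movement_state]
    a39 = np.full(n, amps.get(f39, amps.get(39.0, 0.0)), dtype=float)
    a41 = np.full(n, amps.get(f41, amps.get(41.0, 0.0)), dtype=float)

    if cfg.lateral_gain != 1.0 and cfg.movement_state == "walk":
        p = _lateral_exponent(t, cfg)
        a39 *= cfg.lateral_gain ** p
        a41 *= cfg.lateral_gain ** (-p)

    if schedule is not None:
        a39 *= _dip_envelope(t, schedule.onsets("left") + schedule.onsets("central"),
                             cfg.burst_dip)
        a41 *= _dip_envelope(t, schedule.onsets("right") + schedule.onsets("central"),
                             cfg.burst_dip)

    src39 = a39 * np.sin(2 * np.pi * f39 * t + rng.uniform(0, 2 * np.pi))
    src41 = a41 * np.sin(2 * np.pi * f41 * t + rng.uniform(0, 2 * np.pi))
    alpha = _alpha_source(rng, n, fs, cfg.alpha_amp[cfg.movement_state])

    topo_assr = _gaussian_topography(_ASSR_CENTER, _ASSR_SIGMA)
    topo_alpha = _gaussian_topography(_ALPHA_CENTER, _ALPHA_SIGMA)
    n_scalp = len(SCALP_CHANNELS)
    scalp = (np.outer(topo_assr, src39 + src41) + np.outer(topo_alpha, alpha))

    # evoked responses, added on the ASSR (frontocentral) topography
    if schedule is not None and (cfg.erp_p1_uv or cfg.erp_p2_uv):
        erp_len = int(round(0.7 * fs)) + 1
        template = _erp_template(np.arange(erp_len) / fs, cfg.erp_p1_uv, cfg.erp_p2_uv)
        erp_trace = np.zeros(n)
        for on, _ in schedule.events:
            i0 = int(round(on * fs))
            seg = min(erp_len, n - i0)
            if seg > 0:
                erp_trace[i0:i0 + seg] += template[:seg]
        scalp += np.outer(topo_assr, erp_trace)

    offset, exponent = cfg.aperiodic
    for ch in range(n_scalp):
        scalp[ch] += _aperiodic_noise(rng, n, fs, offset, exponent)
    scalp += cfg.noise_uv * rng.standard_normal((n_scalp, n))

    refs = 0.5 * rng.standard_normal((2, n))
    eog = 2.0 * rng.standard_normal((6, n))
    data = np.vstack([scalp, refs, eog])

    labels = SCALP_CHANNELS + REF_CHANNELS + EOG_CHANNELS
    roles = ["eeg"] * n_scalp + ["ref"] * 2 + ["eog"] * 6
    events = [Event(0, f"state_{cfg.movement_state}")]
    if schedule is not None:
        for on, kind in schedule.events:
            events.append(Event(int(round(on * fs)), f"burst_{kind}"))
    events.sort(key=lambda e: e.sample)

    left, right = turn_apex_times(cfg)
    truth = {
        "apex_left_s": left.tolist() if cfg.movement_state == "walk" else [],
        "apex_right_s": right.tolist() if cfg.movement_state == "walk" else [],
        "assr_amp": {str(f39): float(amps.get(f39, 0.0)),
                     str(f41): float(amps.get(f41, 0.0))},
        "alpha_rms": float(cfg.alpha_amp[cfg.movement_state]),
        "lateral_gain": float(cfg.lateral_gain),
        "aperiodic": list(cfg.aperiodic),
        "topo_assr": topo_assr.tolist(),
        "topo_alpha": topo_alpha.tolist(),
        "seed": int(seed),
    }
    return Recording(data=data, channel_labels=labels, channel_roles=roles,
                     fs=fs, events=events,
                     meta={"movement_state": cfg.movement_state, "truth": truth})
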