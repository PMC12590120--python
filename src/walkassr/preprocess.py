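"""EEG preprocessing: rereference, zero-phase filtering, PCA+ICA, spectra.

The chain follows the standard mobile-EEG recipe: earlobe-average reference,
1 Hz high-pass, 100 Hz low-pass, 49.5–50.5 Hz band-stop for line noise, PCA
reduction of the (EEG-only) channels to 16 dimensions followed by extended
Infomax ICA, Welch spectra of the component activations (1 s window, 50 %
overlap), and back-projection of selected components to sensor space.

All filters are zero-phase (forward–backward), so evoked-potential latencies
are not shifted.  Filter families and orders are configurable through
:class:`FilterSpec`; the defaults are Butterworth IIR sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.preprocessing import infomax
from scipy import signal

from .recording import Recording

__all__ = ["FilterSpec", "PowerSpectrum", "ComponentDecomposition",
           "rereference", "apply_filters", "decompose", "component_spectra",
           "backproject", "welch_spectrum"]


@dataclass(frozen=True)
class FilterSpec:
    """Cutoffs and orders for the zero-phase preprocessing filters."""

    highpass_hz: float = 1.0
    lowpass_hz: float = 100.0
    bandstop_hz: tuple[float, float] = (49.5, 50.5)
    highpass_order: int = 2
    lowpass_order: int = 4
    bandstop_order: int = 3

    def __post_init__(self) -> None:
        if not self.highpass_hz < self.lowpass_hz:
            raise ValueError("highpass cutoff must be below lowpass cutoff")
        lo, hi = self.bandstop_hz
        if not (self.highpass_hz < lo < hi < self.lowpass_hz):
            raise ValueError("band-stop must lie inside the passband")


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density (µV²/Hz) on a 1/window_s grid."""

    freqs: np.ndarray
    power: np.ndarray
    window_s: float = 1.0
    overlap: float = 0.5
    scaling: str = "density"

    def band_mean(self, lo: float, hi: float) -> float:
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return float(np.mean(self.power[m]))


@dataclass
class ComponentDecomposition:
    """PCA(16) + Infomax ICA of the EEG channels.

    ``unmixing`` (components × channels) maps sensor data to activations;
    ``mixing`` (channels × components) is its pseudoinverse, whose columns are
    the component topographies.  ``mixing @ unmixing`` is the projector onto
    the retained PCA subspace (idempotent).
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    activations: np.ndarray
    channel_labels: list[str]
    mean: np.ndarray
    n_dims: int = 16
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def topography(self, comp: int) -> np.ndarray:
        return self.mixing[:, comp]


# ---------------------------------------------------------------------------

def rereference(rec: Recording, ref_labels: tuple[str, str] = ("A1", "A2"),
                ) -> Recording:
    """Subtract the mean of the two earlobe electrodes from every channel.

    EOG channels are left untouched; the reference channels themselves are
    also re-expressed against the earlobe average (their mean becomes zero).
    """
    idx = [rec.channel_index(l) for l in ref_labels]
    ref = rec.data[idx].mean(axis=0)
    out = rec.data.copy()
    for i in range(rec.n_channels):
        if rec.channel_roles[i] != "eog":
            out[i] = out[i] - ref
    new = rec.copy_with(out)
    new.meta["reference"] = list(ref_labels)
    return new


def _sos_chain(spec: FilterSpec, fs: float) -> list[np.ndarray]:
    if fs <= 2 * spec.lowpass_hz:
        raise ValueError("sampling rate too low for the requested low-pass")
    return [
        signal.butter(spec.highpass_order, spec.highpass_hz, "highpass",
                      fs=fs, output="sos"),
        signal.butter(spec.lowpass_order, spec.lowpass_hz, "lowpass",
                      fs=fs, output="sos"),
        signal.butter(spec.bandstop_order, spec.bandstop_hz, "bandstop",
                      fs=fs, output="sos"),
    ]


def apply_filters(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase high-pass, low-pass and line-noise band-stop filtering."""
    spec = spec or FilterSpec()
    soss = _sos_chain(spec, rec.fs)
    min_len = 3 * max(s.shape[0] * 2 for s in soss) + 1
    if rec.n_samples < min_len:
        raise ValueError("recording shorter than the filter warm-up")
    out = rec.data
    for sos in soss:
        out = signal.sosfiltfilt(sos, out, axis=1)
    new = rec.copy_with(out)
    new.meta["filters"] = {
        "highpass_hz": spec.highpass_hz, "lowpass_hz": spec.lowpass_hz,
        "bandstop_hz": list(spec.bandstop_hz), "design": "butter sosfiltfilt"}
    return new


def decompose(rec: Recording, n_dims: int = 16, seed: int = 0) -> ComponentDecomposition:
    """PCA to ``n_dims`` then extended Infomax ICA on the EEG channels.

    EOG and reference channels are excluded from the decomposition input.
    Deterministic given ``seed``.
    """
    picks = rec.picks(role="eeg")
    if len(picks) < n_dims:
        raise ValueError(f"need at least {n_dims} EEG channels, have {len(picks)}")
    X = rec.data[picks]
    if X.shape[1] <= X.shape[0]:
        raise ValueError("need more samples than channels")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    # PCA via SVD; components scaled to unit variance for the ICA step
    U, s, _ = np.linalg.svd(Xc @ Xc.T / Xc.shape[1])
    if s[n_dims - 1] <= 1e-12 * s[0]:
        raise ValueError("data rank below the requested dimensionality")
    W_pca = (U[:, :n_dims] / np.sqrt(s[:n_dims])).T      # n_dims × channels
    scores = W_pca @ Xc                                   # whitened
    W_ica = infomax(scores.T, extended=True, rng=seed, verbose="error")
    unmix = W_ica @ W_pca                                 # comps × channels
    mix = np.linalg.pinv(unmix)
    acts = unmix @ Xc
    return ComponentDecomposition(
        unmixing=unmix, mixing=mix, activations=acts,
        channel_labels=[rec.channel_labels[i] for i in picks],
        mean=mean.ravel(), n_dims=n_dims, seed=seed,
        meta={"fs": rec.fs, "algorithm": "pca+extended-infomax",
              "events": [ev.as_tuple for ev in rec.events]})


def welch_spectrum(x: np.ndarray, fs: float, window_s: float = 1.0,
                   overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD with a Hamming window; frequency resolution 1/window_s."""
    nperseg = int(round(window_s * fs))
    if len(x) < 2 * nperseg:
        raise ValueError("signal shorter than two Welch windows")
    freqs, pxx = signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                              noverlap=int(nperseg * overlap), detrend="constant")
    return PowerSpectrum(freqs=freqs, power=pxx, window_s=window_s, overlap=overlap)


def component_spectra(decomp: ComponentDecomposition, fs: float | None = None,
                      window_s: float = 1.0, overlap: float = 0.5,
                      ) -> list[PowerSpectrum]:
    """Welch spectrum of each component activation (1 s window, 50 % overlap)."""
    fs = fs if fs is not None else decomp.meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate not available")
    return [welch_spectrum(decomp.activations[i], fs, window_s, overlap)
            for i in range(decomp.n_components)]


def backproject(decomp: ComponentDecomposition, keep: list[int],
                rec: Recording | None = None) -> Recording:
    """Sensor-space signal of the kept components: ``mixing[:, keep] @ acts``.

    If ``rec`` is given, the result is embedded back into a copy of it (EEG
    channels replaced, events preserved); otherwise an EEG-only Recording is
    returned.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    if any(k < 0 or k >= decomp.n_components for k in keep):
        raise ValueError("invalid component id in keep set")
    sensor = decomp.mixing[:, keep] @ decomp.activations[keep, :]
    if rec is not None:
        out = rec.data.copy()
        for j, label in enumerate(decomp.channel_labels):
            out[rec.channel_index(label)] = sensor[j]
        new = rec.copy_with(out)
        new.meta["backprojected_components"] = keep
        return new
    from .recording import Event
    fs = decomp.meta.get("fs", 0.0)
    events = [Event(s, l) for s, l in decomp.meta.get("events", [])]
    return Recording(data=sensor, channel_labels=list(decomp.channel_labels),
                     channel_roles=["eeg"] * len(decomp.channel_labels),
                     fs=fs, events=events,
                     meta={"backprojected_components": keep})
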