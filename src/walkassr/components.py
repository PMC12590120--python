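"""Selection of ASSR and alpha ICA components from their spectra/topographies.

ASSR components are accepted when the parameterized spectrum shows a peak
within ±0.5 Hz of either amplitude-modulation rate (39 or 41 Hz) with an
over-aperiodic height above a stated threshold ("clear ASSR signal" made
operational).

Alpha components must satisfy four criteria: (1) a local power peak between
6 and 14 Hz; (2) peak width — the distance between the two adjacent local
minima — of at least 4 Hz, taking the widest local peak when several exist;
(3) power at the peak at least three times the mean power between 20 and
50 Hz; (4) the maximum absolute topography weight over the occipital sensors
(O1, O2, POz) exceeding the maximum over all other sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ComponentDecomposition, PowerSpectrum
from .specparam import ParameterizedSpectrum, fit_parameterized

__all__ = ["AlphaCriteria", "SelectionReport",
           "select_assr_components", "select_alpha_components"]


@dataclass(frozen=True)
class AlphaCriteria:
    """Constants of the four alpha-component criteria."""

    peak_band: tuple[float, float] = (6.0, 14.0)
    min_peak_width_hz: float = 4.0
    ratio_band: tuple[float, float] = (20.0, 50.0)
    min_ratio: float = 3.0
    occipital_labels: tuple[str, ...] = ("O1", "O2", "POz")


@dataclass
class SelectionReport:
    """Per-component outcome with the measured quantities behind each check."""

    component: int
    accepted: bool
    criteria: dict = field(default_factory=dict)   # name -> bool
    measures: dict = field(default_factory=dict)   # name -> value


# ---------------------------------------------------------------------------

def select_assr_components(decomp: ComponentDecomposition,
                           spectra: list[PowerSpectrum],
                           target_hzs: tuple[float, ...] = (39.0, 41.0),
                           center_tol: float = 0.5,
                           min_height: float = 0.10,
                           parameterized: list[ParameterizedSpectrum] | None = None,
                           ) -> list[SelectionReport]:
    """Accept components whose parameterized spectrum has a peak within
    ``center_tol`` of one of ``target_hzs`` and height ≥ ``min_height``
    (log10 over-aperiodic units)."""
    if len(spectra) != decomp.n_components:
        raise ValueError("one spectrum per component required")
    if parameterized is None:
        parameterized = [fit_parameterized(s) for s in spectra]
    reports = []
    for i, ps in enumerate(parameterized):
        best = None
        for p in ps.peaks:
            d = min(abs(p.center_hz - f) for f in target_hzs)
            if d <= center_tol and (best is None or p.height_log10 > best[1]):
                best = (p.center_hz, p.height_log10)
        has_peak = best is not None
        tall = has_peak and best[1] >= min_height
        reports.append(SelectionReport(
            component=i, accepted=bool(has_peak and tall),
            criteria={"peak_at_target": has_peak, "height": tall},
            measures={"peak_center_hz": best[0] if best else None,
                      "peak_height_log10": best[1] if best else 0.0,
                      "threshold_log10": min_height}))
    return reports


# ---------------------------------------------------------------------------

def _local_extrema(power: np.ndarray) -> tuple[list[int], list[int]]:
    """Strict-neighbour local maxima/minima indices; plateaus break toward
    the lower frequency.  Endpoints count as minima for width bracketing."""
    maxima, minima = [], []
    n = len(power)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n - 1 and power[j + 1] == power[j]:
            j += 1  # plateau: represent by its lowest-frequency bin
        if power[i - 1] < power[i] and power[j] > power[j + 1]:
            maxima.append(i)
        elif power[i - 1] > power[i] and power[j] < power[j + 1]:
            minima.append(i)
        i = j + 1
    return maxima, minima


def _peak_width(power: np.ndarray, freqs: np.ndarray, peak_idx: int) -> tuple[float, float, float]:
    """Width between the two local minima adjacent to ``peak_idx`` (endpoints
    of the spectrum bracket when no interior minimum exists)."""
    _, minima = _local_extrema(power)
    left_candidates = [m for m in minima if m < peak_idx]
    right_candidates = [m for m in minima if m > peak_idx]
    li = max(left_candidates) if left_candidates else 0
    ri = min(right_candidates) if right_candidates else len(power) - 1
    return freqs[ri] - freqs[li], freqs[li], freqs[ri]


def select_alpha_components(decomp: ComponentDecomposition,
                            spectra: list[PowerSpectrum],
                            crit: AlphaCriteria | None = None,
                            ) -> list[SelectionReport]:
    """Apply the four alpha criteria to every component."""
    crit = crit or AlphaCriteria()
    if len(spectra) != decomp.n_components:
        raise ValueError("one spectrum per component required")
    occ_idx = [decomp.channel_labels.index(l) for l in crit.occipital_labels
               if l in decomp.channel_labels]
    if len(occ_idx) != len(crit.occipital_labels):
        missing = set(crit.occipital_labels) - set(decomp.channel_labels)
        raise ValueError(f"occipital sensors missing from decomposition: {missing}")
    other_idx = [i for i in range(len(decomp.channel_labels)) if i not in occ_idx]

    reports = []
    for ci, spec in enumerate(spectra):
        freqs, power = np.asarray(spec.freqs), np.asarray(spec.power)
        if freqs[-1] < crit.ratio_band[1]:
            raise ValueError("spectrum does not cover the 20–50 Hz ratio band")
        maxima, _ = _local_extrema(power)
        in_band = [m for m in maxima
                   if crit.peak_band[0] <= freqs[m] <= crit.peak_band[1]]
        c1 = len(in_band) > 0

        width = 0.0
        peak_idx = None
        if in_band:
            # widest local peak wins (also used for the ratio criterion)
            widths = [(_peak_width(power, freqs, m)[0], m) for m in in_band]
            width, peak_idx = max(widths, key=lambda wm: wm[0])
        c2 = width >= crit.min_peak_width_hz

        ratio = 0.0
        if peak_idx is not None:
            band_mean = power[(freqs >= crit.ratio_band[0])
                              & (freqs <= crit.ratio_band[1])].mean()
            ratio = float(power[peak_idx] / band_mean) if band_mean > 0 else np.inf
        c3 = ratio >= crit.min_ratio

        topo = np.abs(decomp.topography(ci))
        occ_max = float(topo[occ_idx].max())
        other_max = float(topo[other_idx].max()) if other_idx else -np.inf
        c4 = occ_max > other_max
        winner = decomp.channel_labels[int(np.argmax(topo))]

        reports.append(SelectionReport(
            component=ci, accepted=bool(c1 and c2 and c3 and c4),
            criteria={"peak_in_band": c1, "peak_width": c2,
                      "peak_ratio": c3, "occipital_topography": c4},
            measures={"peak_center_hz": float(freqs[peak_idx]) if peak_idx is not None else None,
                      "peak_width_hz": float(width), "peak_ratio": ratio,
                      "winning_sensor": winner}))
    return reports
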