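"""Spectral parameterization: aperiodic 1/f fit plus Gaussian peaks.

Separates a power spectrum into an aperiodic component, modelled in log-log
space as ``log10 P(f) = offset − exponent · log10 f`` (fixed mode, no knee —
appropriate for fit ranges ending below ~50 Hz), and periodic components
modelled as Gaussians in log-power over the aperiodic fit.  "Parameterized
power" of an oscillation is the over-aperiodic height of its peak in log10
units; this unit convention is recorded in the result.

Algorithm: robust aperiodic fit (iteratively down-weighting points that sit
above the fit, i.e. the peaks) → subtract → iteratively extract the largest
residual Gaussian until the height floor or the peak-count cap is reached →
joint refit of all Gaussians → final aperiodic refit on the peak-removed
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .preprocess import PowerSpectrum

__all__ = ["Peak", "ParameterizedSpectrum", "fit_parameterized",
           "parameterized_power", "alpha_band_power"]

ALPHA_BAND = (8.0, 14.0)


@dataclass(frozen=True)
class Peak:
    """A periodic component: centre (Hz), over-aperiodic height (log10 power
    units), and width (Hz, 2σ of the Gaussian)."""

    center_hz: float
    height_log10: float
    width_hz: float

    @property
    def sigma(self) -> float:
        return self.width_hz / 2


@dataclass
class ParameterizedSpectrum:
    """Joint aperiodic + periodic model of a power spectrum."""

    fit_range: tuple[float, float]
    offset: float
    exponent: float
    peaks: list[Peak]
    r_squared: float
    rmse: float
    meta: dict = field(default_factory=lambda: {
        "power_unit": "log10 over-aperiodic", "aperiodic_mode": "fixed"})

    @property
    def aperiodic(self) -> tuple[float, float]:
        return (self.offset, self.exponent)

    def aperiodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def model_log10(self, freqs: np.ndarray) -> np.ndarray:
        out = self.aperiodic_log10(freqs)
        for p in self.peaks:
            out = out + p.height_log10 * np.exp(
                -0.5 * ((freqs - p.center_hz) / p.sigma) ** 2)
        return out


def _gauss_sum(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for c, h, s in zip(params[0::3], params[1::3], params[2::3]):
        out += h * np.exp(-0.5 * ((freqs - c) / s) ** 2)
    return out


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray,
                      n_iter: int = 3) -> tuple[float, float]:
    """Linear fit in log-log, iteratively discarding points well above the
    fit (peak regions only push residuals upward)."""
    mask = np.ones_like(logf, dtype=bool)
    slope = intercept = 0.0
    for _ in range(n_iter):
        A = np.vstack([np.ones(mask.sum()), logf[mask]]).T
        intercept, slope = np.linalg.lstsq(A, logp[mask], rcond=None)[0]
        resid = logp - (intercept + slope * logf)
        sd = np.std(resid[mask])
        if sd == 0:
            break
        mask = resid <= np.median(resid[mask]) + 1.0 * sd
        if mask.sum() < 3:
            break
    return float(intercept), float(-slope)


def fit_parameterized(spec: PowerSpectrum, fit_range: tuple[float, float] = (1.0, 48.0),
                      max_peaks: int = 6, min_height: float = 0.05,
                      width_bounds_hz: tuple[float, float] = (1.0, 12.0),
                      ) -> ParameterizedSpectrum:
    """Fit the aperiodic + Gaussian-peak model on ``fit_range``.

    Parameters
    ----------
    spec : PowerSpectrum
        Strictly positive power on a frequency grid covering ``fit_range``.
    max_peaks : int
        Cap on extracted Gaussians (largest first).
    min_height : float
        Detection floor for over-aperiodic height, log10 units.
    width_bounds_hz : tuple
        Bounds on peak width (2σ), Hz.
    """
    lo, hi = fit_range
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    freqs = np.asarray(spec.freqs[m], dtype=float)
    power = np.asarray(spec.power[m], dtype=float)
    if freqs.size < 8:
        raise ValueError("fit range covers too few frequency bins")
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive on the fit range")
    logf, logp = np.log10(freqs), np.log10(power)

    offset, exponent = _robust_aperiodic(logf, logp)
    flat = logp - (offset - exponent * logf)

    # iterative peak extraction, largest residual first; each guess is
    # refined by a local single-Gaussian fit so its subtraction leaves no
    # shoulder artifacts, and guesses overlapping an earlier one are skipped
    smin, smax = width_bounds_hz[0] / 2, width_bounds_hz[1] / 2
    df = freqs[1] - freqs[0]
    guesses: list[tuple[float, float, float]] = []
    resid = flat.copy()
    for _ in range(max_peaks):
        order = np.argsort(resid)[::-1]
        i = None
        for cand in order:
            if resid[cand] < max(min_height, 2.0 * _noise_floor(resid)):
                break
            if all(abs(freqs[cand] - c) > 1.0 * s for c, _, s in guesses):
                i = int(cand)
                break
        if i is None:
            break
        h = resid[i]
        c = freqs[i]
        # width guess from half-height crossings; the walk also stops where
        # the residual turns upward again (a local minimum marks the border
        # to a neighbouring peak, so closely spaced peaks are not merged)
        half = h / 2
        r = i
        while (r + 1 < len(resid) and resid[r + 1] > half
               and resid[r + 1] <= resid[r]):
            r += 1
        # a rise before the half-crossing marks a neighbouring peak: keep the
        # margin bin out of the refinement window on that side
        r_margin = 0 if (r + 1 < len(resid) and resid[r + 1] > half) else 1
        l = i
        while (l - 1 >= 0 and resid[l - 1] > half
               and resid[l - 1] <= resid[l]):
            l -= 1
        l_margin = 0 if (l - 1 >= 0 and resid[l - 1] > half) else 1
        fwhm = max((r - l) * df, df)
        s = float(np.clip(fwhm / 2.355, smin, smax))
        # refine on the walk span; the candidate is a grid local maximum, so
        # its true centre lies within about one bin — pinning it there keeps
        # a neighbouring peak from capturing the fit
        local = slice(max(l - l_margin, 0), min(r + r_margin + 1, len(freqs)))
        if local.stop - local.start >= 4:
            s_hi = float(np.clip(2 * fwhm / 2.355, smin + 1e-6, smax))
            try:
                (c, h, s), _ = curve_fit(
                    _gauss_sum, freqs[local], resid[local], p0=[c, h, s],
                    bounds=([c - 0.75 * df, 0.0, smin],
                            [c + 0.75 * df, 2 * h, s_hi]),
                    maxfev=1000)
            except RuntimeError:
                pass
        if h < min_height:
            break
        guesses.append((float(c), float(h), float(s)))
        resid = resid - h * np.exp(-0.5 * ((freqs - c) / s) ** 2)

    peaks: list[Peak] = []
    if guesses:
        p0, lb, ub = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            # keep each refit Gaussian near its own peak (within a quarter
            # bin or half its width, whichever is larger)
            wiggle = max(s / 2, df / 4)
            lb += [max(lo, c - wiggle), 0.0, smin]
            ub += [min(hi, c + wiggle), 1.5 * max(h, 1e-3) + 1.0, smax]
        try:
            popt, _ = curve_fit(_gauss_sum, freqs, flat, p0=p0,
                                bounds=(lb, ub), maxfev=5000)
        except RuntimeError:
            popt = np.array(p0)
        for c, h, s in zip(popt[0::3], popt[1::3], popt[2::3]):
            if h >= min_height:
                peaks.append(Peak(float(c), float(h), float(2 * s)))
        peaks.sort(key=lambda p: -p.height_log10)
        # drop refit peaks that collapsed onto a taller neighbour
        kept: list[Peak] = []
        for p in peaks:
            if all(abs(p.center_hz - q.center_hz) > 0.75 * q.sigma
                   for q in kept):
                kept.append(p)
        peaks = kept

    # final aperiodic refit on the peak-removed spectrum
    peak_model = _gauss_sum(freqs, *[v for p in peaks
                                     for v in (p.center_hz, p.height_log10, p.sigma)])
    A = np.vstack([np.ones_like(logf), logf]).T
    coef = np.linalg.lstsq(A, logp - peak_model, rcond=None)[0]
    offset, exponent = float(coef[0]), float(-coef[1])

    model = (offset - exponent * logf) + peak_model
    err = logp - model
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    return ParameterizedSpectrum(
        fit_range=(lo, hi), offset=offset, exponent=exponent, peaks=peaks,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        rmse=float(np.sqrt(ss_res / len(freqs))))


def _noise_floor(resid: np.ndarray) -> float:
    """Robust scale of the flattened residual (median absolute deviation)."""
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def parameterized_power(ps: ParameterizedSpectrum,
                        target_hz: float | tuple[float, float],
                        tol: float = 1.0) -> float:
    """Over-aperiodic height (log10 units) of the peak nearest ``target_hz``.

    A scalar target returns the height of the detected peak whose centre lies
    within ``tol`` Hz (0 if none; ties broken by distance).  A ``(lo, hi)``
    band target returns the summed heights of all peaks with centres in the
    band, the convention used for alpha power.
    """
    lo, hi = ps.fit_range
    if isinstance(target_hz, tuple):
        blo, bhi = target_hz
        if not (lo <= blo <= bhi <= hi):
            raise ValueError("band outside fit range")
        return float(sum(p.height_log10 for p in ps.peaks
                         if blo <= p.center_hz <= bhi))
    if not lo <= target_hz <= hi:
        raise ValueError("target outside fit range")
    best = None
    for p in ps.peaks:
        d = abs(p.center_hz - target_hz)
        if d <= tol and (best is None or d < best[0]):
            best = (d, p.height_log10)
    return float(best[1]) if best else 0.0


def alpha_band_power(ps: ParameterizedSpectrum,
                     band: tuple[float, float] = ALPHA_BAND) -> float:
    """Summed over-aperiodic peak heights with centres in the alpha band."""
    return parameterized_power(ps, band)
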