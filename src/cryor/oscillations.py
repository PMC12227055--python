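"""Fourier analysis of coherent oscillations in fit residuals.

After subtracting a global multiexponential fit from ultrafast TA data,
the residuals on the wings of the ESA/GSB bands can carry damped cosine
oscillations from vibrational coherences. This module band-averages the
residuals, computes a tapered Fourier power spectrum on a uniform time
window and converts frequencies to wavenumbers. Peaks whose period
exceeds the analysis-window duration cannot be resolved and are flagged
as window artifacts rather than reported as vibrational modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import TAMatrix, TIME_UNITS
from .kinetics import GlobalLifetimeResults

__all__ = ["compute_residuals", "oscillation_spectrum",
           "OscillationSpectrum", "SpectralPeak", "C_CM_PER_S"]

#: speed of light in cm/s (exact)
C_CM_PER_S = 2.99792458e10


def compute_residuals(data: TAMatrix, fit: GlobalLifetimeResults) -> TAMatrix:
    """Data minus model reconstruction, on the same axes and units.

    Note the multiexponential model has no constant-offset term, so a
    constant added to the data propagates into the residuals.
    """
    if (data.wavelengths.size != fit.wavelengths.size
            or not np.allclose(data.wavelengths, fit.wavelengths)
            or data.times.size != fit.times.size
            or not np.allclose(data.times, fit.times)):
        raise ValueError("fit axes do not match the data axes")
    resid = data.values - fit.fitted_values
    return TAMatrix(data.wavelengths, data.times, resid,
                    time_unit=data.time_unit, signal_unit=data.signal_unit,
                    metadata={**data.metadata, "kind": "residuals"})


@dataclass
class SpectralPeak:
    wavenumber: float      # cm^-1
    power: float
    resolved: bool         # False -> window artifact

    @property
    def flag(self) -> str:
        return "resolved" if self.resolved else "window-artifact"


@dataclass
class OscillationSpectrum:
    """One-sided Fourier power spectrum of band-averaged residuals."""

    wavenumbers: np.ndarray        # cm^-1
    power: np.ndarray
    window_duration: float         # s
    resolution_floor: float        # cm^-1, = 1 / (c * window_duration)
    peaks: list[SpectralPeak]

    @property
    def dominant_resolved(self) -> SpectralPeak | None:
        resolved = [p for p in self.peaks if p.resolved]
        return max(resolved, key=lambda p: p.power) if resolved else None

    def summary(self) -> str:
        lines = ["Residual oscillation spectrum", "=" * 40,
                 f"window duration   : {self.window_duration:.4g} s",
                 f"resolution floor  : {self.resolution_floor:.4g} cm^-1"]
        for p in self.peaks:
            lines.append(f"peak {p.wavenumber:8.1f} cm^-1  power "
                         f"{p.power:.4g}  [{p.flag}]")
        return "\n".join(lines)


def _refine_peak(wn: np.ndarray, power: np.ndarray, i: int) -> float:
    """Parabolic sub-bin refinement of a local maximum position."""
    if i == 0 or i == power.size - 1:
        return float(wn[i])
    y0, y1, y2 = power[i - 1], power[i], power[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(wn[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(wn[i] + delta * (wn[i + 1] - wn[i - 1]) / 2.0)


def oscillation_spectrum(residuals: TAMatrix, band: tuple[float, float],
                         window: tuple[float, float], detrend: bool = True,
                         taper: bool = True, pad_factor: int = 8,
                         rel_threshold: float = 0.05) -> OscillationSpectrum:
    """Band-averaged residual power spectrum in wavenumbers.

    Parameters
    ----------
    residuals : TAMatrix of fit residuals
    band : wavelength range (nm) averaged before the transform
    window : time range in the data's own time unit; must be uniformly
        sampled within 1% and contain at least 8 samples
    detrend : remove a linear trend before tapering
    taper : apply a Hann taper (reduces spectral leakage)
    pad_factor : zero-padding factor; refines the frequency sampling of
        the reported peak positions without changing the physical
        resolution floor
    rel_threshold : local maxima below this fraction of the maximum
        power are not reported as peaks

    Notes
    -----
    The power normalization satisfies Parseval's identity: the summed
    power equals the summed squared (detrended, tapered) time-domain
    signal. The resolution floor is 1/(c T) for window duration T: an
    oscillation period longer than the window is not observable, so any
    peak below the floor is flagged as a window artifact.
    """
    trace = residuals.band_mean(*band)
    t = residuals.times
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 8:
        raise ValueError("analysis window must contain at least 8 samples")
    tw, x = t[mask], trace[mask].copy()
    dt = np.diff(tw)
    if (dt.max() - dt.min()) / dt.mean() > 0.01:
        raise ValueError("window is not uniformly sampled (>1% spacing "
                         "variation); resample the linear segment first")
    dt_s = float(dt.mean()) * TIME_UNITS[residuals.time_unit]
    duration = float(tw[-1] - tw[0]) * TIME_UNITS[residuals.time_unit]
    floor = 1.0 / (C_CM_PER_S * duration)
    if detrend:
        x = x - np.polyval(np.polyfit(tw, x, 1), tw)
    if taper:
        x = x * np.hanning(x.size)
    n = int(pad_factor) * x.size
    spec = np.fft.rfft(x, n=n)
    freqs = np.fft.rfftfreq(n, d=dt_s)
    # one-sided Parseval weights: sum(power) == sum(x^2)
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    power = weights * np.abs(spec) ** 2 / n
    wavenumbers = freqs / C_CM_PER_S
    peaks: list[SpectralPeak] = []
    top = power.max()
    if top > 0:
        for i in range(1, power.size - 1):
            if (power[i] > power[i - 1] and power[i] >= power[i + 1]
                    and power[i] >= rel_threshold * top):
                wn = _refine_peak(wavenumbers, power, i)
                peaks.append(SpectralPeak(wn, float(power[i]),
                                          resolved=wn >= floor))
        # a low-frequency component can pile up at the zero bin rather
        # than form an interior maximum; report it as an artifact peak
        if power[0] >= rel_threshold * top and power[0] > power[1]:
            peaks.insert(0, SpectralPeak(float(wavenumbers[0]),
                                         float(power[0]), resolved=False))
    return OscillationSpectrum(wavenumbers=wavenumbers, power=power,
                               window_duration=duration,
                               resolution_floor=floor, peaks=peaks)
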