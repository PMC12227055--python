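"""Core in-memory containers shared across the toolkit.

The central object is :class:`TAMatrix`, a wavelength x time matrix of
difference absorbance with declared units, used for both femtosecond
transient-absorption and flash-photolysis data. Steady-state titration
series and patch-clamp traces get small dedicated containers with the
same validation style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TAMatrix", "TitrationSpectra", "CurrentTrace"]

#: time-unit suffixes accepted in headers, and their value in seconds
TIME_UNITS = {"fs": 1e-15, "ps": 1e-12, "ns": 1e-9, "us": 1e-6,
              "ms": 1e-3, "s": 1.0}


def _check_axis(name: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError(f"{name} axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} axis contains non-finite values")
    if np.any(np.diff(values) <= 0):
        raise ValueError(f"{name} axis not strictly increasing")
    return values


@dataclass
class TAMatrix:
    """Difference-absorbance matrix dA(wavelength, time).

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    times : array in `time_unit`, strictly increasing (may be negative
        around time zero for IRF-limited data)
    values : array, shape (n_wavelengths, n_times), in `signal_unit`
    time_unit : one of fs/ps/ns/us/ms/s
    signal_unit : "OD" or "mOD"
    metadata : free-form provenance (pH, excitation_nm, scenario, seed...)
    """

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray
    time_unit: str = "s"
    signal_unit: str = "mOD"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _check_axis("wavelength", self.wavelengths)
        self.times = _check_axis("time", self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.wavelengths.size, self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.wavelengths.size}, {self.times.size})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"unknown time unit {self.time_unit!r}; "
                             f"expected one of {sorted(TIME_UNITS)}")
        if self.signal_unit not in ("OD", "mOD"):
            raise ValueError("signal_unit must be 'OD' or 'mOD'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def band_mean(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Average the signal over a wavelength band; returns a time trace."""
        mask = (self.wavelengths >= lo_nm) & (self.wavelengths <= hi_nm)
        if not mask.any():
            raise ValueError(f"band [{lo_nm}, {hi_nm}] nm does not overlap "
                             "the wavelength axis")
        return self.values[mask].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t:.10g}" for t in self.times]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "wavelength_nm", self.wavelengths)
        return df


@dataclass
class TitrationSpectra:
    """Steady-state absorbance spectra A(wavelength) keyed by pH."""

    wavelengths: np.ndarray
    ph_values: np.ndarray
    values: np.ndarray  # (n_wavelengths, n_pH), OD
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _check_axis("wavelength", self.wavelengths)
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        if self.ph_values.ndim != 1 or self.ph_values.size == 0:
            raise ValueError("pH axis must be a non-empty 1-D array")
        if np.unique(self.ph_values).size != self.ph_values.size:
            raise ValueError("duplicate pH values")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.wavelengths.size, self.ph_values.size):
            raise ValueError("values shape does not match axes")

    def spectrum(self, ph: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.ph_values, ph))
        if idx.size == 0:
            raise KeyError(f"no spectrum at pH {ph}")
        return self.values[:, idx[0]]

    def reorder(self, order: np.ndarray) -> "TitrationSpectra":
        order = np.asarray(order, dtype=int)
        return TitrationSpectra(self.wavelengths, self.ph_values[order],
                                self.values[:, order], dict(self.metadata))


@dataclass
class CurrentTrace:
    """Whole-cell photocurrent trace for one (voltage, excitation) condition.

    Currents are in pA with the electrophysiology sign convention
    (negative = inward); `pulse_times` are the laser-pulse onsets in s.
    """

    times: np.ndarray      # s
    current: np.ndarray    # pA
    voltage: float         # mV
    excitation: float      # nm
    pulse_times: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _check_axis("time", self.times)
        self.current = np.asarray(self.current, dtype=float)
        if self.current.shape != self.times.shape:
            raise ValueError("current and time arrays differ in length")
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_times.size == 0:
            raise ValueError("at least one pulse time required")
        if self.pulse_times[0] <= self.times[0]:
            raise ValueError("no pre-pulse samples available for baseline")
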