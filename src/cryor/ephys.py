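"""Patch-clamp photocurrent analysis: charge integration and
subpopulation algebra.

Transient photocurrents elicited by nanosecond laser pulses are
baseline-corrected and integrated pulse by pulse until the transferred
charge falls below a floor ("until the photocurrents ceased"). Charge
ratios between two holding voltages then estimate the voltage-dependent
split of the ground state into subpopulations with nonprotonated
(probed at 500 nm) and protonated (620 nm) counterion complexes:

    alpha = Q500(0 mV) / Q500(-40 mV) = p_non(0) / p_non(-40)
    beta  = Q620(0 mV) / Q620(-40 mV) = (1 - p_non(0)) / (1 - p_non(-40))
    p_non(0 mV)   = alpha (1 - beta) / (alpha - beta)
    p_non(-40 mV) = (1 - beta) / (alpha - beta)

with the two fractions at each voltage summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CurrentTrace

__all__ = ["ChargeRecord", "FractionEstimate", "integrate_charge",
           "subpopulation_fractions", "reversal_voltage"]

_REL_EQ = 1e-9  # relative tolerance for the alpha == beta degeneracy


@dataclass
class ChargeRecord:
    """Integrated charges for one (excitation, voltage) trace."""

    excitation: float          # nm
    voltage: float             # mV
    per_pulse_pC: np.ndarray
    total_pC: float
    baseline_pA: float
    n_pulses_used: int

    def summary(self) -> str:
        pulses = ", ".join(f"{q:.3g}" for q in self.per_pulse_pC)
        return (f"Charge record ({self.excitation:g} nm, "
                f"{self.voltage:+g} mV): total {self.total_pC:.4g} pC over "
                f"{self.n_pulses_used} pulses [{pulses}]")


def integrate_charge(trace: CurrentTrace,
                     baseline_window: tuple[float, float] | None = None,
                     pulse_window: float | None = None,
                     floor_frac: float = 0.01,
                     floor_pC: float | None = None) -> ChargeRecord:
    """Baseline-corrected trapezoidal charge integration over pulses.

    The baseline is the mean current over `baseline_window` (default:
    everything before the first pulse). Each pulse is integrated over
    `pulse_window` seconds after its onset (default: the pulse spacing,
    or the remaining trace for a single pulse). Accumulation stops at
    the first pulse whose |charge| falls below the floor — an absolute
    `floor_pC` if given, otherwise `floor_frac` of the first pulse's
    magnitude. Signed totals are preserved (inward currents stay
    negative).
    """
    t, current = trace.times, trace.current
    pulses = np.sort(trace.pulse_times)
    if baseline_window is None:
        baseline_window = (t[0], pulses[0])
    b0, b1 = baseline_window
    if b1 > pulses[0] + 1e-12:
        raise ValueError("baseline window must precede the first pulse")
    bmask = (t >= b0) & (t < b1)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(current[bmask].mean())
    if pulse_window is None:
        pulse_window = (float(np.min(np.diff(pulses))) if pulses.size > 1
                        else float(t[-1] - pulses[0]))
    if pulses.size > 1 and pulse_window > np.min(np.diff(pulses)) + 1e-12:
        raise ValueError("pulse windows overlap")
    if pulses[-1] >= t[-1]:
        raise ValueError("pulse window extends beyond the trace")
    corrected = current - baseline
    charges: list[float] = []
    floor = floor_pC
    for t_k in pulses:
        wmask = (t >= t_k) & (t < t_k + pulse_window)
        q = float(np.trapezoid(corrected[wmask], t[wmask]))  # pA s = pC
        if floor is None:
            floor = floor_frac * abs(q) if charges == [] else floor
        if charges and floor is not None and abs(q) < floor:
            break
        charges.append(q)
        if floor is None:
            floor = floor_frac * abs(q)
    per_pulse = np.asarray(charges)
    return ChargeRecord(excitation=trace.excitation, voltage=trace.voltage,
                        per_pulse_pC=per_pulse,
                        total_pC=float(per_pulse.sum()),
                        baseline_pA=baseline, n_pulses_used=per_pulse.size)


@dataclass
class FractionEstimate:
    """Voltage-dependent ground-state subpopulation fractions."""

    alpha: float
    beta: float
    p_nonprot_0mV: float
    p_nonprot_minus40mV: float
    valid: bool
    notes: str

    @property
    def p_prot_0mV(self) -> float:
        return 1.0 - self.p_nonprot_0mV

    @property
    def p_prot_minus40mV(self) -> float:
        return 1.0 - self.p_nonprot_minus40mV

    def summary(self) -> str:
        return ("Subpopulation fractions\n"
                f"alpha (Q500 0/-40)  : {self.alpha:.6g}\n"
                f"beta  (Q620 0/-40)  : {self.beta:.6g}\n"
                f"p_nonprot(0 mV)     : {self.p_nonprot_0mV:.6g}\n"
                f"p_nonprot(-40 mV)   : {self.p_nonprot_minus40mV:.6g}\n"
                f"valid               : {self.valid} ({self.notes})")


def subpopulation_fractions(q500_0mV: float, q500_m40mV: float,
                            q620_0mV: float, q620_m40mV: float
                            ) -> FractionEstimate:
    """Solve the charge-ratio constraint system for the fractions.

    Raises on zero denominator charges; alpha == beta (within relative
    1e-9) or fractions outside [0, 1] are reported with valid=False
    rather than clipped, since they signal inconsistent inputs.
    """
    for name, q in (("q500_m40mV", q500_m40mV), ("q620_m40mV", q620_m40mV)):
        if q == 0:
            raise ZeroDivisionError(f"{name} is zero; charge ratio undefined")
    alpha = q500_0mV / q500_m40mV
    beta = q620_0mV / q620_m40mV
    scale = max(abs(alpha), abs(beta), 1e-300)
    if abs(alpha - beta) <= _REL_EQ * scale:
        return FractionEstimate(alpha, beta, np.nan, np.nan, False,
                                "indeterminate (equal ratios)")
    p0 = alpha * (1.0 - beta) / (alpha - beta)
    pm40 = (1.0 - beta) / (alpha - beta)
    fracs = (p0, 1 - p0, pm40, 1 - pm40)
    ok = all(-1e-12 <= f <= 1 + 1e-12 for f in fracs)
    notes = "consistent" if ok else "fractions outside [0, 1]"
    return FractionEstimate(float(alpha), float(beta), float(p0),
                            float(pm40), ok, notes)


def reversal_voltage(voltages_mV: np.ndarray, amplitudes: np.ndarray
                     ) -> tuple[float | None, str]:
    """Reversal potential by linear interpolation between sign changes.

    Returns (voltage, note); voltage is None when the amplitudes never
    change sign within the sampled range.
    """
    v = np.asarray(voltages_mV, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 voltages")
    if np.unique(v).size != v.size:
        raise ValueError("duplicate voltages")
    order = np.argsort(v)
    v, a = v[order], a[order]
    exact = np.flatnonzero(a == 0)
    if exact.size:
        return float(v[exact[0]]), "amplitude crosses zero at a sample"
    for i in range(v.size - 1):
        if a[i] * a[i + 1] < 0:
            vr = v[i] - a[i] * (v[i + 1] - v[i]) / (a[i + 1] - a[i])
            return float(vr), "interpolated between bracketing voltages"
    return None, "no reversal in range"
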