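"""Steady-state spectral models: pH titration and photochromic switching.

The titration model describes the dark-state spectrum as a pH-weighted
mixture of spectral species (Gaussian bands in wavelength), with weights
from a sequential-protonation Henderson-Hasselbalch scheme. The
photoswitch model is a two-state (ground <-> M) photochromic system
driven by LED illumination with thermal back-relaxation, reproducing
photostationary-state (PSS) formation and blue-light quenching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import argrelmax

from .datatypes import TitrationSpectra

__all__ = [
    "SpectralBand", "gaussian_bands", "TitrationModel", "titration_fractions",
    "TitrationFitModel", "TitrationFitResults", "fit_titration",
    "lambda_max", "lambda_max_shift", "normalize_at_reference",
    "LEDSource", "PhotoswitchModel", "simulate_illumination",
    "IlluminationResult",
]

_LN10 = np.log(10.0)

# physical constants (SI): Planck, speed of light, Avogadro
_H = 6.62607015e-34
_C = 2.99792458e8
_NA = 6.02214076e23


@dataclass(frozen=True)
class SpectralBand:
    """Gaussian absorption band parameterized in wavelength."""

    center: float      # nm
    width: float       # Gaussian sigma, nm
    amplitude: float

    def __post_init__(self) -> None:
        if not 250.0 <= self.center <= 800.0:
            raise ValueError("band center must lie in [250, 800] nm")
        if self.width <= 0:
            raise ValueError("band width must be positive")


def gaussian_bands(wavelengths: np.ndarray,
                   bands: list[SpectralBand]) -> np.ndarray:
    lam = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(lam)
    for b in bands:
        out += b.amplitude * np.exp(-0.5 * ((lam - b.center) / b.width) ** 2)
    return out


def _as_bands(bands) -> list[SpectralBand]:
    out = []
    for b in bands:
        if isinstance(b, SpectralBand):
            out.append(b)
        else:
            out.append(SpectralBand(b["center_nm"], b["sigma_nm"],
                                    b["amplitude"]))
    return out


# ---------------------------------------------------------------------------
# titration


@dataclass
class TitrationModel:
    """Ordered (acidic -> alkaline) spectral species with pKa-linked weights.

    `species` maps name -> band list; `pkas` has one entry fewer than
    species; `hill` holds one Hill coefficient per pKa (default 1,
    single-proton transitions).
    """

    species: list[tuple[str, list[SpectralBand]]]
    pkas: np.ndarray
    hill: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pkas = np.atleast_1d(np.asarray(self.pkas, dtype=float))
        if len(self.species) != self.pkas.size + 1:
            raise ValueError("need exactly one pKa per species transition")
        if self.pkas.size > 1 and np.any(np.diff(self.pkas) <= 0):
            raise ValueError("pKa values must be strictly increasing")
        if self.hill is None:
            self.hill = np.ones_like(self.pkas)
        else:
            self.hill = np.atleast_1d(np.asarray(self.hill, dtype=float))
            if self.hill.shape != self.pkas.shape or np.any(self.hill <= 0):
                raise ValueError("one positive Hill coefficient per pKa")

    def spectrum(self, wavelengths: np.ndarray, ph: float) -> np.ndarray:
        fracs = titration_fractions(ph, self)
        out = np.zeros_like(np.asarray(wavelengths, dtype=float))
        for f, (_, bands) in zip(fracs, self.species):
            out += f * gaussian_bands(wavelengths, bands)
        return out


def titration_fractions(ph: float, model: TitrationModel) -> np.ndarray:
    """Species fractions at a given pH for the sequential scheme.

    The weight of species s (0 = most acidic) is the product of
    Henderson-Hasselbalch deprotonation factors 10^(n_j (pH - pKa_j))
    over the transitions j < s; fractions are the normalized weights and
    sum to 1. Computed in log space for numerical stability.
    """
    logw = np.concatenate(
        [[0.0], np.cumsum(model.hill * (ph - model.pkas) * _LN10)])
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


@dataclass
class TitrationFitResults:
    """Joint decomposition of a pH series into spectral species."""

    model: TitrationModel
    residual_rms: float
    success: bool
    pka_stderr: np.ndarray | None
    fit_window: tuple[float, float]
    nfev: int

    @property
    def pkas(self) -> np.ndarray:
        return self.model.pkas

    @property
    def band_centers(self) -> np.ndarray:
        """Visible band center per species, ordered acidic -> alkaline."""
        return np.array([bands[0].center for _, bands in self.model.species])

    def summary(self) -> str:
        lines = ["pH titration decomposition", "=" * 40,
                 f"species          : {len(self.model.species)}",
                 f"fit window       : {self.fit_window[0]:g}-"
                 f"{self.fit_window[1]:g} nm",
                 f"residual RMS     : {self.residual_rms:.4g}",
                 f"converged        : {self.success}"]
        for i, (name, bands) in enumerate(self.model.species):
            b = bands[0]
            lines.append(f"{name:<16} : center {b.center:.1f} nm, sigma "
                         f"{b.width:.1f} nm, amplitude {b.amplitude:.3f}")
        for j, pka in enumerate(self.model.pkas):
            err = ""
            if self.pka_stderr is not None and np.isfinite(self.pka_stderr[j]):
                err = f" +/- {self.pka_stderr[j]:.2g}"
            lines.append(f"pKa_{j + 1:<12} : {pka:.3f}{err}")
        return "\n".join(lines)


class TitrationFitModel:
    """Joint nonlinear least squares over pKa values and band parameters.

    Each species carries one Gaussian band inside `fit_window` (default
    320-780 nm, excluding the aromatic 280-nm region); fractions follow
    :func:`titration_fractions`. Initialization is heuristic (peak
    positions of the extreme-pH spectra) unless explicit centers are
    supplied.
    """

    def __init__(self, spectra: TitrationSpectra, n_species: int,
                 init: str | list[float] = "heuristic",
                 fit_window: tuple[float, float] = (320.0, 780.0)):
        if n_species < 1:
            raise ValueError("n_species must be >= 1")
        if spectra.ph_values.size < 2 * n_species:
            raise ValueError("need at least 2 x n_species distinct pH points")
        self.spectra = spectra
        self.n_species = n_species
        self.fit_window = fit_window
        mask = ((spectra.wavelengths >= fit_window[0])
                & (spectra.wavelengths <= fit_window[1]))
        if mask.sum() < 5:
            raise ValueError("fit window too narrow for the wavelength axis")
        self._lam = spectra.wavelengths[mask]
        order = np.argsort(spectra.ph_values)
        self._ph = spectra.ph_values[order]
        self._obs = spectra.values[mask][:, order]
        self._init = init

    def _initial_centers(self) -> np.ndarray:
        """Candidate band centers, ordered acidic -> alkaline (red -> blue)."""
        if not isinstance(self._init, str):
            centers = np.asarray(self._init, dtype=float)
            if centers.size != self.n_species:
                raise ValueError("need one initial center per species")
            return centers
        cand: list[float] = []
        for col in (0, self._obs.shape[1] // 2, -1):
            spec = self._obs[:, col]
            for i in argrelmax(spec, order=3)[0]:
                if spec[i] > 0.1 * spec.max():
                    cand.append(self._lam[i])
        uniq: list[float] = []
        for c in sorted(cand, reverse=True):
            if all(abs(c - u) > 40.0 for u in uniq):
                uniq.append(c)
        while len(uniq) < self.n_species:
            uniq.append(self._lam[0] + 50.0 * len(uniq))
        return np.asarray(uniq[: self.n_species])

    def fit(self) -> TitrationFitResults:
        n = self.n_species
        centers0 = self._initial_centers()
        amp_scale = max(self._obs.max(), 1e-6)
        params = lmfit.Parameters()
        ph_lo, ph_hi = self._ph[0], self._ph[-1]
        for j in range(n - 1):
            frac = (j + 1) / n
            params.add(f"pka{j}", value=ph_lo + frac * (ph_hi - ph_lo),
                       min=ph_lo - 3.0, max=ph_hi + 3.0)
        for s in range(n):
            params.add(f"c{s}", value=centers0[s], min=self._lam[0] - 30,
                       max=self._lam[-1] + 30)
            params.add(f"w{s}", value=30.0, min=5.0, max=120.0)
            params.add(f"a{s}", value=amp_scale, min=0.0)

        def residual(p):
            pkas = np.array([p[f"pka{j}"].value for j in range(n - 1)])
            if np.any(np.diff(pkas) <= 0):   # keep ordering identifiable
                pkas = np.sort(pkas)
            bands = [(f"s{s}", [SpectralBand(
                float(np.clip(p[f"c{s}"].value, 250, 800)),
                p[f"w{s}"].value, p[f"a{s}"].value)]) for s in range(n)]
            model = TitrationModel(bands, pkas) if n > 1 else TitrationModel(
                bands, np.empty(0))
            sim = np.column_stack(
                [model.spectrum(self._lam, ph) for ph in self._ph])
            return (sim - self._obs).ravel()

        out = lmfit.minimize(residual, params, method="least_squares")
        p = out.params
        pkas = np.sort([p[f"pka{j}"].value for j in range(n - 1)])
        species = [(f"species_{s}", [SpectralBand(
            float(np.clip(p[f"c{s}"].value, 250, 800)),
            float(p[f"w{s}"].value), float(p[f"a{s}"].value))])
            for s in range(n)]
        # order species red -> blue so index 0 is the most acidic form
        order = np.argsort([-b[1][0].center for b in species])
        species = [species[i] for i in order]
        model = TitrationModel(species, np.asarray(pkas) if n > 1
                               else np.empty(0))
        rms = float(np.sqrt(np.mean(out.residual ** 2)))
        stderr = None
        if n > 1:
            errs = [p[f"pka{j}"].stderr for j in range(n - 1)]
            if all(e is not None for e in errs):
                stderr = np.asarray(errs, dtype=float)
        if not out.success:
            raise RuntimeError(
                f"titration fit did not converge: {out.message}; check "
                f"n_species against the identifiable rank of the data")
        return TitrationFitResults(model=model, residual_rms=rms,
                                   success=bool(out.success),
                                   pka_stderr=stderr,
                                   fit_window=self.fit_window,
                                   nfev=out.nfev)


def fit_titration(spectra: TitrationSpectra, n_species: int,
                  init: str | list[float] = "heuristic",
                  **kwargs) -> TitrationFitResults:
    """Functional front end for :class:`TitrationFitModel`."""
    return TitrationFitModel(spectra, n_species, init=init, **kwargs).fit()


# ---------------------------------------------------------------------------
# lambda-max tracking


def lambda_max(wavelengths: np.ndarray, spectrum: np.ndarray,
               window: tuple[float, float]) -> tuple[float, bool]:
    """Interpolated absorption maximum within a wavelength window.

    Returns (lambda_max, interpolated). A parabola through the discrete
    maximum and its neighbours refines the position; for a flat top or an
    edge maximum the discrete argmax is returned with interpolated=False.
    """
    lam = np.asarray(wavelengths, dtype=float)
    mask = (lam >= window[0]) & (lam <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} does not overlap the axis")
    lam_w, spec_w = lam[mask], np.asarray(spectrum, dtype=float)[mask]
    i = int(np.argmax(spec_w))
    if i == 0 or i == spec_w.size - 1:
        return float(lam_w[i]), False
    y0, y1, y2 = spec_w[i - 1], spec_w[i], spec_w[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat top or degenerate curvature
        return float(lam_w[i]), False
    delta = 0.5 * (y0 - y2) / denom
    x = lam_w[i] + delta * (lam_w[i + 1] - lam_w[i - 1]) / 2.0
    return float(x), True


def lambda_max_shift(spectra: TitrationSpectra,
                     window: tuple[float, float] = (450.0, 700.0)
                     ) -> tuple[pd.DataFrame, float]:
    """Track lambda_max(pH) in a visible window and report the total shift.

    The shift is lambda_max at the lowest pH minus lambda_max at the
    highest pH (positive for an acid-induced red shift).
    """
    rows = []
    for j, ph in enumerate(spectra.ph_values):
        lmax, interp = lambda_max(spectra.wavelengths, spectra.values[:, j],
                                  window)
        rows.append({"pH": float(ph), "lambda_max_nm": lmax,
                     "interpolated": interp})
    table = pd.DataFrame(rows).sort_values("pH", ignore_index=True)
    shift = float(table["lambda_max_nm"].iloc[0]
                  - table["lambda_max_nm"].iloc[-1])
    return table, shift


def normalize_at_reference(wavelengths: np.ndarray, spectrum: np.ndarray,
                           reference_wavelength: float = 280.0) -> np.ndarray:
    """Divide a spectrum by its absorbance at a reference wavelength.

    The nearest axis point is used; it must lie within one axis spacing
    of the requested wavelength, and the reference absorbance must be
    positive.
    """
    lam = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    i = int(np.argmin(np.abs(lam - reference_wavelength)))
    spacing = np.max(np.diff(lam)) if lam.size > 1 else np.inf
    if abs(lam[i] - reference_wavelength) > spacing:
        raise ValueError(f"reference wavelength {reference_wavelength} nm "
                         "is outside the sampled axis")
    ref = spec[i]
    if ref <= 0:
        raise ValueError("reference absorbance must be positive")
    return spec / ref


# ---------------------------------------------------------------------------
# photoswitch / illumination model


@dataclass(frozen=True)
class LEDSource:
    """LED emitter modeled as a unit-area Gaussian emission line."""

    center: float          # nm
    fwhm: float            # nm
    power: float           # mW
    beam_area: float = 1.0  # cm^2

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("LED power must be >= 0")
        if self.fwhm <= 0 or self.beam_area <= 0:
            raise ValueError("LED fwhm and beam area must be positive")

    @property
    def photon_flux(self) -> float:
        """Photons per cm^2 per second at the band center energy."""
        photon_energy = _H * _C / (self.center * 1e-9)
        return (self.power * 1e-3) / (photon_energy * self.beam_area)


@dataclass
class PhotoswitchModel:
    """Two-state photochromic system: ground <-> M.

    Photoexcitation rates are phi x photon flux x absorption cross
    section, with the cross section from `extinction_scale`
    (M^-1 cm^-1 per unit band amplitude) times the spectral overlap of
    the species bands with the LED emission line. The M state also decays
    thermally with `k_thermal`.
    """

    ground_spectrum: list[SpectralBand]
    m_spectrum: list[SpectralBand]
    phi_forward: float = 0.3
    phi_back: float = 0.3
    k_thermal: float = 1.0 / 942.0   # 1/s
    extinction_scale: float = 45000.0

    def __post_init__(self) -> None:
        for phi in (self.phi_forward, self.phi_back):
            if not 0 < phi <= 1:
                raise ValueError("quantum yields must lie in (0, 1]")
        if self.k_thermal <= 0:
            raise ValueError("k_thermal must be positive")

    def _overlap(self, bands: list[SpectralBand], led: LEDSource) -> float:
        """Analytic overlap of the band set with the unit-area LED line."""
        sig_led = led.fwhm / 2.3548200450309493  # fwhm -> sigma
        total = 0.0
        for b in bands:
            var = b.width ** 2 + sig_led ** 2
            total += (b.amplitude * b.width / np.sqrt(var)
                      * np.exp(-0.5 * (b.center - led.center) ** 2 / var))
        return total

    def rates(self, led: LEDSource | None) -> tuple[float, float]:
        """(k_GM, k_MG) photoexcitation rates under a given LED (or dark)."""
        if led is None or led.power == 0:
            return 0.0, 0.0
        # epsilon (M^-1 cm^-1) -> cross section (cm^2): 1000 ln10 / N_A
        xsec = 1000.0 * _LN10 / _NA * self.extinction_scale
        k_gm = self.phi_forward * led.photon_flux * xsec * self._overlap(
            self.ground_spectrum, led)
        k_mg = self.phi_back * led.photon_flux * xsec * self._overlap(
            self.m_spectrum, led)
        return k_gm, k_mg

    def composite_spectrum(self, wavelengths: np.ndarray,
                           ground_fraction: float) -> np.ndarray:
        return (ground_fraction * gaussian_bands(wavelengths,
                                                 self.ground_spectrum)
                + (1 - ground_fraction) * gaussian_bands(wavelengths,
                                                         self.m_spectrum))


@dataclass
class IlluminationResult:
    """Ground-state trajectory and checkpoint spectra for a protocol."""

    trajectory: pd.DataFrame             # columns time_s, ground_fraction
    checkpoints: list[dict]              # per protocol step
    wavelengths: np.ndarray

    @property
    def final_ground_fraction(self) -> float:
        return float(self.trajectory["ground_fraction"].iloc[-1])

    def summary(self) -> str:
        lines = ["Illumination protocol", "=" * 40]
        for c in self.checkpoints:
            lines.append(f"{c['label']:<18} t={c['time_s']:8.1f} s  "
                         f"ground fraction {c['ground_fraction']:.4f}")
        return "\n".join(lines)


def simulate_illumination(model: PhotoswitchModel,
                          protocol: list[tuple[LEDSource | None, float]],
                          initial: float = 1.0,
                          wavelengths: np.ndarray | None = None,
                          samples_per_step: int = 60) -> IlluminationResult:
    """Integrate the two-state system through an ordered LED protocol.

    Each protocol entry is (LEDSource or None for dark, duration in s).
    Within a step the rates are constant, so the exact piecewise solution
    G(t) = G_ss + (G_0 - G_ss) exp(-kappa t) is used, with
    kappa = k_GM + k_MG + k_thermal and
    G_ss = (k_MG + k_thermal) / kappa.
    """
    if not 0.0 <= initial <= 1.0:
        raise ValueError("initial ground fraction must lie in [0, 1]")
    if not protocol:
        raise ValueError("protocol must contain at least one step")
    if wavelengths is None:
        wavelengths = np.arange(250.0, 751.0, 2.0)
    times, fracs, checkpoints = [0.0], [float(initial)], []
    t_abs, g = 0.0, float(initial)
    for step, (led, duration) in enumerate(protocol):
        if duration <= 0:
            raise ValueError(f"protocol step {step}: duration must be > 0")
        k_gm, k_mg = model.rates(led)
        kappa = k_gm + k_mg + model.k_thermal
        g_ss = (k_mg + model.k_thermal) / kappa
        tloc = np.linspace(0.0, duration, samples_per_step + 1)[1:]
        gseg = g_ss + (g - g_ss) * np.exp(-kappa * tloc)
        times.extend((t_abs + tloc).tolist())
        fracs.extend(gseg.tolist())
        t_abs += duration
        g = float(gseg[-1])
        label = "dark" if led is None else f"LED {led.center:g} nm"
        checkpoints.append({
            "label": label, "time_s": t_abs, "ground_fraction": g,
            "spectrum": model.composite_spectrum(wavelengths, g)})
    traj = pd.DataFrame({"time_s": times, "ground_fraction": fracs})
    return IlluminationResult(trajectory=traj, checkpoints=checkpoints,
                              wavelengths=wavelengths)
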