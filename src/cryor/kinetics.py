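"""Photocycle kinetics: simulation and time-resolved fitting.

Three fitting engines operate on :class:`~cryor.datatypes.TAMatrix` data:

* :class:`GlobalLifetimeModel` — global multiexponential analysis by
  variable projection: a small set of lifetimes is shared across all
  wavelengths while the per-wavelength amplitudes (the decay-associated
  spectra, DAS) are solved linearly at every iterate. Optional Gaussian
  instrument-response convolution with fittable width and time zero.
* :class:`LifetimeDistributionModel` — model-free inversion onto a dense
  log-spaced lifetime grid with Tikhonov regularization, summarized as a
  lifetime-distribution map (LDM); transition lifetimes are read from the
  amplitude maxima of the distributions.
* :class:`RecoveryModel` — monoexponential fit of slow photostationary-
  state thermal recovery, with the illumination period subtracted from
  the time stamps before fitting.

Sequential unbranched photocycle chains (e.g. K -> M1 -> M2 -> ground)
are simulated with the closed-form Bateman solution in
:func:`simulate_chain`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import optimize, special

from .datatypes import TAMatrix

__all__ = [
    "KineticScheme", "simulate_chain", "exp_conv_irf",
    "GlobalLifetimeModel", "GlobalLifetimeResults", "global_lifetime_fit",
    "LifetimeDistributionModel", "LDMResult", "lifetime_distribution",
    "LifetimePeak", "pick_lifetimes",
    "RecoveryModel", "RecoveryFit", "fit_recovery",
]

_REL_GAP = 1e-9  # minimum relative spacing between chain lifetimes


# ---------------------------------------------------------------------------
# chain simulation


@dataclass
class KineticScheme:
    """Sequential first-order photocycle chain.

    `lifetimes[i]` is the lifetime of `states[i]`; the last transition
    returns to the recovered ground state. Species (difference) spectra
    may be attached as `{state: [band dicts]}` for dataset synthesis.
    """

    states: list[str]
    lifetimes: np.ndarray
    initial_state: str | None = None
    species_spectra: dict[str, list[dict]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        if len(self.states) != self.lifetimes.size:
            raise ValueError("need one lifetime per state")
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        tau = np.sort(self.lifetimes)
        if tau.size > 1 and np.any(np.diff(tau) / tau[:-1] <= _REL_GAP):
            raise ValueError(
                "degenerate chain: lifetimes closer than relative "
                f"{_REL_GAP:g}; perturb one of them")
        if self.initial_state is None:
            self.initial_state = self.states[0]
        if self.initial_state not in self.states:
            raise ValueError(f"unknown initial state {self.initial_state!r}")


def simulate_chain(scheme: KineticScheme, times: np.ndarray) -> np.ndarray:
    """Populations of a sequential first-order chain, states x times.

    Closed-form (Bateman) solution with unit population placed in
    `scheme.initial_state` at t = 0. States preceding the initial state
    stay at zero. Total population over states plus the recovered ground
    state is exactly 1.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    n = len(scheme.states)
    start = scheme.states.index(scheme.initial_state)
    rates = 1.0 / scheme.lifetimes
    pops = np.zeros((n, times.size))
    # Bateman cascade over the sub-chain beginning at the initial state
    for m in range(start, n):
        k_sub = rates[start:m + 1]
        prefac = np.prod(k_sub[:-1]) if m > start else 1.0
        acc = np.zeros_like(times)
        for i, ki in enumerate(k_sub):
            denom = np.prod(np.delete(k_sub, i) - ki) if k_sub.size > 1 else 1.0
            acc += np.exp(-ki * times) / denom
        pops[m] = prefac * acc
    return pops


# ---------------------------------------------------------------------------
# exponential basis with Gaussian IRF


def exp_conv_irf(t: np.ndarray, tau: float, sigma: float = 0.0,
                 t0: float = 0.0) -> np.ndarray:
    """Exponential decay convolved with a normalized Gaussian IRF.

    Returns exp(-(t-t0)/tau) (*) N(t0, sigma); reduces to a step
    exponential for sigma = 0. Numerically stable via erfcx for large
    positive arguments.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    x = t - t0
    if sigma < 0:
        raise ValueError("IRF width must be >= 0")
    if sigma == 0:
        out = np.zeros_like(x)
        pos = x >= 0
        out[pos] = np.exp(-x[pos] / tau)
        return out
    z = (sigma / tau - x / sigma) / np.sqrt(2.0)
    out = np.empty_like(x)
    hi = z >= 0
    # erfc(z) e^{s^2/2tau^2 - x/tau} = erfcx(z) e^{-x^2/2s^2} for z >= 0
    out[hi] = 0.5 * special.erfcx(z[hi]) * np.exp(-0.5 * (x[hi] / sigma) ** 2)
    lo = ~hi
    out[lo] = 0.5 * special.erfc(z[lo]) * np.exp(
        0.5 * (sigma / tau) ** 2 - x[lo] / tau)
    return out


def _basis(times: np.ndarray, lifetimes: np.ndarray, sigma: float,
           t0: float) -> np.ndarray:
    """(n_times, n_components) design matrix of IRF-convolved decays."""
    return np.column_stack([exp_conv_irf(times, tau, sigma, t0)
                            for tau in lifetimes])


# ---------------------------------------------------------------------------
# global lifetime analysis (DAS)


@dataclass
class GlobalLifetimeResults:
    """Decay-associated spectra and shared lifetimes from a global fit."""

    lifetimes: np.ndarray          # ascending, data time units
    das: np.ndarray                # (n_components, n_wavelengths)
    wavelengths: np.ndarray
    times: np.ndarray
    irf_width: float | None
    t0: float | None
    residual_rms: float
    success: bool
    message: str
    nfev: int
    stderr_lifetimes: np.ndarray | None = None
    time_unit: str = "s"

    @property
    def fitted_values(self) -> np.ndarray:
        """Model reconstruction on the data grid, wavelengths x times."""
        sigma = self.irf_width if self.irf_width is not None else 0.0
        t0 = self.t0 if self.t0 is not None else 0.0
        phi = _basis(self.times, self.lifetimes, sigma, t0)
        return (phi @ self.das).T

    def das_at(self, wavelength_lo: float, wavelength_hi: float) -> np.ndarray:
        mask = ((self.wavelengths >= wavelength_lo)
                & (self.wavelengths <= wavelength_hi))
        if not mask.any():
            raise ValueError("band does not overlap the wavelength axis")
        return self.das[:, mask].mean(axis=1)

    def summary(self) -> str:
        lines = ["Global lifetime analysis",
                 "=" * 40,
                 f"components       : {self.lifetimes.size}",
                 f"wavelengths      : {self.wavelengths.size}",
                 f"time points      : {self.times.size}",
                 f"residual RMS     : {self.residual_rms:.6g}",
                 f"converged        : {self.success}"]
        for i, tau in enumerate(self.lifetimes):
            err = ""
            if self.stderr_lifetimes is not None and np.isfinite(
                    self.stderr_lifetimes[i]):
                err = f" +/- {self.stderr_lifetimes[i]:.3g}"
            lines.append(f"tau_{i + 1:<2d}           : {tau:.6g}{err} "
                         f"{self.time_unit}")
        if self.irf_width is not None:
            lines.append(f"IRF sigma        : {self.irf_width:.6g} "
                         f"{self.time_unit}")
            lines.append(f"time zero        : {self.t0:.6g} {self.time_unit}")
        return "\n".join(lines)


class GlobalLifetimeModel:
    """Global multiexponential model for a TA matrix (variable projection).

    Parameters
    ----------
    data : TAMatrix
    n_components : number of shared lifetimes (1..8)
    irf : "fit" | "fixed" | "none"
        Gaussian IRF handling. "fixed" uses `irf_sigma` / `t0` as given;
        "fit" optimizes both; "none" uses an ideal step response.
    initial_lifetimes : optional starting lifetimes; defaults to the
        peaks of a quick lifetime-distribution analysis, padded with
        log-spaced guesses.
    """

    MAX_COMPONENTS = 8

    def __init__(self, data: TAMatrix, n_components: int, irf: str = "none",
                 initial_lifetimes=None, irf_sigma: float | None = None,
                 t0: float = 0.0):
        if not 1 <= n_components <= self.MAX_COMPONENTS:
            raise ValueError(
                f"n_components must be in [1, {self.MAX_COMPONENTS}]")
        if data.times.size < 3 * n_components:
            raise ValueError("need at least 3 time points per component")
        if irf not in ("fit", "fixed", "none"):
            raise ValueError("irf must be 'fit', 'fixed' or 'none'")
        if irf == "fixed" and (irf_sigma is None or irf_sigma <= 0):
            raise ValueError("irf='fixed' requires a positive irf_sigma")
        self.data = data
        self.n_components = n_components
        self.irf = irf
        self.irf_sigma = irf_sigma
        self.t0 = t0
        self.initial_lifetimes = (None if initial_lifetimes is None
                                  else np.asarray(initial_lifetimes, float))

    # -- helpers

    def _default_lifetimes(self) -> np.ndarray:
        times = self.data.times
        tpos = times[times > 0]
        lo, hi = tpos.min(), times.max()
        guesses: list[float] = []
        try:
            ldm = LifetimeDistributionModel(
                self.data, points_per_decade=10).fit(regularization="auto")
            peaks = pick_lifetimes(
                ldm, (self.data.wavelengths[0], self.data.wavelengths[-1]))
            guesses = [p.lifetime for p in
                       sorted(peaks, key=lambda p: -p.amplitude)]
        except Exception:  # noqa: BLE001 - fall back to log spacing
            pass
        guesses = sorted(guesses[: self.n_components])
        extra = np.geomspace(3 * lo, hi / 3,
                             self.n_components) if self.n_components else []
        for g in extra:
            if len(guesses) >= self.n_components:
                break
            guesses.append(g)
        return np.sort(np.asarray(guesses[: self.n_components]))

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float, float]:
        tau = np.exp(theta[: self.n_components])
        if self.irf == "fit":
            t0, sigma = theta[-2], np.exp(theta[-1])
        elif self.irf == "fixed":
            t0, sigma = self.t0, self.irf_sigma
        else:
            t0, sigma = 0.0, 0.0
        return tau, sigma, t0

    def _project(self, theta: np.ndarray):
        tau, sigma, t0 = self._unpack(theta)
        phi = _basis(self.data.times, tau, sigma, t0)
        amps, *_ = np.linalg.lstsq(phi, self.data.values.T, rcond=None)
        resid = self.data.values.T - phi @ amps
        return resid, amps, tau, sigma, t0

    def fit(self, max_nfev: int = 200) -> GlobalLifetimeResults:
        times = self.data.times
        tpos = times[times > 0]
        if tpos.size == 0:
            raise ValueError("no positive time points to fit")
        tau0 = (self.initial_lifetimes if self.initial_lifetimes is not None
                else self._default_lifetimes())
        if tau0.size != self.n_components or np.any(tau0 <= 0):
            raise ValueError("initial_lifetimes must be n_components "
                             "positive values")
        dt_min = np.min(np.diff(times))
        theta0 = list(np.log(tau0))
        lo = [np.log(0.05 * dt_min)] * self.n_components
        hi = [np.log(30 * times[-1])] * self.n_components
        if self.irf == "fit":
            sigma0 = self.irf_sigma if self.irf_sigma else 1.5 * dt_min
            theta0 += [self.t0, np.log(sigma0)]
            lo += [times[0], np.log(0.02 * dt_min)]
            hi += [times[-1], np.log(0.5 * (times[-1] - times[0]))]

        sol = optimize.least_squares(
            lambda th: self._project(th)[0].ravel(), np.asarray(theta0),
            bounds=(np.asarray(lo), np.asarray(hi)), max_nfev=max_nfev,
            method="trf", x_scale="jac")
        resid, amps, tau, sigma, t0 = self._project(sol.x)

        order = np.argsort(tau)
        tau, amps = tau[order], amps[order]
        stderr = self._stderr(sol, order)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        success = bool(sol.status > 0)
        if not success:
            warnings.warn(f"global lifetime fit did not converge: "
                          f"{sol.message} (last lifetimes {tau})",
                          stacklevel=2)
        return GlobalLifetimeResults(
            lifetimes=tau, das=amps, wavelengths=self.data.wavelengths,
            times=times, irf_width=(sigma if self.irf != "none" else None),
            t0=(t0 if self.irf != "none" else None), residual_rms=rms,
            success=success, message=sol.message, nfev=sol.nfev,
            stderr_lifetimes=stderr, time_unit=self.data.time_unit)

    def _stderr(self, sol, order) -> np.ndarray | None:
        """Asymptotic lifetime errors from the projected Jacobian."""
        try:
            jac = sol.jac
            dof = jac.shape[0] - jac.shape[1]
            if dof <= 0:
                return None
            s2 = 2 * sol.cost / dof
            cov = s2 * np.linalg.pinv(jac.T @ jac)
            log_err = np.sqrt(np.diag(cov))[: self.n_components]
            tau = np.exp(sol.x[: self.n_components])
            return (tau * log_err)[order]
        except Exception:  # noqa: BLE001
            return None


def global_lifetime_fit(data: TAMatrix, n_components: int, irf: str = "none",
                        initial_lifetimes=None,
                        **kwargs) -> GlobalLifetimeResults:
    """Functional front end for :class:`GlobalLifetimeModel`."""
    return GlobalLifetimeModel(data, n_components, irf=irf,
                               initial_lifetimes=initial_lifetimes,
                               **kwargs).fit()


# ---------------------------------------------------------------------------
# lifetime distribution analysis (LDM)


@dataclass
class LDMResult:
    """Regularized lifetime-distribution map."""

    lifetime_grid: np.ndarray      # log-spaced, data time units
    amplitudes: np.ndarray         # (n_wavelengths, n_grid)
    wavelengths: np.ndarray
    regularization: float
    residual_rms: float
    time_unit: str = "s"

    def summary(self) -> str:
        return (f"Lifetime distribution map: {self.wavelengths.size} "
                f"wavelengths x {self.lifetime_grid.size} grid points "
                f"({self.lifetime_grid[0]:.4g}..{self.lifetime_grid[-1]:.4g} "
                f"{self.time_unit}), alpha={self.regularization:.4g}, "
                f"residual RMS {self.residual_rms:.4g}")


class LifetimeDistributionModel:
    """Penalized linear inversion onto a dense exponential basis.

    The per-wavelength amplitude vector x solves
    ``min ||Phi x - d||^2 + alpha^2 ||x||^2`` with
    ``Phi[t, g] = exp(-t / tau_g)`` over the positive part of the time
    axis; amplitudes keep their sign, so bleach and absorption features
    appear with opposite polarity, as in an LDM.
    """

    def __init__(self, data: TAMatrix, grid: np.ndarray | None = None,
                 points_per_decade: int = 30):
        self.data = data
        tpos = data.times[data.times > 0]
        if tpos.size < 4:
            raise ValueError("need at least 4 positive time points")
        self._tmask = data.times > 0
        if grid is None:
            lo, hi = 0.5 * tpos.min(), 2.0 * tpos.max()
            n = max(8, int(np.ceil(np.log10(hi / lo) * points_per_decade)))
            grid = np.geomspace(lo, hi, n)
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("lifetime grid must be strictly increasing")
        if grid[0] < 0.3 * tpos.min() - 1e-12 or grid[-1] > 3.0 * data.times[-1] + 1e-12:
            raise ValueError("grid must lie within [0.3 x first positive "
                             "time, 3 x last time]")
        self.grid = grid
        t = data.times[self._tmask]
        self.phi = np.exp(-t[:, None] / grid[None, :])
        self._svd = np.linalg.svd(self.phi, full_matrices=False)

    def _solve(self, alpha: float) -> tuple[np.ndarray, float]:
        u, s, vt = self._svd
        d = self.data.values[:, self._tmask].T          # (n_t, n_lambda)
        filt = s / (s ** 2 + alpha ** 2)
        x = (vt.T * filt) @ (u.T @ d)                   # (n_grid, n_lambda)
        resid = d - self.phi @ x
        return x.T, float(np.sqrt(np.mean(resid ** 2)))

    def fit(self, regularization: float | str = "auto",
            noise_sigma: float | None = None) -> LDMResult:
        """Invert the data; `regularization` is alpha or "auto".

        Auto mode applies the discrepancy principle at the declared noise
        level (`noise_sigma` argument or ``data.metadata['noise_sigma']``);
        without a declared level it falls back to generalized
        cross-validation over a log-spaced alpha scan.
        """
        if regularization == "auto":
            alpha = self._auto_alpha(noise_sigma)
        else:
            alpha = float(regularization)
            if alpha < 0:
                raise ValueError("regularization must be >= 0")
        amps, rms = self._solve(alpha)
        if not np.all(np.isfinite(amps)):
            raise np.linalg.LinAlgError(
                "singular design despite penalty; increase regularization")
        return LDMResult(lifetime_grid=self.grid, amplitudes=amps,
                         wavelengths=self.data.wavelengths,
                         regularization=alpha, residual_rms=rms,
                         time_unit=self.data.time_unit)

    def _auto_alpha(self, noise_sigma: float | None) -> float:
        sigma = (noise_sigma if noise_sigma is not None
                 else self.data.metadata.get("noise_sigma"))
        s = self._svd[1]
        alphas = np.geomspace(1e-4 * s[0], s[0], 25)
        if sigma is not None:
            # discrepancy principle: residual ~ declared noise level
            rms = np.array([self._solve(a)[1] for a in alphas])
            return float(alphas[np.argmin(np.abs(rms - sigma))])
        # GCV fallback
        u, s, _ = self._svd
        d = self.data.values[:, self._tmask].T
        utd = u.T @ d
        n = d.shape[0] * d.shape[1]
        best, best_alpha = np.inf, alphas[0]
        for a in alphas:
            filt = s ** 2 / (s ** 2 + a ** 2)
            rss = (np.sum(((1 - filt)[:, None] * utd) ** 2)
                   + np.sum(d ** 2) - np.sum(utd ** 2))
            edf = np.sum(filt)
            gcv = rss / (n * (1 - edf * d.shape[1] / n) ** 2)
            if gcv < best:
                best, best_alpha = gcv, a
        return float(best_alpha)


def lifetime_distribution(data: TAMatrix, grid: np.ndarray | None = None,
                          regularization: float | str = "auto",
                          points_per_decade: int = 30,
                          noise_sigma: float | None = None) -> LDMResult:
    """Functional front end for :class:`LifetimeDistributionModel`."""
    return LifetimeDistributionModel(
        data, grid=grid, points_per_decade=points_per_decade).fit(
            regularization=regularization, noise_sigma=noise_sigma)


@dataclass
class LifetimePeak:
    lifetime: float
    amplitude: float
    is_global_max: bool


def pick_lifetimes(ldm: LDMResult, band: tuple[float, float],
                   rel_threshold: float = 0.05) -> list[LifetimePeak]:
    """Read transition lifetimes from an LDM over a wavelength band.

    Averages |amplitude| over the band and returns the local maxima of
    the resulting distribution, sorted by lifetime; the point of maximum
    amplitude is flagged. Maxima below `rel_threshold` of the global
    maximum are suppressed.
    """
    lo, hi = band
    mask = (ldm.wavelengths >= lo) & (ldm.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] nm does not overlap the "
                         "wavelength axis")
    dist = np.abs(ldm.amplitudes[mask]).mean(axis=0)
    top = dist.max()
    if top <= 0:
        return []
    peaks: list[LifetimePeak] = []
    for i in range(dist.size):
        left = dist[i - 1] if i > 0 else -np.inf
        right = dist[i + 1] if i < dist.size - 1 else -np.inf
        if dist[i] > left and dist[i] >= right and dist[i] >= rel_threshold * top:
            peaks.append(LifetimePeak(float(ldm.lifetime_grid[i]),
                                      float(dist[i]), False))
    if peaks:
        gmax = max(range(len(peaks)), key=lambda j: peaks[j].amplitude)
        peaks[gmax].is_global_max = True
    return sorted(peaks, key=lambda p: p.lifetime)


# ---------------------------------------------------------------------------
# PSS thermal recovery


@dataclass
class RecoveryFit:
    """Monoexponential recovery A(t) = offset - amplitude exp(-t/tau)."""

    tau: float                     # s
    amplitude: float
    offset: float
    sigma_tau: float
    residual_rms: float
    n_points: int

    def summary(self) -> str:
        return ("PSS thermal recovery fit\n"
                f"tau       : {self.tau:.6g} +/- {self.sigma_tau:.3g} s\n"
                f"amplitude : {self.amplitude:.6g}\n"
                f"offset    : {self.offset:.6g}\n"
                f"residual RMS {self.residual_rms:.4g} over "
                f"{self.n_points} points")


class RecoveryModel:
    """Fit slow thermal recovery of the dark-state absorbance.

    Time stamps are corrected by subtracting `illumination_offset`
    (default 100 s, the LED-on period) before the nonlinear fit.
    """

    def __init__(self, times_s: np.ndarray, absorbance: np.ndarray,
                 illumination_offset: float = 100.0):
        times_s = np.asarray(times_s, dtype=float)
        absorbance = np.asarray(absorbance, dtype=float)
        if times_s.size < 5:
            raise ValueError("need at least 5 points")
        if np.any(np.diff(times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if times_s.size != absorbance.size:
            raise ValueError("times and absorbance differ in length")
        self.times = times_s - illumination_offset
        self.absorbance = absorbance

    def fit(self) -> RecoveryFit:
        a = self.absorbance
        span = a.max() - a.min()
        if span == 0:
            raise ValueError("flat series: recovery amplitude is zero and "
                             "tau is unidentifiable")
        model = lmfit.Model(
            lambda t, tau, amplitude, offset:
            offset - amplitude * np.exp(-t / tau))
        params = model.make_params(
            tau=dict(value=(self.times[-1] - self.times[0]) / 3.0,
                     min=1e-6 * self.times[-1]),
            amplitude=dict(value=a[-1] - a[0]),
            offset=dict(value=float(a[-1])))
        out = model.fit(a, params, t=self.times)
        if not out.success:
            raise RuntimeError(f"recovery fit failed to converge: "
                               f"{out.message}; last tau="
                               f"{out.params['tau'].value:.4g}")
        tau = out.params["tau"]
        sigma_tau = tau.stderr if tau.stderr is not None else np.nan
        return RecoveryFit(
            tau=float(tau.value), amplitude=float(out.params["amplitude"]),
            offset=float(out.params["offset"]),
            sigma_tau=float(sigma_tau),
            residual_rms=float(np.sqrt(np.mean(out.residual ** 2))),
            n_points=a.size)


def fit_recovery(series, illumination_offset: float = 100.0) -> RecoveryFit:
    """Fit a (time_s, absorbance) table; see :class:`RecoveryModel`.

    `series` may be a pandas DataFrame with columns ``time_s`` and
    ``absorbance`` or a pair of arrays.
    """
    if hasattr(series, "columns"):
        times, values = series["time_s"].to_numpy(), series["absorbance"].to_numpy()
    else:
        times, values = series
    return RecoveryModel(times, values,
                         illumination_offset=illumination_offset).fit()
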