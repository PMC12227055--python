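"""Synthetic data generation from packaged scenario configurations.

Every input the analysis pipeline consumes can be generated here at desk
scale. Scenario files (YAML) are the single home of the numeric study
conditions — recovery lifetimes, excited-state lifetimes, band
positions, oscillation frequencies, subpopulation fractions — so no
physical constant is hard-coded in the generators. All noise is
additive Gaussian and seeded: identical (config, seed) gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
import yaml

from . import kinetics, photosteady
from .datatypes import CurrentTrace, TAMatrix, TitrationSpectra
from .motifs import SequenceRecord, br_reference

__all__ = [
    "ScenarioConfig", "ScenarioError", "available_scenarios",
    "load_scenario", "make_recovery_series", "make_flash_dataset",
    "make_fsta_dataset", "make_titration_dataset", "make_current_traces",
    "make_sequence_set", "photoswitch_from_scenario",
]

SCENARIO_KINDS = ("flash", "fsta", "recovery", "titration", "ephys",
                  "sequences", "pss")

#: speed of light in cm/s, for wavenumber -> frequency conversion
C_CM_PER_S = 2.99792458e10


class ScenarioError(ValueError):
    """Invalid scenario name or parameter."""


@dataclass
class ScenarioConfig:
    """Named, validated parameter set for one synthetic experiment."""

    name: str
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ScenarioError(f"unknown scenario kind {self.kind!r}; "
                                f"expected one of {SCENARIO_KINDS}")
        self.seed = int(self.seed)
        self._validate()

    def _validate(self) -> None:
        p = self.parameters

        def positive(key):
            if key in p and not np.all(np.asarray(p[key], dtype=float) > 0):
                raise ScenarioError(
                    f"scenario {self.name!r}: parameter {key!r} must be "
                    "positive")

        for key in ("tau_s", "lifetimes_ps", "lifetimes_s", "irf_sigma_ps",
                    "sample_interval_s", "duration_s", "rise_ms", "decay_ms",
                    "pulse_period_s", "sample_rate_hz", "k_thermal_per_s",
                    "step_duration_s"):
            positive(key)
        for key in ("noise_sigma", "noise_pA"):
            if key in p and float(p[key]) < 0:
                raise ScenarioError(f"scenario {self.name!r}: {key!r} must "
                                    "be >= 0")
        for bands in _iter_band_lists(p):
            for b in bands:
                if float(b["sigma_nm"]) <= 0:
                    raise ScenarioError(f"scenario {self.name!r}: band "
                                        "width must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ScenarioConfig":
        return cls(name=payload["name"], kind=payload["kind"],
                   parameters=payload.get("parameters", {}),
                   seed=payload.get("seed", 0))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, seed: int | None = None, **overrides) -> "ScenarioConfig":
        params = dict(self.parameters)
        params.update(overrides)
        return ScenarioConfig(self.name, self.kind, params,
                              self.seed if seed is None else seed)


def _iter_band_lists(params: dict):
    for comp in params.get("components", []):
        yield comp["bands"]
    for bands in params.get("species_spectra", {}).values():
        yield bands
    for sp in params.get("species", []):
        yield sp["bands"]
    if "reference_band" in params:
        yield [params["reference_band"]]
    for key in ("ground_bands", "m_bands"):
        if key in params:
            yield params[key]


def available_scenarios() -> list[str]:
    files = resources.files("cryor.scenarios")
    return sorted(p.name[:-5] for p in files.iterdir()
                  if p.name.endswith(".yaml"))


def load_scenario(name: str) -> ScenarioConfig:
    """Load a packaged scenario by name, or a user YAML file by path."""
    candidate = Path(name)
    if candidate.suffix in (".yaml", ".yml") and candidate.exists():
        payload = yaml.safe_load(candidate.read_text())
    else:
        res = resources.files("cryor.scenarios") / f"{name}.yaml"
        try:
            payload = yaml.safe_load(res.read_text())
        except FileNotFoundError:
            raise ScenarioError(
                f"unknown scenario {name!r}; available: "
                f"{', '.join(available_scenarios())}") from None
    return ScenarioConfig.from_dict(payload)


def _rng(config: ScenarioConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def _bands_array(wavelengths: np.ndarray, bands: list[dict]) -> np.ndarray:
    return photosteady.gaussian_bands(
        wavelengths, photosteady._as_bands(bands))


# ---------------------------------------------------------------------------
# PSS thermal recovery


def make_recovery_series(config: ScenarioConfig,
                         seed: int | None = None) -> pd.DataFrame:
    """Absorbance recovery after PSS formation, sampled every 120 s.

    Returns columns (time_s, absorbance). Time stamps count from the
    start of the illumination period, as recorded by the spectrometer:
    the first spectrum is taken one sampling interval after illumination
    begins, and the underlying recovery clock starts when the LED turns
    off (`illumination_s` after t = 0).
    """
    if config.kind != "recovery":
        raise ScenarioError(f"scenario {config.name!r} is not a recovery "
                            "scenario")
    p = config.parameters
    tau = float(p["tau_s"])
    if tau <= 0:
        raise ScenarioError("tau_s must be positive")
    offset = float(p.get("illumination_s", 100.0))
    interval = float(p.get("sample_interval_s", 120.0))
    duration = float(p.get("duration_s", 18000.0))
    times = np.arange(interval, duration + interval / 2, interval)
    clock = times - offset
    a = (float(p.get("a_inf", 1.0))
         - float(p.get("delta_a", 0.5)) * np.exp(-clock / tau))
    rng = _rng(config, seed)
    a = a + rng.normal(0.0, float(p.get("noise_sigma", 0.0)), a.shape)
    return pd.DataFrame({"time_s": times, "absorbance": a})


# ---------------------------------------------------------------------------
# flash photolysis (sequential photocycle chain)


def _scheme_from_config(p: dict) -> kinetics.KineticScheme:
    return kinetics.KineticScheme(
        states=list(p["states"]),
        lifetimes=np.asarray(p["lifetimes_s"], dtype=float),
        species_spectra={s: p["species_spectra"][s] for s in p["states"]})


def make_flash_dataset(config: ScenarioConfig,
                       seed: int | None = None) -> TAMatrix:
    """Flash-photolysis difference-absorbance matrix from a chain model.

    dA(lambda, t) = sum_s spectrum_s(lambda) population_s(t) + noise,
    with populations from the analytic first-order chain solution.
    """
    if config.kind != "flash":
        raise ScenarioError(f"scenario {config.name!r} is not a flash "
                            "scenario")
    p = config.parameters
    scheme = _scheme_from_config(p)
    times = np.geomspace(float(p["time_start_s"]), float(p["time_stop_s"]),
                         int(p["time_points"]))
    lam = np.arange(float(p["wavelength_start_nm"]),
                    float(p["wavelength_stop_nm"]) + 1e-9,
                    float(p["wavelength_step_nm"]))
    pops = kinetics.simulate_chain(scheme, times)
    values = np.zeros((lam.size, times.size))
    for i, state in enumerate(scheme.states):
        values += np.outer(_bands_array(lam, scheme.species_spectra[state]),
                           pops[i])
    rng = _rng(config, seed)
    values = values + rng.normal(0.0, float(p.get("noise_sigma", 0.0)),
                                 values.shape)
    meta = {"scenario": config.name, "pH": p.get("pH"),
            "excitation_nm": p.get("excitation_nm"),
            "noise_sigma": float(p.get("noise_sigma", 0.0)),
            "seed": config.seed if seed is None else seed}
    return TAMatrix(lam, times, values, time_unit="s", signal_unit="mOD",
                    metadata=meta)


# ---------------------------------------------------------------------------
# femtosecond transient absorption


def _fsta_time_axis(p: dict) -> np.ndarray:
    lin = np.arange(float(p["time_linear_start_ps"]),
                    float(p["time_linear_stop_ps"]) + 1e-12,
                    float(p["time_linear_step_ps"]))
    if "time_log_stop_ps" in p:
        start = lin[-1] * 1.15
        log = np.geomspace(start, float(p["time_log_stop_ps"]),
                           int(p["time_log_points"]))
        return np.concatenate([lin, log])
    return lin


def make_fsta_dataset(config: ScenarioConfig,
                      seed: int | None = None) -> TAMatrix:
    """Femtosecond TA matrix: IRF-convolved multiexponential components.

    Component band sets encode the canonical ESA (positive), GSB and SE
    (negative) structure. Optional coherent-oscillation terms add a
    damped cosine A(lambda) cos(2 pi c nu t + phi) exp(-t / tau_damp)
    for t >= 0.
    """
    if config.kind != "fsta":
        raise ScenarioError(f"scenario {config.name!r} is not an fsta "
                            "scenario")
    p = config.parameters
    sigma = float(p["irf_sigma_ps"])
    if sigma <= 0:
        raise ScenarioError("irf_sigma_ps must be positive")
    t0 = float(p.get("t0_ps", 0.0))
    taus = np.asarray(p["lifetimes_ps"], dtype=float)
    comps = p["components"]
    if taus.size != len(comps):
        raise ScenarioError("need one band set per lifetime")
    times = _fsta_time_axis(p)
    lam = np.arange(float(p["wavelength_start_nm"]),
                    float(p["wavelength_stop_nm"]) + 1e-9,
                    float(p["wavelength_step_nm"]))
    values = np.zeros((lam.size, times.size))
    for tau, comp in zip(taus, comps):
        das = _bands_array(lam, comp["bands"])
        values += np.outer(das, kinetics.exp_conv_irf(times, tau, sigma, t0))
    for osc in p.get("oscillations", []):
        nu = float(osc["wavenumber_cm"])
        if nu <= 0:
            raise ScenarioError("oscillation wavenumber must be positive")
        amp = _bands_array(lam, [{"center_nm": osc["band_center_nm"],
                                  "sigma_nm": osc["band_sigma_nm"],
                                  "amplitude": osc["amplitude"]}])
        t_ps = np.clip(times - t0, 0.0, None)
        carrier = (np.cos(2 * np.pi * C_CM_PER_S * nu * t_ps * 1e-12
                          + float(osc.get("phase_rad", 0.0)))
                   * np.exp(-t_ps / float(osc["tau_damp_ps"])))
        carrier[times < t0] = 0.0
        values += np.outer(amp, carrier)
    rng = _rng(config, seed)
    values = values + rng.normal(0.0, float(p.get("noise_sigma", 0.0)),
                                 values.shape)
    meta = {"scenario": config.name, "pH": p.get("pH"),
            "excitation_nm": p.get("excitation_nm"),
            "noise_sigma": float(p.get("noise_sigma", 0.0)),
            "seed": config.seed if seed is None else seed}
    return TAMatrix(lam, times, values, time_unit="ps", signal_unit="mOD",
                    metadata=meta)


# ---------------------------------------------------------------------------
# pH titration


def make_titration_dataset(config: ScenarioConfig,
                           seed: int | None = None) -> TitrationSpectra:
    """Steady-state absorbance spectra over a pH series.

    A(lambda, pH) = sum_s f_s(pH) band_s(lambda) + reference band +
    noise, with fractions from the sequential Henderson-Hasselbalch
    scheme. The pH-independent 280-nm band supports normalization tests.
    """
    if config.kind != "titration":
        raise ScenarioError(f"scenario {config.name!r} is not a titration "
                            "scenario")
    p = config.parameters
    ph = np.arange(float(p["pH_start"]), float(p["pH_stop"]) + 1e-9,
                   float(p.get("pH_step", 0.5)))
    lam = np.arange(float(p["wavelength_start_nm"]),
                    float(p["wavelength_stop_nm"]) + 1e-9,
                    float(p["wavelength_step_nm"]))
    species = [(sp["name"], photosteady._as_bands(sp["bands"]))
               for sp in p["species"]]
    pkas = np.asarray(p.get("pkas", []), dtype=float)
    model = photosteady.TitrationModel(
        species, pkas, np.asarray(p["hill"], dtype=float)
        if "hill" in p else None) if len(species) > 1 else None
    if pkas.size and (pkas.min() < ph.min() - 3 or pkas.max() > ph.max() + 3):
        warnings.warn("a pKa lies more than 3 units outside the pH range "
                      "and will be poorly constrained", stacklevel=2)
    ref = (_bands_array(lam, [p["reference_band"]])
           if "reference_band" in p else 0.0)
    values = np.zeros((lam.size, ph.size))
    for j, ph_j in enumerate(ph):
        if model is None:
            spec = photosteady.gaussian_bands(lam, species[0][1])
        else:
            spec = model.spectrum(lam, ph_j)
        values[:, j] = spec + ref
    rng = _rng(config, seed)
    values = values + rng.normal(0.0, float(p.get("noise_sigma", 0.0)),
                                 values.shape)
    meta = {"scenario": config.name,
            "noise_sigma": float(p.get("noise_sigma", 0.0)),
            "seed": config.seed if seed is None else seed}
    return TitrationSpectra(lam, ph, values, metadata=meta)


# ---------------------------------------------------------------------------
# patch-clamp photocurrents


def make_current_traces(config: ScenarioConfig, seed: int | None = None
                        ) -> dict[tuple[float, float], CurrentTrace]:
    """Transient photocurrent traces keyed by (excitation nm, voltage mV).

    Each laser pulse injects a biexponential (rise/decay) current whose
    time integral equals the configured subpopulation fraction times the
    per-protein unit charge; sequential pulses deplete the activatable
    pool geometrically. 500-nm activation probes the nonprotonated
    counterion subpopulation (positive transients), 620-nm the
    protonated one (negative transients).
    """
    if config.kind != "ephys":
        raise ScenarioError(f"scenario {config.name!r} is not an ephys "
                            "scenario")
    p = config.parameters
    fractions = {float(k): float(v) for k, v in p["fraction_nonprot"].items()}
    for v, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ScenarioError(f"fraction at {v} mV outside [0, 1]")
    tau_r = float(p["rise_ms"]) * 1e-3
    tau_d = float(p["decay_ms"]) * 1e-3
    period = float(p["pulse_period_s"])
    n_pulses = int(p["n_pulses"])
    depletion = float(p.get("depletion_per_pulse", 0.5))
    pre = float(p.get("pre_pulse_s", 0.1))
    fs = float(p.get("sample_rate_hz", 5000.0))
    baseline = float(p.get("baseline_pA", 0.0))
    rng = _rng(config, seed)
    total = pre + n_pulses * period
    times = np.arange(0.0, total, 1.0 / fs)
    pulse_times = pre + period * np.arange(n_pulses)
    traces: dict[tuple[float, float], CurrentTrace] = {}
    for exc_key, unit_q in p["unit_charge_pC"].items():
        exc = float(exc_key)
        for volt in map(float, p["voltages_mV"]):
            f_non = fractions[volt]
            frac = f_non if exc < 560 else 1.0 - f_non
            current = np.full_like(times, baseline)
            for k, t_k in enumerate(pulse_times):
                q_k = float(unit_q) * frac * depletion ** k
                dt = times - t_k
                shape = np.zeros_like(times)
                pos = dt >= 0
                # unit-integral biexponential pulse (pC x 1/s = pA)
                shape[pos] = (np.exp(-dt[pos] / tau_d)
                              - np.exp(-dt[pos] / tau_r)) / (tau_d - tau_r)
                current += q_k * shape
            current += rng.normal(0.0, float(p.get("noise_pA", 0.0)),
                                  times.shape)
            traces[(exc, volt)] = CurrentTrace(
                times=times, current=current, voltage=volt, excitation=exc,
                pulse_times=pulse_times,
                metadata={"scenario": config.name,
                          "unit_charge_pC": float(unit_q),
                          "fraction": frac, "depletion": depletion,
                          "seed": config.seed if seed is None else seed})
    return traces


# ---------------------------------------------------------------------------
# sequence fixtures for the motif module


_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_sequence_set(config: ScenarioConfig, seed: int | None = None
                      ) -> list[SequenceRecord]:
    """Motif-implanted mutant sequences on the packaged BR scaffold.

    Each record carries its implanted seven-letter motif in the
    description (``implant=XXXXXXX``) as ground truth. Substitutions and
    short (1-3 aa) indels are applied outside a protection pad around
    the anchor positions so the ground-truth motif stays defined.
    """
    if config.kind != "sequences":
        raise ScenarioError(f"scenario {config.name!r} is not a sequences "
                            "scenario")
    p = config.parameters
    motifs_list = list(p["motifs"])
    for m in motifs_list:
        if len(m) != 7:
            raise ScenarioError(f"implanted motif {m!r} must have 7 letters")
    n_records = int(p.get("n_records", len(motifs_list)))
    mut_rate = float(p.get("mutation_rate", 0.0))
    indel_rate = float(p.get("indel_rate", 0.0))
    pad = int(p.get("anchor_pad", 5))
    scaffold = br_reference().residues
    anchors0 = [a - 1 for a in (46, 82, 85, 89, 96, 212, 216)]
    protected = set()
    for a in anchors0:
        protected.update(range(a - pad, a + pad + 1))
    rng = _rng(config, seed)
    records = []
    for i in range(n_records):
        motif = motifs_list[i % len(motifs_list)]
        res = list(scaffold)
        for a, ch in zip(anchors0, motif):
            res[a] = ch
        out: list[str] = []
        j = 0
        while j < len(res):
            if j not in protected and rng.random() < indel_rate:
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    out.extend(rng.choice(list(_AA), size=size))
                    out.append(res[j])
                    j += 1
                else:  # deletion, never across a protected position
                    stop = j
                    while (stop < len(res) and stop - j < size
                           and stop not in protected):
                        stop += 1
                    j = stop
                continue
            ch = res[j]
            if j not in set(anchors0) and rng.random() < mut_rate:
                choices = [c for c in _AA if c != ch]
                ch = str(rng.choice(choices))
            out.append(ch)
            j += 1
        records.append(SequenceRecord(
            id=f"syn{i:03d}", description=f"syn{i:03d} implant={motif}",
            residues="".join(out)))
    return records


# ---------------------------------------------------------------------------
# photoswitch scenario


def photoswitch_from_scenario(config: ScenarioConfig) -> tuple[
        photosteady.PhotoswitchModel, dict[str, photosteady.LEDSource],
        float]:
    """Build the photoswitch model, named LEDs and step duration."""
    if config.kind != "pss":
        raise ScenarioError(f"scenario {config.name!r} is not a pss scenario")
    p = config.parameters
    model = photosteady.PhotoswitchModel(
        ground_spectrum=photosteady._as_bands(p["ground_bands"]),
        m_spectrum=photosteady._as_bands(p["m_bands"]),
        phi_forward=float(p.get("phi_forward", 0.3)),
        phi_back=float(p.get("phi_back", 0.3)),
        k_thermal=float(p["k_thermal_per_s"]),
        extinction_scale=float(p.get("extinction_scale", 45000.0)))
    leds = {name: photosteady.LEDSource(
        center=float(cfg["center_nm"]), fwhm=float(cfg["fwhm_nm"]),
        power=float(cfg["power_mW"]),
        beam_area=float(cfg.get("beam_area_cm2", 1.0)))
        for name, cfg in p.get("leds", {}).items()}
    return model, leds, float(p.get("step_duration_s", 100.0))
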