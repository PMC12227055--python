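"""Generators: determinism, closed-form agreement, scenario plumbing."""

import numpy as np
import pytest
import yaml
from scipy.integrate import solve_ivp

from cryor import kinetics, synthgen
from cryor.synthgen import ScenarioConfig, ScenarioError, load_scenario


class TestScenarioConfig:
    def test_unknown_name_lists_available(self):
        with pytest.raises(ScenarioError, match="cryor1_rec_20C"):
            load_scenario("no_such_scenario")

    def test_packaged_scenarios_load_and_validate(self):
        for name in synthgen.available_scenarios():
            cfg = load_scenario(name)
            assert cfg.name == name

    def test_recovery_scenarios_encode_published_lifetimes(self):
        assert load_scenario("cryor1_rec_20C").parameters["tau_s"] == 942.0
        assert load_scenario("cryor1_rec_5C").parameters["tau_s"] == 3318.0

    def test_titration_scenario_has_three_species_bands(self):
        cfg = load_scenario("cryor1_titration")
        centers = [sp["bands"][0]["center_nm"]
                   for sp in cfg.parameters["species"]]
        assert centers == [620.0, 540.0, 400.0]

    def test_invalid_lifetime_rejected(self):
        with pytest.raises(ScenarioError, match="tau_s"):
            ScenarioConfig("bad", "recovery", {"tau_s": -1.0})

    def test_negative_noise_rejected(self):
        with pytest.raises(ScenarioError, match="noise_sigma"):
            ScenarioConfig("bad", "recovery",
                           {"tau_s": 1.0, "noise_sigma": -0.1})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ScenarioError, match="kind"):
            ScenarioConfig("bad", "nonsense", {})

    def test_yaml_round_trip(self, tmp_path, rec20_config):
        path = tmp_path / "scenario.yaml"
        rec20_config.save(path)
        again = ScenarioConfig.from_dict(yaml.safe_load(path.read_text()))
        assert again == rec20_config
        assert load_scenario(str(path)) == rec20_config


class TestRecoverySeries:
    def test_closed_form_noiseless(self):
        cfg = ScenarioConfig("t", "recovery", {
            "tau_s": 100.0, "a_inf": 1.0, "delta_a": 1.0,
            "illumination_s": 0.0, "sample_interval_s": 10.0,
            "duration_s": 1000.0, "noise_sigma": 0.0})
        table = synthgen.make_recovery_series(cfg)
        expect = 1.0 - np.exp(-table["time_s"].to_numpy() / 100.0)
        np.testing.assert_allclose(table["absorbance"], expect, rtol=1e-12)
        # asymptote at late times
        assert table["absorbance"].iloc[-1] == pytest.approx(1.0, abs=1e-4)

    def test_seed_determinism(self, rec20_config):
        a = synthgen.make_recovery_series(rec20_config, seed=7)
        b = synthgen.make_recovery_series(rec20_config, seed=7)
        assert (a == b).all().all()
        c = synthgen.make_recovery_series(rec20_config, seed=8)
        assert not (a["absorbance"] == c["absorbance"]).all()

    def test_default_sampling_matches_protocol(self, rec20_config):
        table = synthgen.make_recovery_series(rec20_config, seed=1)
        dt = np.diff(table["time_s"])
        assert np.all(dt == 120.0)
        assert table["time_s"].iloc[-1] == pytest.approx(18000.0)


class TestFlashDataset:
    def test_single_state_is_plain_exponential(self):
        cfg = ScenarioConfig("t", "flash", {
            "states": ["M"], "lifetimes_s": [2.0],
            "time_start_s": 1e-3, "time_stop_s": 20.0, "time_points": 40,
            "wavelength_start_nm": 380.0, "wavelength_stop_nm": 420.0,
            "wavelength_step_nm": 10.0,
            "species_spectra": {"M": [{"center_nm": 400.0, "sigma_nm": 20.0,
                                       "amplitude": 5.0}]},
            "noise_sigma": 0.0})
        ta = synthgen.make_flash_dataset(cfg)
        decay = np.exp(-ta.times / 2.0)
        for row in ta.values:
            np.testing.assert_allclose(row, row[0] * decay / decay[0],
                                       rtol=1e-12)

    def test_degenerate_chain_rejected(self):
        cfg = dict(states=["A", "B"], lifetimes_s=[1.0, 1.0 + 1e-12],
                   time_start_s=1e-3, time_stop_s=10.0, time_points=10,
                   wavelength_start_nm=400.0, wavelength_stop_nm=410.0,
                   wavelength_step_nm=10.0,
                   species_spectra={"A": [], "B": []}, noise_sigma=0.0)
        with pytest.raises(ValueError, match="perturb"):
            synthgen.make_flash_dataset(ScenarioConfig("t", "flash", cfg))

    def test_m_band_persists_to_minutes(self):
        ta = synthgen.make_flash_dataset(
            load_scenario("cryor1_flash_ph10p5"), seed=1)
        trace = ta.band_mean(395.0, 405.0)
        i = np.argmin(np.abs(ta.times - 120.0))
        assert trace[i] > 1.0  # mOD, two minutes after the flash

    def test_populations_match_ode_oracle_on_random_chains(self, rng):
        """Analytic chain solution vs Runge-Kutta on 5 random chains."""
        for _ in range(5):
            n = int(rng.integers(2, 6))
            taus = np.sort(rng.uniform(0.05, 80.0, n))
            scheme = kinetics.KineticScheme([f"S{i}" for i in range(n)], taus)
            t = np.linspace(0.0, 150.0, 60)
            pops = kinetics.simulate_chain(scheme, t)
            k = 1.0 / taus

            def rhs(_, y):
                dy = -k * y
                dy[1:] += k[:-1] * y[:-1]
                return dy

            sol = solve_ivp(rhs, (0, 150.0), np.eye(n)[0], t_eval=t,
                            rtol=1e-11, atol=1e-13)
            assert np.max(np.abs(pops - sol.y)) < 1e-8


class TestFstaDataset:
    def test_irf_to_zero_limit_is_biexponential(self):
        base = dict(lifetimes_ps=[0.5, 5.0], irf_sigma_ps=1e-7, t0_ps=0.0,
                    wavelength_start_nm=450.0, wavelength_stop_nm=500.0,
                    wavelength_step_nm=25.0,
                    time_linear_start_ps=0.1, time_linear_stop_ps=20.0,
                    time_linear_step_ps=0.1,
                    components=[
                        {"bands": [{"center_nm": 470.0, "sigma_nm": 30.0,
                                    "amplitude": 3.0}]},
                        {"bands": [{"center_nm": 480.0, "sigma_nm": 30.0,
                                    "amplitude": 2.0}]}],
                    noise_sigma=0.0)
        ta = synthgen.make_fsta_dataset(ScenarioConfig("t", "fsta", base))
        lam = ta.wavelengths

        def band(c, s, a):
            return a * np.exp(-0.5 * ((lam - c) / s) ** 2)

        expect = (np.outer(band(470, 30, 3), np.exp(-ta.times / 0.5))
                  + np.outer(band(480, 30, 2), np.exp(-ta.times / 5.0)))
        np.testing.assert_allclose(ta.values, expect, rtol=1e-9, atol=1e-12)

    def test_gsb_region_is_a_bleach(self, fsta105_config):
        ta = synthgen.make_fsta_dataset(fsta105_config, seed=2)
        i = np.argmin(np.abs(ta.times - 1.0))
        band = ta.band_mean(560.0, 620.0)
        assert band[i] < 0

    def test_oscillation_period_in_residual(self, osc_config):
        """Residual after subtracting the exponential part oscillates with
        period 1/(c nu) for the configured 128 cm^-1 mode."""
        ta = synthgen.make_fsta_dataset(
            osc_config.replace(noise_sigma=0.0, oscillations=[
                {"wavenumber_cm": 128.0, "tau_damp_ps": 1e6,
                 "phase_rad": 0.0, "band_center_nm": 530.0,
                 "band_sigma_nm": 25.0, "amplitude": 1.0}]))
        pure = synthgen.make_fsta_dataset(
            osc_config.replace(noise_sigma=0.0, oscillations=[]))
        resid = ta.band_mean(525.0, 535.0) - pure.band_mean(525.0, 535.0)
        mask = ta.times >= 0.1
        t, x = ta.times[mask], resid[mask]
        # zero crossings spaced by half a period; T = 1/(c*128) = 260.5 fs
        sign_changes = t[:-1][np.diff(np.sign(x)) != 0]
        period = 2.0 * np.mean(np.diff(sign_changes))
        assert period == pytest.approx(0.2605, rel=0.02)

    def test_seed_determinism(self, fsta105_config):
        a = synthgen.make_fsta_dataset(fsta105_config, seed=3)
        b = synthgen.make_fsta_dataset(fsta105_config, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_irf_rejected(self, fsta105_config):
        with pytest.raises(ScenarioError):
            synthgen.make_fsta_dataset(fsta105_config.replace(
                irf_sigma_ps=0.0))


class TestTitrationDataset:
    def test_single_species_is_ph_independent(self):
        cfg = ScenarioConfig("t", "titration", {
            "pH_start": 3.0, "pH_stop": 9.0, "pH_step": 1.0,
            "wavelength_start_nm": 300.0, "wavelength_stop_nm": 700.0,
            "wavelength_step_nm": 5.0,
            "species": [{"name": "only", "bands": [
                {"center_nm": 550.0, "sigma_nm": 30.0, "amplitude": 1.0}]}],
            "noise_sigma": 0.0})
        spectra = synthgen.make_titration_dataset(cfg)
        for j in range(1, spectra.ph_values.size):
            np.testing.assert_allclose(spectra.values[:, j],
                                       spectra.values[:, 0], rtol=1e-12)

    def test_extreme_ph_lambda_max_in_expected_band(self, titration_config):
        spectra = synthgen.make_titration_dataset(titration_config, seed=1)
        vis = (spectra.wavelengths > 330)
        low = spectra.values[vis, 0]
        high = spectra.values[vis, -1]
        lam = spectra.wavelengths[vis]
        assert 600 < lam[np.argmax(low)] < 640       # red species at pH 2.5
        assert 380 < lam[np.argmax(high)] < 560      # blue species at pH 11

    def test_out_of_range_pka_warns(self, titration_config):
        cfg = titration_config.replace(pkas=[5.8, 15.0])
        with pytest.warns(UserWarning, match="pKa"):
            synthgen.make_titration_dataset(cfg, seed=1)


class TestCurrentTraces:
    def test_zero_unit_charge_gives_flat_trace(self, ephys_config):
        cfg = ephys_config.replace(
            unit_charge_pC={"500": 0.0, "620": 0.0}, noise_pA=0.0)
        traces = synthgen.make_current_traces(cfg)
        for trace in traces.values():
            np.testing.assert_allclose(trace.current,
                                       trace.current[0], atol=1e-12)

    def test_noiseless_first_pulse_integral_matches_configured_charge(
            self, ephys_config):
        """Trapezoid integral of the generated pulse equals the analytic
        integral of the biexponential shape (= Q by construction)."""
        cfg = ephys_config.replace(noise_pA=0.0, n_pulses=1,
                                   pulse_period_s=1.5)
        traces = synthgen.make_current_traces(cfg)
        tr = traces[(500.0, 0.0)]
        q_expect = 20.0 * 2.0 / 3.0   # unit charge x fraction at 0 mV
        base = tr.current - (-5.0)
        q = np.trapezoid(base, tr.times)
        assert q == pytest.approx(q_expect, rel=5e-3)

    def test_voltage_dependence_sign_pattern(self, ephys_traces):
        """500-nm charge magnitude grows with voltage, 620-nm shrinks."""
        from cryor import ephys as ep
        q = {key: ep.integrate_charge(tr).per_pulse_pC[0]
             for key, tr in ephys_traces.items()}
        assert abs(q[(500.0, 40.0)]) > abs(q[(500.0, -40.0)])
        assert abs(q[(620.0, 40.0)]) < abs(q[(620.0, -40.0)])

    def test_invalid_fraction_rejected(self, ephys_config):
        cfg = dict(ephys_config.parameters)
        cfg["fraction_nonprot"] = {"-40.0": 1.2, "0.0": 0.5, "40.0": 0.5}
        with pytest.raises(ScenarioError, match="fraction"):
            synthgen.make_current_traces(
                ScenarioConfig("bad", "ephys", cfg))


class TestSequenceSet:
    def test_implant_round_trip_without_noise(self):
        from cryor import motifs
        cfg = ScenarioConfig("t", "sequences", {
            "motifs": ["RREAEDK"], "n_records": 1,
            "mutation_rate": 0.0, "indel_rate": 0.0})
        rec = synthgen.make_sequence_set(cfg)[0]
        assert motifs.extract_motif(rec).motif == "RREAEDK"

    def test_unmodified_scaffold_keeps_reference_motif(self):
        from cryor import motifs
        cfg = ScenarioConfig("t", "sequences", {
            "motifs": ["TRDTDDK"], "n_records": 1,
            "mutation_rate": 0.0, "indel_rate": 0.0})
        rec = synthgen.make_sequence_set(cfg)[0]
        assert rec.residues == motifs.br_reference().residues
        m = motifs.extract_motif(rec)
        assert m.motif == "TRDTDDK" and m.alignment_identity == 1.0

    def test_wrong_motif_length_rejected(self):
        cfg = ScenarioConfig("t", "sequences", {"motifs": ["RRK"]})
        with pytest.raises(ScenarioError, match="7"):
            synthgen.make_sequence_set(cfg)

    def test_recovery_regression_bound_at_high_indel_rate(self):
        """>= 95% of implanted motifs recovered at 10% indel rate
        (frozen regression bound, 50 seeded records)."""
        from cryor import motifs
        cfg = load_scenario("cryor1_sequences").replace(
            seed=123, n_records=50, indel_rate=0.10, mutation_rate=0.05)
        seqs = synthgen.make_sequence_set(cfg)
        ok = sum(motifs.extract_motif(s).motif
                 == s.description.split("implant=")[1] for s in seqs)
        assert ok >= 48  # 95% of 50, rounded up
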