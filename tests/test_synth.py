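import numpy as np
import pytest

from flashkin.fitting import fit_single_exponential
from flashkin.synth import (GeneratorConfig, generate_nod_trace,
                            generate_temperature_series,
                            generate_two_concentration_set, preset_model,
                            preset_rates, simulate_noisy_trace)
from flashkin.thermo import EyringEntry, eyring_fit, eyring_rate


class TestPresets:
    def test_wt_printed_constants(self):
        r = preset_rates("wt_solution")
        assert r["k_-2"] == 3.04e7
        assert r["k_-1"] == 1.5e7
        assert r["k_2"] == 4.2e7
        assert r["k_c"] == 1.5e7
        assert r["k_b"] == 149.0
        assert r["k_-b"] == 1.8
        for sym in ("k_-2", "k_b", "k_-b", "k_-1", "k_2", "k_c"):
            assert r.provenance[sym] == "printed"

    def test_co_gel_escape_rate(self):
        r = preset_rates("co_gel")
        assert r["k_2"] == 2.1e7
        assert r["k_b"] / r["k_-b"] == pytest.approx(0.9)

    def test_deoxy_gel_equilibrium(self):
        r = preset_rates("deoxy_gel")
        assert r["k_b"] / r["k_-b"] == pytest.approx(170.0)

    def test_he7q_has_no_his_binding(self):
        r = preset_rates("HE7Q")
        assert "k_b" not in r.values and "k_-b" not in r.values

    def test_placeholders_are_flagged(self):
        r = preset_rates("wt_solution")
        placeholders = [s for s, p in r.provenance.items()
                        if p == "placeholder"]
        assert "k_3" in placeholders and "k_h" in placeholders

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            preset_rates("xenon_gel")


class TestNoisyTraces:
    def test_zero_noise_equals_clean_simulation(self):
        cfg = GeneratorConfig(regime="wt_solution", noise_rel=0.0,
                              noise_abs=0.0, seed=1, points_per_decade=20)
        a = simulate_noisy_trace(cfg, 293.15, 1.0)
        b = simulate_noisy_trace(
            GeneratorConfig(regime="wt_solution", noise_rel=0.0,
                            noise_abs=0.0, seed=999, points_per_decade=20),
            293.15, 1.0)
        assert np.array_equal(a.signal, b.signal)

    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(regime="wt_solution", seed=42,
                              points_per_decade=20)
        a = simulate_noisy_trace(cfg, 293.15, 1.0)
        b = simulate_noisy_trace(cfg, 293.15, 1.0)
        assert np.array_equal(a.signal, b.signal)
        assert a.metadata == b.metadata

    def test_different_seeds_differ(self):
        a = simulate_noisy_trace(GeneratorConfig(seed=1,
                                                 points_per_decade=20),
                                 293.15, 1.0)
        b = simulate_noisy_trace(GeneratorConfig(seed=2,
                                                 points_per_decade=20),
                                 293.15, 1.0)
        assert not np.array_equal(a.signal, b.signal)

    def test_truth_embedded_in_metadata(self):
        cfg = GeneratorConfig(regime="wt_solution", seed=4,
                              points_per_decade=20)
        tr = simulate_noisy_trace(cfg, 293.15, 1.0)
        assert tr.metadata["truth_k_-2"] == 3.04e7
        assert tr.metadata["seed"] == 4
        assert tr.metadata["co_molar"] == pytest.approx(1e-3)

    def test_noise_scatter_matches_nominal(self):
        """Empirical residual scatter stays within 20% of the per-point
        sigma over ~1e3 points."""
        cfg = GeneratorConfig(regime="wt_solution", seed=6,
                              points_per_decade=100)
        clean_cfg = GeneratorConfig(regime="wt_solution", noise_rel=0.0,
                                    noise_abs=0.0, seed=6,
                                    points_per_decade=100)
        noisy = simulate_noisy_trace(cfg, 293.15, 1.0)
        clean = simulate_noisy_trace(clean_cfg, 293.15, 1.0)
        z = (noisy.signal - clean.signal) / noisy.sigma
        assert abs(np.std(z) - 1.0) < 0.2


class TestTwoConcentrations:
    def test_molarity_ratio_is_ten(self):
        cfg = GeneratorConfig(regime="wt_solution", seed=3,
                              points_per_decade=20)
        hi, lo = generate_two_concentration_set(cfg, 293.15)
        assert hi.metadata["co_molar"] / lo.metadata["co_molar"] == \
            pytest.approx(10.0)

    def test_geminate_phase_is_concentration_independent(self):
        cfg = GeneratorConfig(regime="wt_solution", seed=3,
                              points_per_decade=40)
        hi, lo = generate_two_concentration_set(cfg, 293.15)
        early = hi.times < 1e-7
        z = (hi.signal[early] - lo.signal[early]) / np.sqrt(
            hi.sigma[early]**2 + lo.sigma[early]**2)
        # underlying curves agree, so z is pure unit-variance noise
        assert abs(np.mean(z)) < 0.5
        assert abs(np.std(z) - 1.0) < 0.35

    def test_low_concentration_rebinding_is_slower(self):
        cfg = GeneratorConfig(regime="wt_solution", noise_rel=0.0,
                              noise_abs=0.0, seed=3, points_per_decade=20)
        hi, lo = generate_two_concentration_set(cfg, 293.15)
        # area under the survival curve (mean rebinding time proxy)
        assert np.trapezoid(lo.signal, lo.times) > \
            np.trapezoid(hi.signal, hi.times)


class TestTemperatureSeries:
    def _eyring_truth(self, model):
        rng = np.random.default_rng(0)
        base = preset_rates("wt_solution")
        truth = {}
        for sym in model.rate_symbols:
            dH = rng.uniform(20, 60)
            # match the preset value at 20 C so curves stay realistic
            k293 = base[sym]
            from flashkin._constants import KB_OVER_H, R_GAS
            dS = R_GAS * (np.log(k293 / (KB_OVER_H * 293.15))
                          + dH * 1e3 / (R_GAS * 293.15))
            truth[sym] = EyringEntry(dH, dS)
        return truth

    def test_rates_follow_eyring_closed_form(self):
        model = preset_model("wt_solution")
        truth = self._eyring_truth(model)
        cfg = GeneratorConfig(regime="wt_solution", eyring=truth, rates=None,
                              seed=8, points_per_decade=10,
                              temperatures_K=(283.15, 293.15, 303.15))
        series = generate_temperature_series(cfg)
        for T, traces in series.items():
            for sym, entry in truth.items():
                assert traces[0].metadata[f"truth_{sym}"] == \
                    eyring_rate(entry, T)

    def test_round_trip_recovers_activation_parameters(self):
        model = preset_model("wt_solution")
        truth = self._eyring_truth(model)
        temps = (283.15, 293.15, 303.15, 313.15)
        ks = {sym: [eyring_rate(truth[sym], T) for T in temps]
              for sym in truth}
        for sym in ("k_-2", "k_b", "k_-b"):
            fit = eyring_fit(temps, ks[sym])
            assert fit.dH_kJ_mol == pytest.approx(truth[sym].dH_kJ_mol,
                                                  rel=1e-6)
            assert fit.dS_J_molK == pytest.approx(truth[sym].dS_J_molK,
                                                  rel=1e-6)

    def test_single_temperature_warns(self):
        model = preset_model("wt_solution")
        truth = self._eyring_truth(model)
        cfg = GeneratorConfig(regime="wt_solution", eyring=truth, rates=None,
                              seed=8, points_per_decade=10,
                              temperatures_K=(293.15,))
        with pytest.warns(UserWarning, match="fewer than 3"):
            generate_temperature_series(cfg)

    def test_missing_symbol_rejected(self):
        cfg = GeneratorConfig(regime="wt_solution",
                              eyring={"k_b": EyringEntry(50, -20)},
                              rates=None, seed=8)
        with pytest.raises(ValueError, match="missing"):
            generate_temperature_series(cfg)


class TestNodTraces:
    def test_fast_association_limit_is_single_exponential(self):
        tr = generate_nod_trace(k_a=1e10, k_b_nod=370.0)
        fit = fit_single_exponential(tr)
        assert fit.rate == pytest.approx(370.0, rel=0.01)

    def test_default_mixing_stoichiometry(self):
        tr = generate_nod_trace()
        assert tr.metadata["o2cygb_molar"] == pytest.approx(3e-6)
        assert tr.metadata["no_molar"] == pytest.approx(9e-6)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_nod_trace(o2cygb_molar=0.0)
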