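import numpy as np
import pytest

from flashkin.fitting import (FitError, FitSpec, bootstrap_uncertainty,
                              fit_global, fit_single_exponential,
                              goodness_of_fit, runs_test)
from flashkin.scheme import NetworkModel, RateSet, StateSpec, Transition
from flashkin.simulate import (TimeTrace, integrate_network, log_time_grid,
                               survival_signal)
from flashkin.synth import GeneratorConfig, generate_nod_trace, preset_rates


def _simple_model():
    """P1 -> bound plus reversible solvent exchange; identifiable from one
    curve that covers both the geminate and the bimolecular window."""
    return NetworkModel(
        (StateSpec("CygbCO", "bound"), StateSpec("P1", "docked"),
         StateSpec("Cygb_p", "deoxy_penta"), StateSpec("CO_solvent",
                                                       "ligand_pool")),
        (Transition("P1", "CygbCO", "k_-1"),
         Transition("P1", "Cygb_p", "k_2", ligand_partner="CO_solvent"),
         Transition("Cygb_p", "P1", "k_-2", order="bimolecular",
                    ligand_partner="CO_solvent")),
    )


def _noise_free_trace(model, rates, co=1e-3):
    times = log_time_grid(1e-9, 10.0, 40)
    traj = integrate_network(model, rates, {"P1": 1.0}, co, times)
    sig = survival_signal(traj)
    return TimeTrace(times, sig.signal,
                     metadata={"temperature_K": 293.15, "co_molar": co})


class TestSingleExponential:
    def test_exact_model_class_recovery(self):
        t = np.linspace(1e-4, 0.02, 200)
        trace = TimeTrace(t, np.exp(-370.0 * t),
                          metadata={"temperature_K": 293.15})
        fit = fit_single_exponential(trace)
        assert fit.rate == pytest.approx(370.0, rel=1e-3)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)

    def test_noisy_stopped_flow_recovery(self):
        """1% noise perturbs the refit by only a few s^-1 around its
        noise-free value (which sits at the true rate in the
        fast-association limit)."""
        clean = fit_single_exponential(
            generate_nod_trace(k_a=1e9, k_b_nod=370.0))
        noisy = fit_single_exponential(
            generate_nod_trace(k_a=1e9, k_b_nod=370.0, noise_rel=0.01,
                               seed=3))
        assert clean.rate == pytest.approx(370.0, rel=0.005)
        assert abs(noisy.rate - clean.rate) <= 3.0

    def test_partially_resolved_association_biases_low(self):
        """At k_a = 1e8 M^-1 s^-1 the formation lag is not fully hidden in
        the dead time and the single-exponential refit under-estimates the
        intermediate decay rate."""
        fit = fit_single_exponential(generate_nod_trace(k_a=1e8,
                                                        k_b_nod=370.0))
        assert fit.rate < 370.0 * 0.95

    def test_constant_signal_rejected(self):
        t = np.linspace(1e-4, 0.02, 50)
        with pytest.raises(FitError):
            fit_single_exponential(
                TimeTrace(t, np.ones(t.size),
                          metadata={"temperature_K": 293.15}))

    def test_rising_signal_rejected(self):
        t = np.linspace(1e-4, 0.02, 50)
        with pytest.raises(FitError):
            fit_single_exponential(
                TimeTrace(t, 1.0 - np.exp(-300 * t),
                          metadata={"temperature_K": 293.15}))

    def test_too_few_points_rejected(self):
        t = np.linspace(1e-4, 0.02, 4)
        with pytest.raises(ValueError):
            fit_single_exponential(
                TimeTrace(t, np.exp(-300 * t),
                          metadata={"temperature_K": 293.15}))


class TestGlobalFit:
    def test_noise_free_exact_recovery(self):
        model = _simple_model()
        truth = RateSet({"k_-1": 1.5e7, "k_2": 4.2e7, "k_-2": 3.04e7})
        trace = _noise_free_trace(model, truth)
        free = {s: (np.log10(truth[s]) - 1, np.log10(truth[s]) + 1)
                for s in truth.values}
        start = RateSet({s: v * 1.6 for s, v in truth.values.items()})
        spec = FitSpec(model=model, datasets=[trace], free=free)
        result = fit_global(spec, start, seed=0, n_starts=1)
        for s, v in truth.values.items():
            assert np.log10(result.estimates[s]) == pytest.approx(
                np.log10(v), abs=1e-5)
        assert result.chi2_per_point < 1e-12

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(regime="wt_solution", seed=11,
                              points_per_decade=25)
        from flashkin.synth import generate_two_concentration_set
        traces = generate_two_concentration_set(cfg, 293.15)
        truth = preset_rates("wt_solution")
        free = {s: (np.log10(truth[s]) - 1, np.log10(truth[s]) + 1)
                for s in ("k_-2", "k_b", "k_-b")}
        fixed = {s: v for s, v in truth.values.items() if s not in free}
        spec = FitSpec(model=cfg.model, datasets=traces, free=free,
                       fixed=fixed)
        a = fit_global(spec, truth, seed=7, n_starts=2)
        b = fit_global(spec, truth, seed=7, n_starts=2)
        assert a.estimates.values == b.estimates.values

    def test_he7q_data_fits_without_hexacoordination_symbols(self):
        """Mutant data fitted with the mutant model: no His-binding rates
        appear and the fit reaches the noise level (no residual slow
        phase)."""
        cfg = GeneratorConfig(regime="HE7Q", seed=13, variant="HE7Q",
                              points_per_decade=25)
        from flashkin.synth import generate_two_concentration_set
        traces = generate_two_concentration_set(cfg, 293.15)
        truth = preset_rates("HE7Q")
        free = {s: (np.log10(truth[s]) - 1, np.log10(truth[s]) + 1)
                for s in ("k_-1", "k_2", "k_-2")}
        fixed = {s: v for s, v in truth.values.items() if s not in free}
        spec = FitSpec(model=cfg.model, datasets=traces, free=free,
                       fixed=fixed)
        result = fit_global(spec, truth, seed=1, n_starts=2)
        assert "k_b" not in result.estimates.values
        assert result.chi2_per_point < 1.2

    def test_shared_two_concentration_fit_beats_single_dataset(self):
        """Tying k_-2 across both CO concentrations must describe the pair
        better than extrapolating a single-concentration fit."""
        cfg = GeneratorConfig(regime="wt_solution", seed=19,
                              points_per_decade=25)
        from flashkin.synth import generate_two_concentration_set
        traces = generate_two_concentration_set(cfg, 293.15)
        truth = preset_rates("wt_solution")
        free = {"k_-2": (np.log10(truth["k_-2"]) - 1.5,
                         np.log10(truth["k_-2"]) + 1.5)}
        fixed = {s: v for s, v in truth.values.items() if s != "k_-2"}
        start = truth.with_values(**{"k_-2": truth["k_-2"] * 3})

        joint = fit_global(FitSpec(model=cfg.model, datasets=traces,
                                   free=free, fixed=fixed), start, seed=0,
                           n_starts=2)
        single = fit_global(FitSpec(model=cfg.model, datasets=[traces[0]],
                                    free=free, fixed=fixed), start, seed=0,
                            n_starts=2)
        # evaluate the single-dataset estimate on both datasets
        both = FitSpec(model=cfg.model, datasets=traces, free=free,
                       fixed=fixed)
        carried = fit_global(both, single.estimates, seed=0, n_starts=1,
                             jitter=0.0)
        assert joint.chi2 <= carried.chi2 + 1e-6

    def test_unidentifiable_bimolecular_rate_warns(self):
        model = _simple_model()
        truth = RateSet({"k_-1": 1.5e7, "k_2": 4.2e7, "k_-2": 3.04e7})
        times = log_time_grid(1e-9, 1e-7, 40)   # geminate window only
        traj = integrate_network(model, truth, {"P1": 1.0}, 1e-3, times)
        trace = TimeTrace(times, survival_signal(traj).signal,
                          metadata={"temperature_K": 293.15,
                                    "co_molar": 1e-3})
        free = {"k_-2": (6.0, 9.0)}
        fixed = {"k_-1": 1.5e7, "k_2": 4.2e7}
        with pytest.warns(UserWarning, match="bimolecular time window"):
            fit_global(FitSpec(model=model, datasets=[trace], free=free,
                               fixed=fixed), truth, seed=0, n_starts=1)


class TestGoodnessOfFit:
    def test_perfect_fit_has_zero_chi2(self):
        model = _simple_model()
        truth = RateSet({"k_-1": 1.5e7, "k_2": 4.2e7, "k_-2": 3.04e7})
        trace = _noise_free_trace(model, truth)
        free = {s: (np.log10(v) - 1, np.log10(v) + 1)
                for s, v in truth.values.items()}
        result = fit_global(FitSpec(model=model, datasets=[trace],
                                    free=free), truth, seed=0, n_starts=1)
        report = goodness_of_fit(result)
        assert report["datasets"][0]["chi2_per_point"] < 1e-12

    def test_pure_noise_residuals_look_random(self):
        rng = np.random.default_rng(11)
        p = runs_test(rng.standard_normal(400))
        assert 0.01 < p < 0.99

    def test_systematic_misfit_is_flagged(self):
        """Fitting a single exponential to clearly biexponential data
        leaves long same-sign residual stretches."""
        t = np.linspace(1e-4, 0.1, 400)
        y = 0.5 * np.exp(-400 * t) + 0.5 * np.exp(-30 * t)
        trace = TimeTrace(t, y, metadata={"temperature_K": 293.15})
        fit = fit_single_exponential(trace)
        resid = y - (fit.amplitude * np.exp(-fit.rate * t) + fit.offset)
        assert runs_test(resid) < 0.01


class TestBootstrap:
    def _fit(self, seed=23):
        model = _simple_model()
        truth = RateSet({"k_-1": 1.5e7, "k_2": 4.2e7, "k_-2": 3.04e7})
        times = log_time_grid(1e-9, 10.0, 15)
        traj = integrate_network(model, truth, {"P1": 1.0}, 1e-3, times)
        clean = survival_signal(traj).signal
        rng = np.random.default_rng(seed)
        sigma = np.full(times.size, 0.01)
        trace = TimeTrace(times, clean + sigma * rng.standard_normal(
            times.size), sigma=sigma,
            metadata={"temperature_K": 293.15, "co_molar": 1e-3})
        free = {s: (np.log10(v) - 1, np.log10(v) + 1)
                for s, v in truth.values.items()}
        spec = FitSpec(model=model, datasets=[trace], free=free)
        return truth, spec, fit_global(spec, truth, seed=0, n_starts=1)

    def test_interval_covers_truth(self):
        truth, spec, result = self._fit()
        boot = bootstrap_uncertainty(spec, result, n_boot=20, seed=5)
        assert boot["failure_fraction"] < 0.2
        for sym, q in boot["parameters"].items():
            assert q["q025_log10"] - 0.05 <= np.log10(truth[sym]) \
                <= q["q975_log10"] + 0.05

    def test_zero_boot_rejected(self):
        truth, spec, result = self._fit()
        with pytest.raises(ValueError):
            bootstrap_uncertainty(spec, result, n_boot=0, seed=0)
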