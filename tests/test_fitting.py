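import numpy as np
import pytest

from navsig import (AcquisitionConfig, OnsetSigmoidicityModel,
                    activation_iv_curve, activation_recovery_dataset,
                    boltzmann_availability, build_activation_protocol,
                    build_inactivation_protocol, fit_activation_iv,
                    fit_inactivation_boltzmann, fit_onset_sigmoidicity,
                    inactivation_recovery_dataset, measure_peak,
                    normalize_dataset, parametric_trace, sigmoidicity_profile,
                    simulate_current)
from navsig.protocols import VoltageProtocol
from navsig.simulate import CurrentTrace


def _proto(hold_ms=5.0, test_ms=5.0, vtest=0.0):
    return VoltageProtocol(((hold_ms, -110.0), (test_ms, vtest)))


class TestMeasurePeak:
    def test_pure_rise_peak_is_plateau(self):
        tr = parametric_trace(_proto(test_ms=10.0), amplitude=500.0, tau=0.2,
                              n_gates=5.0)
        amp, _t = measure_peak(tr)
        assert amp == pytest.approx(500.0, rel=1e-6)

    def test_hh_peak_is_negative(self, hh_model):
        proto = build_activation_protocol(-120.0, 150.0, [0.0], 25.0)[0]
        amp, t_peak = measure_peak(simulate_current(hh_model, proto))
        assert amp < 0
        assert t_peak > 0

    def test_flat_trace_zero_peak(self):
        tr = CurrentTrace(dt=0.01, current=np.zeros(1000), onset_index=500,
                          protocol=_proto())
        amp, _ = measure_peak(tr)
        assert amp == 0.0

    def test_all_excluded_window_rejected(self):
        tr = CurrentTrace(dt=0.01, current=np.ones(1000), onset_index=500,
                          protocol=None,
                          excluded=np.arange(1000) >= 500)
        with pytest.raises(ValueError, match="excluded"):
            measure_peak(tr)


class TestOnsetFit:
    @pytest.mark.parametrize("n_true", [1.0, 2.0, 3.0, 5.0, 9.0])
    @pytest.mark.parametrize("tau_true", [0.05, 0.2, 1.0])
    def test_exact_self_recovery(self, n_true, tau_true):
        """Noiseless exponential-power waveforms are recovered to 1e-3."""
        tr = parametric_trace(_proto(test_ms=max(10 * tau_true, 2.0)),
                              amplitude=-500.0, tau=tau_true, n_gates=n_true,
                              dt=0.002)
        fit = OnsetSigmoidicityModel(tr, truncation=0.0).fit()
        assert fit.converged
        assert fit.imax == pytest.approx(500.0, rel=1e-3)
        assert fit.tau == pytest.approx(tau_true, rel=1e-3)
        assert fit.n == pytest.approx(n_true, rel=1e-3)

    def test_window_respects_truncation_and_half_rise(self):
        tr = parametric_trace(_proto(), amplitude=-500.0, tau=0.3, n_gates=3.0)
        fit = fit_onset_sigmoidicity(tr)
        assert fit.window[0] == pytest.approx(0.05)
        t50 = -0.3 * np.log(1 - 0.5 ** (1 / 3.0))
        assert fit.window[1] == pytest.approx(t50, abs=2 * tr.dt)

    def test_hh_at_zero_mv_gives_three_gates(self, hh_model):
        proto = build_activation_protocol(-120.0, 150.0, [0.0], 25.0)[0]
        fit = fit_onset_sigmoidicity(simulate_current(hh_model, proto))
        assert fit.n == pytest.approx(3.0, abs=0.3)

    def test_fixed_n_leaves_n_pinned_and_residual_larger(self):
        tr = parametric_trace(_proto(), amplitude=-500.0, tau=0.2, n_gates=9.0)
        free = fit_onset_sigmoidicity(tr)
        fixed = fit_onset_sigmoidicity(tr, fix_n=3.0)
        assert fixed.n == 3.0
        assert fixed.fixed_n
        assert free.residual_norm <= fixed.residual_norm

    def test_nine_gate_recovery_under_noise(self):
        """1% noise: N recovered near 9 across repeated seeds."""
        proto = _proto(test_ms=10.0)
        cfg_base = dict(leak_conductance=0.0, cap_amplitude=0.0,
                        filter_cutoff_khz=0.0, sampling_interval=0.005)
        ns_rec = []
        for seed in range(20):
            tr = parametric_trace(proto, amplitude=-500.0, tau=0.4,
                                  n_gates=9.0)
            from navsig import emulate_acquisition
            rec = emulate_acquisition(
                tr, AcquisitionConfig(noise_sd=5.0, seed=seed, **cfg_base))
            ns_rec.append(fit_onset_sigmoidicity(rec).n)
        ns_rec = np.array(ns_rec)
        assert abs(ns_rec.mean() - 9.0) < 3 * ns_rec.std(ddof=1)
        assert ns_rec.std(ddof=1) < 2.0

    def test_short_window_rejected(self):
        tr = parametric_trace(_proto(), amplitude=-500.0, tau=0.01,
                              n_gates=1.0, dt=0.005)
        with pytest.raises(ValueError, match="at least"):
            fit_onset_sigmoidicity(tr)

    def test_scale_invariance(self):
        tr = parametric_trace(_proto(), amplitude=-400.0, tau=0.25,
                              n_gates=4.0)
        scaled = CurrentTrace(dt=tr.dt, current=tr.current * 7.5,
                              onset_index=tr.onset_index, protocol=tr.protocol)
        f1, f2 = fit_onset_sigmoidicity(tr), fit_onset_sigmoidicity(scaled)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-6)
        assert f2.n == pytest.approx(f1.n, rel=1e-6)
        assert f2.imax == pytest.approx(7.5 * f1.imax, rel=1e-6)


class TestActivationCurve:
    def test_exact_recovery(self):
        v = np.arange(-60.0, 41.0, 5.0)
        truth = dict(b=0.0126, e_rev=75.0, v_half=-24.0, z=5.2)
        i = activation_iv_curve(v, **truth)
        fit = fit_activation_iv(v, i)
        assert fit.converged
        for k, val in truth.items():
            assert getattr(fit, k if k != "b" else "b") == pytest.approx(
                val, rel=1e-4)
        # fitted curve vanishes at the reversal potential
        assert fit.predict(fit.e_rev) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_data_flagged_degenerate(self):
        v = np.arange(-60.0, 41.0, 10.0)
        fit = fit_activation_iv(v, np.zeros_like(v))
        assert fit.degenerate
        assert not fit.converged

    def test_degenerate_voltage_range_rejected(self):
        with pytest.raises(ValueError):
            fit_activation_iv([0.0, 1.0, 2.0, 3.0, 4.0], np.ones(5))


class TestInactivationCurve:
    def test_exact_recovery_on_standard_grid(self):
        v = np.arange(-110.0, -24.0, 5.0)
        a = boltzmann_availability(v, -64.5, 8.3)
        fit = fit_inactivation_boltzmann(v, a)
        assert fit.converged and fit.monotone
        assert fit.v_half == pytest.approx(-64.5, abs=1e-6)
        assert fit.z == pytest.approx(8.3, abs=1e-6)
        assert fit.predict(fit.v_half) == pytest.approx(0.5)

    def test_non_monotone_data_flagged_but_fitted(self):
        v = np.arange(-110.0, -24.0, 10.0)
        a = boltzmann_availability(v, -64.5, 8.3)[::-1]  # grossly reversed
        fit = fit_inactivation_boltzmann(v, a)
        assert not fit.monotone

    def test_hh_pipeline_recovers_h_inf_midpoint(self, hh_model):
        """simulate -> emulate -> normalize -> fit lands within 2 mV of
        the analytic h_inf midpoint of the model."""
        from navsig import generate_patch_dataset

        protos = build_inactivation_protocol(np.arange(-110.0, -24.0, 5.0),
                                             150.0, 0.0, 25.0)
        cfg = AcquisitionConfig(noise_sd=0.0)
        ds = generate_patch_dataset(hh_model, protos, n_patches=1,
                                    scale_cv=0.0, config=cfg, seed=0,
                                    mode="inactivation")
        table = normalize_dataset(ds, mode="inactivation")
        fit = fit_inactivation_boltzmann(table.index.to_numpy(),
                                         table["mean"].to_numpy())
        s = hh_model.scheme
        vv = np.linspace(-90.0, -40.0, 2001)
        h_inf = s.alpha_h(vv) / (s.alpha_h(vv) + s.beta_h(vv))
        v_mid = vv[np.argmin(np.abs(h_inf - 0.5))]
        assert fit.v_half == pytest.approx(v_mid, abs=2.0)


class TestNormalizeDataset:
    def _dataset(self, seed=0, scale_cv=0.0, noise=0.0):
        cfg = AcquisitionConfig(noise_sd=noise)
        return activation_recovery_dataset(n_patches=2, scale_cv=scale_cv,
                                           amplitude_jitter_sd=0.0,
                                           config=cfg, seed=seed)

    def test_reference_is_minus_one_for_inward(self):
        ds = self._dataset()
        table = normalize_dataset(ds, mode="activation")
        assert table.loc[-10.0, "mean"] == pytest.approx(-1.0, abs=1e-6)

    def test_identical_patches_zero_sem(self):
        table = normalize_dataset(self._dataset(), mode="activation")
        assert np.allclose(table["sem"], 0.0, atol=1e-9)

    def test_scale_jitter_invariance(self):
        """Per-patch conductance scaling cancels in normalized curves."""
        t0 = normalize_dataset(self._dataset(scale_cv=0.0), "activation")
        t1 = normalize_dataset(self._dataset(scale_cv=0.3), "activation")
        assert np.allclose(t0["mean"], t1["mean"], atol=1e-6)

    def test_missing_reference_names_patch(self):
        ds = self._dataset()
        for patch in ds.traces:
            del patch[10]  # the -10 mV condition
        with pytest.raises(ValueError, match="patch 0"):
            normalize_dataset(ds, mode="activation")


class TestSigmoidicityProfile:
    def test_hh_activation_sweep_flat_at_three(self, hh_model):
        protos = build_activation_protocol(-120.0, 150.0,
                                           np.arange(-20.0, 41.0, 10.0), 25.0)
        traces = []
        for p in protos:
            tr = simulate_current(hh_model, p)
            tr.condition_voltage = p.test_voltage
            traces.append(tr)
        prof = sigmoidicity_profile(traces)
        assert np.all(np.abs(prof["n_mean"] - 3.0) <= 0.3)
        assert prof["n_failed"].sum() == 0

    def test_chain_prepulse_profile_monotone_nonincreasing(self, chain6_model):
        protos = build_inactivation_protocol(np.arange(-120.0, -39.0, 10.0),
                                             150.0, 0.0, 25.0)
        traces = []
        for p in protos:
            tr = simulate_current(chain6_model, p)
            tr.condition_voltage = p.epochs[0][1]
            traces.append(tr)
        prof = sigmoidicity_profile(traces, condition="prepulse")
        ok = prof[prof["n_reps"] > 0]
        assert np.all(np.diff(ok["n_mean"]) <= 1e-6)

    def test_failed_fits_counted_not_raised(self):
        tr = CurrentTrace(dt=0.01, current=np.zeros(1000), onset_index=500,
                          protocol=_proto(), condition_voltage=0.0)
        prof = sigmoidicity_profile([tr])
        assert prof.loc[0, "n_failed"] == 1
        assert np.isnan(prof.loc[0, "n_mean"])


class TestMonteCarloRecovery:
    def test_activation_parameters_recovered(self):
        truth = dict(e_rev=75.0, v_half=-24.0, z=5.2)
        est = {k: [] for k in truth}
        for seed in range(30):
            ds = activation_recovery_dataset(n_patches=9, scale_cv=0.2,
                                             seed=seed)
            table = normalize_dataset(ds, mode="activation")
            fit = fit_activation_iv(table.index.to_numpy(),
                                    table["mean"].to_numpy())
            for k in truth:
                est[k].append(getattr(fit, k))
        for k, val in truth.items():
            arr = np.array(est[k])
            assert abs(arr.mean() - val) < 3 * max(arr.std(ddof=1), 1e-3)

    def test_inactivation_parameters_recovered(self):
        truth = dict(v_half=-64.5, z=8.3)
        est = {k: [] for k in truth}
        for seed in range(30):
            ds = inactivation_recovery_dataset(n_patches=11, scale_cv=0.2,
                                               seed=seed)
            table = normalize_dataset(ds, mode="inactivation")
            fit = fit_inactivation_boltzmann(table.index.to_numpy(),
                                             table["mean"].to_numpy())
            for k in truth:
                est[k].append(getattr(fit, k))
        for k, val in truth.items():
            arr = np.array(est[k])
            assert abs(arr.mean() - val) < 3 * max(arr.std(ddof=1), 5e-3)
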