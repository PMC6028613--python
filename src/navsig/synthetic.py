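"""Parametric synthetic current families for recovery studies.

These generators produce traces whose test-epoch transients follow the
exponential-power rise exactly and whose peak amplitudes follow a
prescribed activation I-V relation or steady-state inactivation
(availability) curve.  Passed through the acquisition-chain emulation
they provide ground-truth datasets for Monte-Carlo parameter-recovery
checks of the analysis stage — something no Markov simulation can give,
because there the curve parameters are emergent rather than prescribed.
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionConfig, PatchDataset, emulate_acquisition
from .fitting import activation_iv_curve, boltzmann_availability, onset_waveform
from .protocols import (VoltageProtocol, build_activation_protocol,
                        build_inactivation_protocol)
from .simulate import CurrentTrace

__all__ = ["parametric_trace", "activation_recovery_dataset",
           "inactivation_recovery_dataset"]


def parametric_trace(protocol: VoltageProtocol, amplitude: float,
                     tau: float = 0.3, n_gates: float = 3.0,
                     dt: float = 0.005) -> CurrentTrace:
    """An ideal trace whose test-epoch current is amplitude*(1-e^(-t/tau))^N.

    ``amplitude`` is signed (negative for inward).  The current is zero
    outside the test epoch, mimicking a perfectly leak-subtracted
    recording with no pre-step conductance.
    """
    if tau <= 0 or n_gates <= 0 or dt <= 0:
        raise ValueError("tau, n_gates and dt must be positive")
    n_total = int(round(protocol.total_duration / dt))
    onset = int(round(protocol.onset_time / dt))
    current = np.zeros(n_total + 1)
    t_rel = (np.arange(onset, n_total + 1) - onset) * dt
    current[onset:] = np.sign(amplitude) * onset_waveform(
        t_rel, abs(amplitude), tau, n_gates)
    return CurrentTrace(dt=dt, current=current, onset_index=onset,
                        protocol=protocol,
                        meta={"model": "parametric", "ideal": True,
                              "filtered": False, "truncated": False})


def _patch_scales(rng: np.random.Generator, n_patches: int,
                  scale_cv: float) -> np.ndarray:
    if scale_cv <= 0:
        return np.ones(n_patches)
    sigma = np.sqrt(np.log1p(scale_cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=n_patches)


def activation_recovery_dataset(voltages=None, b: float | None = None,
                                e_rev: float = 75.0, v_half: float = -24.0,
                                z: float = 5.2, i_ref: float = 1000.0,
                                n_patches: int = 9, scale_cv: float = 0.2,
                                amplitude_jitter_sd: float = 0.05,
                                config: AcquisitionConfig | None = None,
                                seed: int | None = None,
                                hold: float = -110.0, hold_duration: float = 5.0,
                                test_duration: float = 5.0) -> PatchDataset:
    """Multi-patch activation family with peaks drawn from the I-V curve.

    Defaults place the half-activation at -24 mV with slope 5.2 mV and
    reversal at +75 mV, with ``b`` chosen so the -10 mV response has
    magnitude ``i_ref`` (the conventional normalization point).
    ``amplitude_jitter_sd`` adds independent per-patch, per-condition
    amplitude scatter (in normalized units) on top of the acquisition
    noise, emulating sweep-to-sweep biological variability.  Short
    5 ms epochs keep the dataset compact; the curve parameters are
    unaffected by epoch length.
    """
    if voltages is None:
        voltages = np.arange(-60.0, 41.0, 5.0)
    voltages = np.asarray(voltages, dtype=float)
    if b is None:
        b = 1.0 / abs(activation_iv_curve(-10.0, 1.0, e_rev, v_half, z))
    config = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    scales = _patch_scales(rng, n_patches, scale_cv)
    protos = build_activation_protocol(hold, hold_duration, voltages,
                                       test_duration)
    amplitudes = i_ref * activation_iv_curve(voltages, b, e_rev, v_half, z)
    patches = []
    for i in range(n_patches):
        patch = []
        for proto, amp, v in zip(protos, amplitudes, voltages):
            amp_i = amp + i_ref * amplitude_jitter_sd * rng.standard_normal()
            tr = parametric_trace(proto, amp_i * scales[i])
            tr.condition_voltage = float(v)
            rec = emulate_acquisition(tr, config, rng=rng)
            rec.meta["patch"] = i
            patch.append(rec)
        patches.append(patch)
    return PatchDataset(traces=patches, scales=scales, mode="activation",
                        meta={"model": "parametric-activation", "seed": seed,
                              "truth": {"b": float(b), "e_rev": e_rev,
                                        "v_half": v_half, "z": z}})


def inactivation_recovery_dataset(prepulses=None, v_half: float = -64.5,
                                  z: float = 8.3, i_ref: float = 1000.0,
                                  n_patches: int = 11, scale_cv: float = 0.2,
                                  amplitude_jitter_sd: float = 0.05,
                                  config: AcquisitionConfig | None = None,
                                  seed: int | None = None,
                                  prepulse_duration: float = 5.0,
                                  test_duration: float = 5.0) -> PatchDataset:
    """Multi-patch inactivation family with availability from a Boltzmann.

    Defaults: half-inactivation at -64.5 mV, slope 8.3 mV, pre-pulses
    from -110 to -25 mV in 5 mV steps, all stepping to 0 mV, with
    per-sweep amplitude scatter as in
    :func:`activation_recovery_dataset`.
    """
    if prepulses is None:
        prepulses = np.arange(-110.0, -24.0, 5.0)
    prepulses = np.asarray(prepulses, dtype=float)
    config = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    scales = _patch_scales(rng, n_patches, scale_cv)
    protos = build_inactivation_protocol(prepulses, prepulse_duration, 0.0,
                                         test_duration)
    avail = boltzmann_availability(prepulses, v_half, z)
    patches = []
    for i in range(n_patches):
        patch = []
        for proto, a, v in zip(protos, avail, prepulses):
            a_i = a + amplitude_jitter_sd * rng.standard_normal()
            tr = parametric_trace(proto, -i_ref * a_i * scales[i])
            tr.condition_voltage = float(v)
            rec = emulate_acquisition(tr, config, rng=rng)
            rec.meta["patch"] = i
            patch.append(rec)
        patches.append(patch)
    return PatchDataset(traces=patches, scales=scales, mode="inactivation",
                        meta={"model": "parametric-inactivation", "seed": seed,
                              "truth": {"v_half": v_half, "z": z}})
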