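"""Patch-clamp acquisition-chain emulation and synthetic patch datasets.

Ideal simulated currents are turned into "recorded" traces with the
statistical structure of nucleated-patch voltage-clamp data: linear
leak, capacitive transients at each command step, P/4 leak subtraction,
4-pole low-pass Bessel filtering (20 kHz, causal), resampling to the
acquisition grid (100 kHz), band-limited Gaussian noise, and exclusion
of the first 50 us after the test-step onset from all analysis.

P/4 subtraction is emulated analytically: the linear part of the leak
and capacitive responses is subtracted exactly, which is what an ideal
P/4 protocol achieves for linear components.  A residual remains only
if the capacitive transient is given a nonlinear amplitude component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .protocols import VoltageProtocol
from .schemes import ChannelModel
from .simulate import CurrentTrace, simulate_current

__all__ = [
    "AcquisitionConfig",
    "PatchDataset",
    "emulate_acquisition",
    "generate_patch_dataset",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of the emulated acquisition chain.

    Defaults follow standard nucleated-patch practice: 100 kHz sampling,
    20 kHz low-pass, capacitive transients decaying well inside 40 us,
    and the first 50 us after the step discarded from analysis.
    """

    sampling_interval: float = 0.01  # ms (100 kHz)
    filter_cutoff_khz: float = 20.0  # low-pass corner; 0 disables filtering
    noise_sd: float = 2.0  # pA, white noise added before filtering
    truncate_after_onset: float = 0.05  # ms excluded from fits after the step
    leak_conductance: float = 1.0  # nS
    leak_reversal: float = 0.0  # mV
    cap_amplitude: float = 10.0  # pA per mV of command step
    cap_tau: float = 0.02  # ms; transient decays to baseline in < 40 us
    cap_nonlinear_fraction: float = 0.0  # fraction of transient escaping P/4
    p4_subtraction: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.truncate_after_onset < 0:
            raise ValueError("truncation window must be >= 0")
        nyquist_khz = 0.5 / self.sampling_interval  # kHz, since dt is in ms
        if self.filter_cutoff_khz >= nyquist_khz:
            raise ValueError(
                f"filter cutoff {self.filter_cutoff_khz} kHz must be below the "
                f"Nyquist frequency {nyquist_khz} kHz of the acquisition grid"
            )
        if self.cap_tau <= 0:
            raise ValueError("capacitive time constant must be positive")


@dataclass
class PatchDataset:
    """Traces for a set of simulated patches across a protocol family.

    ``traces[patch_index]`` is a list of :class:`CurrentTrace`, one per
    protocol, each carrying its ``condition_voltage``.  ``scales`` holds
    the per-patch multiplicative conductance factors.
    """

    traces: list[list[CurrentTrace]]
    scales: np.ndarray
    mode: str  # "activation" | "inactivation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("per-patch scale factors must be positive")
        if len(self.traces) != self.scales.size:
            raise ValueError("one scale factor per patch required")

    @property
    def n_patches(self) -> int:
        return len(self.traces)

    def iter_traces(self):
        for i, patch in enumerate(self.traces):
            for tr in patch:
                yield i, tr


def _linear_artifacts(protocol: VoltageProtocol, t: np.ndarray,
                      config: AcquisitionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Leak current and the (linear, nonlinear) capacitive transients."""
    v = protocol.voltage_at(t)
    leak = config.leak_conductance * (v - config.leak_reversal)
    cap_lin = np.zeros_like(t)
    cap_nl = np.zeros_like(t)
    t_edge = 0.0
    for k in range(len(protocol.epochs) - 1):
        t_edge += protocol.epochs[k][0]
        dv = protocol.epochs[k + 1][1] - protocol.epochs[k][1]
        after = t >= t_edge - 1e-12
        decay = np.exp(-(t[after] - t_edge) / config.cap_tau)
        cap_lin[after] += config.cap_amplitude * dv * decay
        # quadratic amplitude component (per 100 mV of step) escapes P/4
        cap_nl[after] += (config.cap_nonlinear_fraction * config.cap_amplitude
                          * dv * abs(dv) / 100.0 * decay)
    return leak, (cap_lin, cap_nl)


def emulate_acquisition(ideal: CurrentTrace, config: AcquisitionConfig,
                        rng: np.random.Generator | None = None) -> CurrentTrace:
    """Pass an ideal trace through the emulated recording chain.

    Order of operations: add leak and capacitive transients, add white
    noise, apply P/4 subtraction (exact for the linear components),
    low-pass filter (causal 4-pole Bessel), resample to the acquisition
    grid, and mark the truncation window after the test onset as
    excluded.  Noise precedes the filter so that recorded noise is
    band-limited, as in a real amplifier chain.
    """
    if ideal.protocol is None:
        raise ValueError("acquisition emulation needs the trace's protocol")
    if config.sampling_interval + 1e-12 < ideal.dt:
        raise ValueError("ideal trace must be sampled at least as finely as the "
                         "acquisition grid")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    t = ideal.time
    y = ideal.current.copy()
    leak, (cap_lin, cap_nl) = _linear_artifacts(ideal.protocol, t, config)
    y = y + leak + cap_lin + cap_nl
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=y.size)
    if config.p4_subtraction:
        y = y - leak - cap_lin  # linear components cancel exactly

    fine_rate_khz = 1.0 / ideal.dt  # kHz
    if config.filter_cutoff_khz > 0:
        if config.filter_cutoff_khz >= 0.5 * fine_rate_khz:
            raise ValueError("filter cutoff at or above the Nyquist frequency "
                             "of the ideal trace")
        sos = signal.bessel(4, config.filter_cutoff_khz / (0.5 * fine_rate_khz),
                            btype="low", output="sos", norm="mag")
        y = signal.sosfilt(sos, y)
        # A Bessel response has maximally flat group delay, so the filter
        # acts (within its band) as a pure delay; compensate the known
        # constant delay to keep the recorded time base aligned with the
        # command step.
        _w, gd = signal.group_delay(signal.sos2tf(sos), w=[0.0], fs=2 * np.pi)
        shift = int(round(float(gd[0])))
        if shift > 0:
            y = np.concatenate([y[shift:], np.full(shift, y[-1])])

    ratio = config.sampling_interval / ideal.dt
    if abs(ratio - round(ratio)) < 1e-9:
        stride = int(round(ratio))
        y_out = y[::stride]
        n_out = y_out.size
        onset_out = ideal.onset_index // stride
        if ideal.onset_index % stride:
            raise ValueError("test onset does not fall on the acquisition grid")
    else:
        t_out = np.arange(0.0, t[-1] + 1e-12, config.sampling_interval)
        y_out = np.interp(t_out, t, y)
        n_out = y_out.size
        onset_out = int(round(ideal.onset_time / config.sampling_interval))

    excluded = np.zeros(n_out, dtype=bool)
    if config.truncate_after_onset > 0:
        t_rel = (np.arange(n_out) - onset_out) * config.sampling_interval
        excluded[(t_rel >= -1e-12)
                 & (t_rel < config.truncate_after_onset - 1e-12)] = True

    meta = dict(ideal.meta)
    meta.update({"filtered": config.filter_cutoff_khz > 0, "truncated": True,
                 "ideal": False, "noise_sd": config.noise_sd,
                 "sampling_interval": config.sampling_interval})
    return CurrentTrace(
        dt=config.sampling_interval,
        current=y_out,
        onset_index=onset_out,
        protocol=ideal.protocol,
        condition_voltage=ideal.condition_voltage,
        excluded=excluded,
        meta=meta,
    )


def generate_patch_dataset(model: ChannelModel, protocols,
                           n_patches: int = 9, scale_cv: float = 0.2,
                           config: AcquisitionConfig | None = None,
                           seed: int | None = None,
                           mode: str = "activation",
                           dt: float = 0.005) -> PatchDataset:
    """Simulate a multi-patch dataset for a protocol family.

    Each patch receives an independent multiplicative conductance scale
    (log-normal with coefficient of variation ``scale_cv``; kinetics are
    shared across patches) and independent acquisition noise.  The
    default of nine patches matches typical nucleated-patch ensemble
    sizes.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if mode not in ("activation", "inactivation"):
        raise ValueError("mode must be 'activation' or 'inactivation'")
    if config is None:
        config = AcquisitionConfig()
    rng = np.random.default_rng(seed)
    if scale_cv > 0:
        sigma = np.sqrt(np.log1p(scale_cv**2))
        scales = rng.lognormal(-0.5 * sigma**2, sigma, size=n_patches)
    else:
        scales = np.ones(n_patches)

    ideals = []
    for proto in protocols:
        tr = simulate_current(model, proto, dt=dt)
        tr.condition_voltage = (proto.test_voltage if mode == "activation"
                                else proto.epochs[proto.test_epoch - 1][1])
        ideals.append(tr)

    patches: list[list[CurrentTrace]] = []
    for i in range(n_patches):
        patch = []
        for tr in ideals:
            scaled = CurrentTrace(
                dt=tr.dt, current=tr.current * scales[i],
                onset_index=tr.onset_index, protocol=tr.protocol,
                condition_voltage=tr.condition_voltage, meta=dict(tr.meta),
            )
            rec = emulate_acquisition(scaled, config, rng=rng)
            rec.meta["patch"] = i
            patch.append(rec)
        patches.append(patch)
    return PatchDataset(
        traces=patches, scales=scales, mode=mode,
        meta={"model": model.name, "n_patches": n_patches,
              "scale_cv": scale_cv, "seed": seed, "dt": dt},
    )
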