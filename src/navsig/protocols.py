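"""Voltage-clamp command protocols.

A protocol is an ordered list of constant-voltage epochs.  One epoch is
designated the *test* epoch; its onset defines t = 0 for all downstream
onset analysis (the command transition is treated as instantaneous — an
ideal clamp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoltageProtocol",
    "build_activation_protocol",
    "build_inactivation_protocol",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered list of (duration ms, command voltage mV) epochs."""

    epochs: tuple[tuple[float, float], ...]
    label: str = ""
    test_epoch: int = 1

    def __post_init__(self) -> None:
        if len(self.epochs) < 2:
            raise ValueError("a protocol needs at least a holding and a test epoch")
        for dur, _v in self.epochs:
            if dur <= 0:
                raise ValueError("epoch durations must be positive")
        if not 0 <= self.test_epoch < len(self.epochs):
            raise ValueError("test epoch index out of range")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.epochs)

    @property
    def onset_time(self) -> float:
        """Time (ms from sweep start) of the test-epoch onset."""
        return sum(d for d, _ in self.epochs[: self.test_epoch])

    @property
    def test_voltage(self) -> float:
        return self.epochs[self.test_epoch][1]

    def voltage_at(self, t):
        """Command voltage at time(s) ``t`` (ms from sweep start)."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([d for d, _ in self.epochs])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, len(self.epochs) - 1)
        volts = np.array([v for _, v in self.epochs])
        out = volts[idx]
        return float(out) if out.ndim == 0 else out


def build_activation_protocol(hold: float, hold_duration: float,
                              test_voltages, test_duration: float = 25.0,
                              ) -> list[VoltageProtocol]:
    """Activation family: hold, then step to each test potential.

    Default geometry mirrors the standard nucleated-patch protocol: a
    150 ms conditioning hold followed by a depolarizing test step whose
    onset is t = 0 for analysis.
    """
    test_voltages = list(np.atleast_1d(test_voltages).astype(float))
    if not test_voltages:
        raise ValueError("test voltage list must be non-empty")
    if hold_duration <= 0 or test_duration <= 0:
        raise ValueError("durations must be positive")
    return [
        VoltageProtocol(
            epochs=((hold_duration, float(hold)), (test_duration, float(vt))),
            label=f"act_{vt:+.0f}mV",
            test_epoch=1,
        )
        for vt in test_voltages
    ]


def build_inactivation_protocol(prepulse_voltages, prepulse_duration: float,
                                test_voltage: float = 0.0,
                                test_duration: float = 25.0,
                                ) -> list[VoltageProtocol]:
    """Steady-state inactivation family: variable pre-pulse, common test step.

    The pre-pulse (typically 150 ms, swept e.g. from -110 to -25 mV)
    sets the channel availability and closed-state occupancy before the
    step to the common test voltage (typically 0 mV).
    """
    prepulse_voltages = list(np.atleast_1d(prepulse_voltages).astype(float))
    if not prepulse_voltages:
        raise ValueError("pre-pulse voltage list must be non-empty")
    if prepulse_duration <= 0 or test_duration <= 0:
        raise ValueError("durations must be positive")
    return [
        VoltageProtocol(
            epochs=((prepulse_duration, float(vp)), (test_duration, float(test_voltage))),
            label=f"inact_{vp:+.0f}mV",
            test_epoch=1,
        )
        for vp in prepulse_voltages
    ]
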