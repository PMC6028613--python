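"""Ideal (noise-free) voltage-clamp current simulation.

``simulate_current`` turns a :class:`~navsig.schemes.ChannelModel` plus
a :class:`~navsig.protocols.VoltageProtocol` into a uniformly sampled
current trace: the initial state is the stationary state at the first
epoch's voltage, occupancy is propagated epoch-by-epoch with continuity
across the command steps, and

    I(t) = g_max * P_open(t) * (V(t) - E_rev)   [pA].

Inward current is negative.  Traces are noise-free and unfiltered; the
acquisition chain (filtering, noise, leak, P/4) lives in
:mod:`navsig.acquisition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import open_probability, propagate_epoch, steady_state
from .protocols import VoltageProtocol
from .schemes import ChannelModel, HHGatingScheme, OccupancyState

__all__ = ["CurrentTrace", "simulate_current"]

DEFAULT_DT = 0.005  # ms (5 us), matches the acquisition-chain emulation


@dataclass
class CurrentTrace:
    """A uniformly sampled current time series.

    Attributes
    ----------
    dt : float
        Sampling interval (ms).
    current : ndarray
        Current samples (pA); inward negative.
    onset_index : int
        Index of the first sample of the test epoch (t = 0 for onset
        analysis).
    protocol : VoltageProtocol or None
    condition_voltage : float or None
        The swept condition this trace belongs to (test potential for an
        activation family, pre-pulse potential for an inactivation
        family).
    excluded : ndarray of bool or None
        Samples excluded from analysis (e.g. the truncation window after
        the step); retained in the trace but never entering fits.
    meta : dict
        Provenance: model id, seed, filtered/truncated flags, ...
    """

    dt: float
    current: np.ndarray
    onset_index: int
    protocol: VoltageProtocol | None = None
    condition_voltage: float | None = None
    excluded: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1:
            raise ValueError("current must be a 1-D array")
        if not 0 <= self.onset_index < self.current.size:
            raise ValueError("onset index out of bounds")
        if self.excluded is not None:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.current.shape:
                raise ValueError("exclusion mask must match the trace length")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms from sweep start."""
        return np.arange(self.n_samples) * self.dt

    @property
    def time_from_onset(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.onset_index) * self.dt

    @property
    def onset_time(self) -> float:
        return self.onset_index * self.dt

    def included_mask(self) -> np.ndarray:
        if self.excluded is None:
            return np.ones(self.n_samples, dtype=bool)
        return ~self.excluded


def simulate_current(model: ChannelModel, protocol: VoltageProtocol,
                     dt: float = DEFAULT_DT, method: str = "expm",
                     ) -> CurrentTrace:
    """Simulate the ensemble current for one protocol sweep.

    The default step of 5 us gives exact piecewise-constant propagation
    (matrix exponential per epoch; analytic relaxation for gate
    schemes); ``method="fixed"`` selects the RK4 fixed-step integrator
    for cross-validation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    scheme = model.scheme
    state = steady_state(scheme, protocol.epochs[0][1])
    po_parts: list[np.ndarray] = []
    onset_index = 0
    for k, (duration, v) in enumerate(protocol.epochs):
        t, course = propagate_epoch(scheme, v, state, duration, dt, method=method)
        po = np.asarray(open_probability(scheme, course), dtype=float)
        last = k == len(protocol.epochs) - 1
        po_parts.append(model.current(po if last else po[:-1], v))
        if k < protocol.test_epoch:
            onset_index += po.size - 1
        # carry the endpoint state into the next epoch (continuity)
        if isinstance(scheme, HHGatingScheme):
            from .kinetics import HHGateState

            state = HHGateState(course["m"][-1],
                                course["h"][-1] if scheme.q else None)
        else:
            state = OccupancyState(course[-1], scheme.labels)
    current = np.concatenate(po_parts)
    return CurrentTrace(
        dt=dt,
        current=current,
        onset_index=onset_index,
        protocol=protocol,
        condition_voltage=None,
        meta={"model": model.name, "dt": dt, "method": method,
              "filtered": False, "truncated": False, "ideal": True},
    )
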