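"""Occupancy dynamics of gating schemes under constant voltage.

The voltage-clamp protocols handled by this package are piecewise
constant, so each epoch can be propagated either exactly — analytic
gate relaxation for independent-gate schemes, matrix exponential for
Markov chains — or with a fixed-step integrator (classical RK4 at the
acquisition-matched step of 5 us) retained for cross-validation.  The
matrix-exponential route is the default.

Also implemented here is the mean activation latency of a linear chain
in the depolarized regime where backward rates are negligible,

    delta(V) = sum_i 1 / alpha_i(V),

the mean first-passage time from the deepest closed state to the open
state of the backward-rate-free chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, null_space

from .schemes import HHGatingScheme, LinearChainScheme, OccupancyState

__all__ = [
    "HHGateState",
    "LatencyResult",
    "steady_state",
    "hh_gate_timecourse",
    "propagate_epoch",
    "open_probability",
    "mean_activation_latency",
]


@dataclass(frozen=True)
class HHGateState:
    """Gate values (m, h) of an independent-gate scheme; h is None if q = 0."""

    m: float
    h: float | None = None


@dataclass(frozen=True)
class LatencyResult:
    """Mean activation latency of a chain at one voltage."""

    voltage: float  # mV
    delta: float  # ms
    contributions: tuple[float, ...]  # 1/alpha_i, ms

    def __post_init__(self) -> None:
        assert abs(self.delta - sum(self.contributions)) <= 1e-12 * max(1.0, self.delta)


def _gate_inf_tau(alpha: float, beta: float) -> tuple[float, float]:
    s = alpha + beta
    if s == 0.0:
        return np.nan, np.inf  # frozen gate
    return alpha / s, 1.0 / s


def steady_state(scheme, v: float):
    """Stationary state of a scheme at constant voltage ``v``.

    For HH schemes returns :class:`HHGateState` (m_inf, h_inf); for
    chains an :class:`OccupancyState` solving Q(v) p = 0.  Raises
    ``ValueError`` if the chain has no unique stationary distribution.
    """
    if isinstance(scheme, HHGatingScheme):
        m_inf, _ = _gate_inf_tau(scheme.alpha_m(v), scheme.beta_m(v))
        if np.isnan(m_inf):
            raise ValueError(f"activation gate has zero rates at V = {v} mV")
        h_inf = None
        if scheme.q:
            h_inf, _ = _gate_inf_tau(scheme.alpha_h(v), scheme.beta_h(v))
            if np.isnan(h_inf):
                raise ValueError(f"inactivation gate has zero rates at V = {v} mV")
        return HHGateState(m_inf, h_inf)
    q = scheme.generator(v)
    ns = null_space(q, rcond=1e-12)
    if ns.shape[1] != 1:
        raise ValueError(
            f"no unique stationary distribution at V = {v} mV "
            f"(null space dimension {ns.shape[1]}); scheme may be disconnected"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-10):
        raise ValueError("stationary solve produced negative occupancy")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return OccupancyState(p, scheme.labels)


def hh_gate_timecourse(alpha: float, beta: float, x0: float, duration: float,
                       dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic relaxation x(t) = x_inf - (x_inf - x0) e^(-t/tau) of one gate.

    Returns (t, x) sampled at ``dt`` from 0 to ``duration`` inclusive.
    With alpha = beta = 0 the gate is frozen at ``x0``.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("gate rates must be non-negative")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    x_inf, tau = _gate_inf_tau(alpha, beta)
    if np.isnan(x_inf):
        return t, np.full(n + 1, x0)
    x = x_inf - (x_inf - x0) * np.exp(-t / tau)
    return t, x


def propagate_epoch(scheme, v: float, p0, duration: float, dt: float,
                    method: str = "expm"):
    """Occupancy time course over one constant-voltage epoch.

    Parameters
    ----------
    scheme : HHGatingScheme or LinearChainScheme
    v : float
        Command voltage (mV), constant over the epoch.
    p0 : HHGateState or OccupancyState
        State at epoch onset.
    duration, dt : float
        Epoch length and sample interval (ms).  Samples run from t = 0
        to t = duration inclusive.
    method : {"expm", "fixed"}
        Exact matrix-exponential stepping (default) or fixed-step RK4 at
        ``dt``.  For HH schemes the analytic gate relaxation is used
        regardless (it is exact).

    Returns
    -------
    t : ndarray, shape (n+1,)
    states : for HH schemes a dict with keys "m" (and "h" when q > 0);
        for chains an ndarray of shape (n+1, n_states).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if isinstance(scheme, HHGatingScheme):
        t, m = hh_gate_timecourse(scheme.alpha_m(v), scheme.beta_m(v), p0.m,
                                  duration, dt)
        out = {"m": m}
        if scheme.q:
            _, h = hh_gate_timecourse(scheme.alpha_h(v), scheme.beta_h(v), p0.h,
                                      duration, dt)
            out["h"] = h
        return t, out

    q = scheme.generator(v)
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    p = np.empty((n + 1, q.shape[0]))
    p[0] = np.asarray(p0.probabilities if isinstance(p0, OccupancyState) else p0,
                      dtype=float)
    if method == "expm":
        step = expm(q * dt)
        for k in range(n):
            p[k + 1] = step @ p[k]
    elif method == "fixed":
        for k in range(n):
            y = p[k]
            k1 = q @ y
            k2 = q @ (y + 0.5 * dt * k1)
            k3 = q @ (y + 0.5 * dt * k2)
            k4 = q @ (y + dt * k3)
            p[k + 1] = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'expm' or 'fixed'")
    total = p.sum(axis=1)
    if np.any(np.abs(total - 1.0) > 1e-8):
        raise FloatingPointError("probability not conserved during propagation")
    return t, p


def open_probability(scheme, state):
    """Open probability of a scheme state (or a time course of states).

    Accepts the containers produced by :func:`steady_state` and
    :func:`propagate_epoch`.
    """
    if isinstance(scheme, HHGatingScheme):
        if isinstance(state, HHGateState):
            return float(scheme.open_probability(state.m, 1.0 if state.h is None
                                                 else state.h))
        return scheme.open_probability(state["m"], state.get("h", 1.0))
    if isinstance(state, OccupancyState):
        return float(state.probabilities[scheme.open_index])
    return scheme.open_probability(state)


def mean_activation_latency(scheme: LinearChainScheme, v: float) -> LatencyResult:
    """Mean latency delta(V) = sum_i 1/alpha_i(V) of a linear chain.

    Backward rates are neglected by construction: in the depolarized
    regime where the channel approaches maximal open probability the
    backward rate constants are much smaller than the forward ones, and
    delta is then the mean first-passage time from C_Nc to O.
    """
    if not isinstance(scheme, LinearChainScheme):
        raise TypeError("mean_activation_latency is defined for linear chains")
    contribs = []
    for i, rf in enumerate(scheme.forward):
        a = rf(v)
        if a <= 0:
            raise ValueError(
                f"forward rate {i} is non-positive at V = {v} mV: latency infinite"
            )
        contribs.append(1.0 / a)
    return LatencyResult(voltage=v, delta=float(sum(contribs)),
                         contributions=tuple(contribs))
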