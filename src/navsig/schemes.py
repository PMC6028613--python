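"""Channel gating schemes and the channel model container.

Two scheme families are supported:

* :class:`HHGatingScheme` — independent-gate (Hodgkin–Huxley style)
  kinetics with ``p`` identical activation gates and ``q`` inactivation
  gates; open probability m(t)^p * h(t)^q.
* :class:`LinearChainScheme` — a linear Markov chain of closed states
  terminating in a single open state,

      C_Nc <=> C_{Nc-1} <=> ... <=> C1 <=> O,

  optionally with inactivated states attached to chain states.  State
  ordering is fixed package-wide as ``C_Nc ... C1, O`` followed by the
  inactivated states in declaration order; the infinitesimal generator
  acts on column occupancy vectors (dp/dt = Q p) and has zero column
  sums, so total occupancy is conserved.

A :class:`ChannelModel` couples a scheme with a maximal conductance
(nS) and reversal potential (mV); the ensemble current is
I = g_max * P_open * (V - E_rev) in pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import RateFunction

__all__ = [
    "OccupancyState",
    "HHGatingScheme",
    "LinearChainScheme",
    "ChannelModel",
    "hh_sodium_model",
    "model_from_dict",
    "model_to_dict",
]


@dataclass
class OccupancyState:
    """Probability vector over the states of a Markov scheme."""

    probabilities: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.shape[0] != len(self.labels):
            raise ValueError("occupancy vector and labels disagree in length")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("occupancy entries must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancy must sum to 1, got {p.sum()!r}")
        self.probabilities = p

    def __getitem__(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])


@dataclass(frozen=True)
class HHGatingScheme:
    """Independent-gate kinetics: P_open = m^p * h^q.

    ``q = 0`` removes inactivation entirely (the gate h is absent, not
    merely frozen).
    """

    p: int
    q: int
    alpha_m: RateFunction
    beta_m: RateFunction
    alpha_h: RateFunction | None = None
    beta_h: RateFunction | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("activation gate power p must be a positive integer")
        if self.q < 0:
            raise ValueError("inactivation gate power q must be >= 0")
        if self.q > 0 and (self.alpha_h is None or self.beta_h is None):
            raise ValueError("q > 0 requires inactivation rate functions")

    @property
    def has_inactivation(self) -> bool:
        return self.q > 0

    def without_inactivation(self) -> "HHGatingScheme":
        """The same activation kinetics with the inactivation gate removed."""
        return HHGatingScheme(self.p, 0, self.alpha_m, self.beta_m)

    def open_probability(self, m, h=1.0):
        po = np.asarray(m, dtype=float) ** self.p
        if self.q:
            po = po * np.asarray(h, dtype=float) ** self.q
        return po

    def to_chain(self) -> "LinearChainScheme":
        """Binomial chain expansion of the activation gates (q must be 0).

        A single gate pool of ``p`` independent two-state gates is exactly
        equivalent to a (p+1)-state chain whose state k counts open gates:
        forward rate from k open gates is (p-k)*alpha_m, backward from
        k open gates is k*beta_m.
        """
        if self.q:
            raise ValueError("chain expansion is defined for q = 0 schemes")
        fw = []
        bw = []
        # chain index i runs over transitions C_{p-k} -> C_{p-k-1}; state
        # C_j has p - j open gates, O has all p open.
        for j in range(self.p, 0, -1):
            k_open = self.p - j
            fw.append(_scaled(self.alpha_m, self.p - k_open))
            bw.append(_scaled(self.beta_m, k_open + 1))
        return LinearChainScheme(forward=tuple(fw), backward=tuple(bw))


def _scaled(rf: RateFunction, factor: float) -> RateFunction:
    return RateFunction(rf.form, rf.rate * factor, rf.v_ref, rf.slope)


@dataclass(frozen=True)
class LinearChainScheme:
    """Linear activation chain C_Nc <=> ... <=> C1 <=> O.

    Parameters
    ----------
    forward, backward : tuple of RateFunction
        ``forward[i]`` is the rate of the i-th forward transition along
        the chain starting from the deepest closed state
        (C_Nc -> C_{Nc-1}, ..., C1 -> O); ``backward[i]`` the reverse.
    inactivation : tuple of (int, RateFunction, RateFunction)
        Each entry attaches an inactivated state to chain state
        ``source`` (0-based index into C_Nc..C1,O) with the given
        forward (into inactivation) and backward rates.
    """

    forward: tuple[RateFunction, ...]
    backward: tuple[RateFunction, ...]
    inactivation: tuple[tuple[int, RateFunction, RateFunction], ...] = ()

    def __post_init__(self) -> None:
        if len(self.forward) == 0:
            raise ValueError("a chain needs at least one transition")
        if len(self.forward) != len(self.backward):
            raise ValueError("forward and backward rate lists must have equal length")
        for src, _fw, _bw in self.inactivation:
            if not 0 <= src <= self.n_closed:
                raise ValueError(f"inactivation source index {src} out of range")

    @property
    def n_closed(self) -> int:
        return len(self.forward)

    @property
    def n_states(self) -> int:
        return self.n_closed + 1 + len(self.inactivation)

    @property
    def open_index(self) -> int:
        return self.n_closed

    @property
    def labels(self) -> tuple[str, ...]:
        closed = tuple(f"C{j}" for j in range(self.n_closed, 0, -1))
        inact = tuple(f"I{k + 1}" for k in range(len(self.inactivation)))
        return closed + ("O",) + inact

    @property
    def has_inactivation(self) -> bool:
        return len(self.inactivation) > 0

    def without_inactivation(self) -> "LinearChainScheme":
        """Delete the inactivated states and their transitions."""
        return LinearChainScheme(self.forward, self.backward)

    def generator(self, v: float) -> np.ndarray:
        """Infinitesimal generator Q(V) with dp/dt = Q p (zero column sums)."""
        n = self.n_states
        q = np.zeros((n, n))
        for i in range(self.n_closed):
            a = self.forward[i](v)
            b = self.backward[i](v)
            q[i + 1, i] += a
            q[i, i] -= a
            q[i, i + 1] += b
            q[i + 1, i + 1] -= b
        for k, (src, fw, bw) in enumerate(self.inactivation):
            j = self.n_closed + 1 + k
            a = fw(v)
            b = bw(v)
            q[j, src] += a
            q[src, src] -= a
            q[src, j] += b
            q[j, j] -= b
        if not np.all(np.isfinite(q)):
            raise FloatingPointError(f"non-finite rate in generator at V = {v} mV")
        return q

    def open_probability(self, occupancy) -> float | np.ndarray:
        p = np.asarray(occupancy, dtype=float)
        return p[..., self.open_index]


@dataclass(frozen=True)
class ChannelModel:
    """A conductance: gating scheme + maximal conductance + reversal potential."""

    scheme: HHGatingScheme | LinearChainScheme
    g_max: float  # nS
    e_rev: float  # mV
    name: str = "channel"

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")

    def current(self, p_open, v):
        """Instantaneous current in pA: g_max * P_open * (V - E_rev)."""
        return self.g_max * np.asarray(p_open, dtype=float) * (np.asarray(v) - self.e_rev)

    def without_inactivation(self) -> "ChannelModel":
        return ChannelModel(
            self.scheme.without_inactivation(),
            self.g_max,
            self.e_rev,
            name=f"{self.name}-noinact",
        )


def hh_sodium_model(g_max: float = 20.0, e_rev: float = 50.0) -> ChannelModel:
    """The built-in Hodgkin–Huxley sodium model (p = 3, q = 1).

    Rate functions are the classic squid-axon forms expressed on the
    modern membrane-potential scale (rest near -65 mV), in 1/ms:

        alpha_m = 0.1 (V + 40) / (1 - exp(-(V + 40)/10))
        beta_m  = 4 exp(-(V + 65)/18)
        alpha_h = 0.07 exp(-(V + 65)/20)
        beta_h  = 1 / (1 + exp(-(V + 35)/10))
    """
    scheme = HHGatingScheme(
        p=3,
        q=1,
        alpha_m=RateFunction("linoid", 0.1, -40.0, 10.0),
        beta_m=RateFunction("exponential", 4.0, -65.0, -18.0),
        alpha_h=RateFunction("exponential", 0.07, -65.0, -20.0),
        beta_h=RateFunction("sigmoid", 1.0, -35.0, 10.0),
    )
    return ChannelModel(scheme, g_max=g_max, e_rev=e_rev, name="hh-na")


# ---------------------------------------------------------------------------
# structured-config (de)serialization


def model_to_dict(model: ChannelModel) -> dict:
    s = model.scheme
    if isinstance(s, HHGatingScheme):
        scheme: dict = {
            "type": "hh",
            "p": s.p,
            "q": s.q,
            "alpha_m": s.alpha_m.to_dict(),
            "beta_m": s.beta_m.to_dict(),
        }
        if s.q:
            scheme["alpha_h"] = s.alpha_h.to_dict()
            scheme["beta_h"] = s.beta_h.to_dict()
    else:
        scheme = {
            "type": "chain",
            "forward": [r.to_dict() for r in s.forward],
            "backward": [r.to_dict() for r in s.backward],
        }
        if s.inactivation:
            scheme["inactivation"] = [
                {"source": src, "forward": fw.to_dict(), "backward": bw.to_dict()}
                for src, fw, bw in s.inactivation
            ]
    return {"name": model.name, "g_max": model.g_max, "e_rev": model.e_rev,
            "scheme": scheme}


def model_from_dict(d: dict) -> ChannelModel:
    """Build a ChannelModel from a nested config mapping.

    Unknown keys are rejected so that config typos never silently fall
    back to defaults.  This is also the loader hook for hand-translated
    literature Markov schemes expressed in the same format.
    """
    allowed = {"name", "g_max", "e_rev", "scheme"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    sd = dict(d["scheme"])
    stype = sd.pop("type", None)
    if stype == "hh":
        keys = {"p", "q", "alpha_m", "beta_m", "alpha_h", "beta_h"}
        unknown = set(sd) - keys
        if unknown:
            raise ValueError(f"unknown hh scheme keys: {sorted(unknown)}")
        scheme = HHGatingScheme(
            p=int(sd["p"]),
            q=int(sd.get("q", 0)),
            alpha_m=RateFunction.from_dict(sd["alpha_m"]),
            beta_m=RateFunction.from_dict(sd["beta_m"]),
            alpha_h=RateFunction.from_dict(sd["alpha_h"]) if "alpha_h" in sd else None,
            beta_h=RateFunction.from_dict(sd["beta_h"]) if "beta_h" in sd else None,
        )
    elif stype == "chain":
        keys = {"forward", "backward", "inactivation"}
        unknown = set(sd) - keys
        if unknown:
            raise ValueError(f"unknown chain scheme keys: {sorted(unknown)}")
        inact = tuple(
            (int(e["source"]), RateFunction.from_dict(e["forward"]),
             RateFunction.from_dict(e["backward"]))
            for e in sd.get("inactivation", [])
        )
        scheme = LinearChainScheme(
            forward=tuple(RateFunction.from_dict(r) for r in sd["forward"]),
            backward=tuple(RateFunction.from_dict(r) for r in sd["backward"]),
            inactivation=inact,
        )
    else:
        raise ValueError(f"unknown scheme type {stype!r}; expected 'hh' or 'chain'")
    return ChannelModel(scheme, g_max=float(d["g_max"]), e_rev=float(d["e_rev"]),
                        name=str(d.get("name", "channel")))
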