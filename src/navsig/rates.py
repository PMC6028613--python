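"""Voltage-dependent transition-rate functions.

All rates are expressed in 1/ms and voltages in mV, the package-wide
electrophysiology convention.  Four functional forms cover the rate laws
used by Hodgkin-Huxley-type gates and by linear Markov activation chains:

``constant``
    r(V) = r0
``exponential``
    r(V) = r0 * exp((V - v_ref) / slope)
``linoid``
    r(V) = r0 * (V - v_ref) / (1 - exp(-(V - v_ref) / slope))
    with the removable singularity at V = v_ref evaluated analytically
    (limit r0 * slope).
``sigmoid``
    r(V) = r0 / (1 + exp(-(V - v_ref) / slope))

For ``linoid`` the base rate carries units of 1/(ms*mV); for the other
forms it is 1/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RateFunction", "RATE_FORMS"]

RATE_FORMS = ("constant", "exponential", "linoid", "sigmoid")


@dataclass(frozen=True)
class RateFunction:
    """A voltage-dependent transition rate r(V).

    Parameters
    ----------
    form : str
        One of ``constant``, ``exponential``, ``linoid``, ``sigmoid``.
    rate : float
        Base rate r0 (1/ms; 1/(ms*mV) for the linoid form). Must be >= 0
        so that the rate is non-negative over the physiological voltage
        range.
    v_ref : float
        Reference voltage (mV). Ignored by the constant form.
    slope : float
        Slope factor (mV per e-fold). Must be nonzero for the
        voltage-dependent forms.
    """

    form: str
    rate: float
    v_ref: float = 0.0
    slope: float = 10.0

    def __post_init__(self) -> None:
        if self.form not in RATE_FORMS:
            raise ValueError(
                f"unknown rate form {self.form!r}; expected one of {RATE_FORMS}"
            )
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError(f"base rate must be finite and >= 0, got {self.rate}")
        if self.form != "constant" and self.slope == 0:
            raise ValueError("slope factor must be nonzero for voltage-dependent forms")

    def __call__(self, v):
        """Evaluate the rate (1/ms) at voltage ``v`` (mV; scalar or array)."""
        v = np.asarray(v, dtype=float)
        if self.form == "constant":
            out = np.broadcast_to(np.float64(self.rate), v.shape).copy()
        elif self.form == "exponential":
            out = self.rate * np.exp((v - self.v_ref) / self.slope)
        elif self.form == "sigmoid":
            out = self.rate / (1.0 + np.exp(-(v - self.v_ref) / self.slope))
        else:  # linoid
            x = (v - self.v_ref) / self.slope
            with np.errstate(over="ignore"):
                denom = -np.expm1(-x)
            small = np.abs(x) < 1e-9
            # x / (1 - e^-x) -> 1 as x -> 0
            ratio = np.where(small, 1.0 + np.asarray(x) / 2.0,
                             np.asarray(x) / np.where(small, 1.0, denom))
            out = self.rate * self.slope * ratio
        out = np.asarray(out, dtype=float)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(
                f"rate {self} is non-finite at some requested voltage"
            )
        if out.ndim == 0:
            return float(out)
        return out

    def to_dict(self) -> dict:
        d = {"form": self.form, "rate": self.rate}
        if self.form != "constant":
            d["v_ref"] = self.v_ref
            d["slope"] = self.slope
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateFunction":
        allowed = {"form", "rate", "v_ref", "slope"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown rate-function keys: {sorted(unknown)}")
        return cls(**d)
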