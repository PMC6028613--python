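"""Curve-fit models for sodium-current kinetics.

Three fitted quantities, each exposed statsmodels-style as a model
object whose ``fit()`` returns a results object with parameter
estimates, uncertainties and a ``summary()``:

* :class:`OnsetSigmoidicityModel` — the exponential-power onset fit

      I(t) = Imax * (1 - e^(-t/tau))^N

  applied to the early rise of a current (from the 50 us truncation
  boundary up to 50% of the peak magnitude).  N is the *apparent number
  of activation gates* (sigmoidicity): a continuous shape statistic
  that equals the gate count for independent-gate models and grows with
  the number of occupied closed states in sequential schemes — larger N
  means a more delayed, steeper onset (the Cole–Moore signature).

* :class:`ActivationCurveModel` — peak current versus test potential,
  a Boltzmann activation factor times the driving force:

      I/|Imax| = B * (V - E_rev) / (1 + e^(-(V - V1/2)/z))

* :class:`InactivationCurveModel` — channel availability versus
  pre-pulse potential, a decreasing Boltzmann function:

      I/I(-110) = 1 / (1 + e^((V - V1/2)/z))

Aggregation helpers (:func:`normalize_dataset`,
:func:`sigmoidicity_profile`) operate on multi-patch datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit

from .acquisition import PatchDataset
from .simulate import CurrentTrace

__all__ = [
    "onset_waveform",
    "activation_iv_curve",
    "boltzmann_availability",
    "measure_peak",
    "OnsetSigmoidicityModel",
    "OnsetFitResult",
    "ActivationCurveModel",
    "ActivationCurveResult",
    "InactivationCurveModel",
    "InactivationFitResult",
    "fit_onset_sigmoidicity",
    "fit_activation_iv",
    "fit_inactivation_boltzmann",
    "normalize_dataset",
    "sigmoidicity_profile",
]

TRUNCATION_DEFAULT = 0.05  # ms removed after the step before any fit
BASELINE_WINDOW = 1.0  # ms of pre-step current averaged as baseline


def onset_waveform(t, imax, tau, n):
    """Exponential-power rise Imax * (1 - e^(-t/tau))^N (magnitude)."""
    t = np.asarray(t, dtype=float)
    return imax * np.clip(-np.expm1(-t / tau), 0.0, None) ** n


def activation_iv_curve(v, b, e_rev, v_half, z):
    """Normalized peak current: B (V - E_rev) / (1 + e^(-(V - V1/2)/z))."""
    v = np.asarray(v, dtype=float)
    return b * (v - e_rev) / (1.0 + np.exp(-(v - v_half) / z))


def boltzmann_availability(v, v_half, z):
    """Steady-state availability: 1 / (1 + e^((V - V1/2)/z))."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v - v_half) / z))


# ---------------------------------------------------------------------------
# peak measurement


def _test_window(trace: CurrentTrace) -> slice:
    stop = trace.n_samples
    if trace.protocol is not None:
        dur = trace.protocol.epochs[trace.protocol.test_epoch][0]
        stop = min(stop, trace.onset_index + int(round(dur / trace.dt)) + 1)
    return slice(trace.onset_index, stop)


def baseline_current(trace: CurrentTrace) -> float:
    """Mean current over the last 1 ms before the test onset (0 if absent)."""
    n_pre = int(round(BASELINE_WINDOW / trace.dt))
    start = max(0, trace.onset_index - n_pre)
    if start >= trace.onset_index:
        return 0.0
    seg = trace.current[start:trace.onset_index]
    inc = trace.included_mask()[start:trace.onset_index]
    if not inc.any():
        return float(seg.mean())
    return float(seg[inc].mean())


def measure_peak(trace: CurrentTrace) -> tuple[float, float]:
    """Maximal baseline-subtracted current change over the test epoch.

    Returns ``(amplitude, time)`` with the amplitude signed (negative
    for inward currents) and the time in ms from the test onset.
    Excluded (truncated) samples never carry the peak.
    """
    win = _test_window(trace)
    y = trace.current[win] - baseline_current(trace)
    inc = trace.included_mask()[win]
    if not inc.any():
        raise ValueError("all samples in the test window are excluded")
    idx = np.flatnonzero(inc)
    k = idx[np.argmax(np.abs(y[idx]))]
    return float(y[k]), float(k * trace.dt)


# ---------------------------------------------------------------------------
# onset sigmoidicity fit


@dataclass
class OnsetFitResult:
    """Results of the exponential-power onset fit."""

    imax: float  # pA (magnitude of the fitted plateau)
    tau: float  # ms
    n: float  # apparent number of activation gates
    window: tuple[float, float]  # (start, end) ms from test onset
    residual_norm: float
    converged: bool
    fixed_n: bool
    bse: dict
    peak: float  # signed peak amplitude, pA
    n_points: int
    at_bound: bool = False  # a free parameter stuck at its box bound
    lmfit_result: lmfit.model.ModelResult | None = None

    @property
    def params(self) -> dict:
        return {"imax": self.imax, "tau": self.tau, "n": self.n}

    def predict(self, t):
        """Fitted onset magnitude at times ``t`` (ms from test onset)."""
        return onset_waveform(t, self.imax, self.tau, self.n)

    def summary(self) -> str:
        lines = [
            "Onset sigmoidicity fit: I = Imax (1 - exp(-t/tau))^N",
            f"  window       : {self.window[0]:.3f} .. {self.window[1]:.3f} ms "
            f"({self.n_points} samples)",
            f"  peak         : {self.peak:.1f} pA",
        ]
        for name in ("imax", "tau", "n"):
            se = self.bse.get(name)
            se_s = f" +/- {se:.3g}" if se is not None and np.isfinite(se) else ""
            fixed = " (fixed)" if name == "n" and self.fixed_n else ""
            lines.append(f"  {name:<13}: {getattr(self, name):.4g}{se_s}{fixed}")
        lines.append(f"  residual norm: {self.residual_norm:.4g}")
        lines.append(f"  converged    : {self.converged}")
        return "\n".join(lines)

    def plot(self, trace: CurrentTrace | None = None, ax=None):
        """Quick-look plot of the fitted rise (and the data if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        t = np.linspace(0, self.window[1] * 1.5, 200)
        ax.plot(t, np.sign(self.peak) * self.predict(t), "r-", label="fit")
        if trace is not None:
            tt = trace.time_from_onset
            sel = (tt >= 0) & (tt <= self.window[1] * 1.5)
            ax.plot(tt[sel], trace.current[sel] - baseline_current(trace),
                    "k.", ms=2, label="data")
        ax.set_xlabel("time from step (ms)")
        ax.set_ylabel("current (pA)")
        ax.legend()
        return ax


class OnsetSigmoidicityModel:
    """Fit the early rise of a current transient with Imax(1-e^(-t/tau))^N.

    The fit window runs from the truncation boundary (default 50 us
    after the test-step onset; any wider per-trace exclusion mask is
    honored) to the first sample whose baseline-subtracted magnitude
    reaches 50% of the peak magnitude, inclusive.  Time is physical time
    since the step, so the model stays anchored at the true onset even
    though the first samples are excluded from the residuals.

    Parameters
    ----------
    trace : CurrentTrace
    truncation : float, optional
        Fit-window start (ms from onset); defaults to 0.05 ms.
    rise_fraction : float
        Fraction of the peak magnitude defining the window end
        (default 0.5: only the initial rise is fitted, keeping the fit
        insensitive to inactivation).
    """

    min_points = 8

    def __init__(self, trace: CurrentTrace, truncation: float | None = None,
                 rise_fraction: float = 0.5):
        self.trace = trace
        self.truncation = TRUNCATION_DEFAULT if truncation is None else truncation
        if not 0 < rise_fraction <= 1:
            raise ValueError("rise_fraction must lie in (0, 1]")
        self.rise_fraction = rise_fraction

    def _window(self):
        trace = self.trace
        win = _test_window(trace)
        y = trace.current[win] - baseline_current(trace)
        a = np.abs(y)
        inc = trace.included_mask()[win]
        if not inc.any():
            raise ValueError("all samples in the test window are excluded")
        idx = np.flatnonzero(inc)
        k_peak = idx[np.argmax(a[idx])]
        peak = y[k_peak]
        if abs(peak) <= 0:
            raise ValueError("zero peak amplitude: nothing to fit")
        # window end: first sample reaching rise_fraction of the peak magnitude
        k_end = int(np.flatnonzero(a >= self.rise_fraction * abs(peak))[0])
        t_rel = np.arange(win.stop - win.start) * trace.dt
        in_fit = (t_rel >= self.truncation - 1e-12) & (np.arange(t_rel.size) <= k_end)
        in_fit &= inc
        if in_fit.sum() < self.min_points:
            raise ValueError(
                f"fit window holds {int(in_fit.sum())} samples; "
                f"at least {self.min_points} required"
            )
        # crude 10%-90%-free initializer: t10 -> t50 spread sets tau scale
        k10 = int(np.flatnonzero(a >= 0.1 * abs(peak))[0])
        tau0 = max(t_rel[k_end] - t_rel[k10], trace.dt)
        return t_rel[in_fit], a[in_fit], peak, (self.truncation, t_rel[k_end]), tau0

    def fit(self, fix_n: float | None = None) -> OnsetFitResult:
        """Nonlinear least squares; ``fix_n`` pins N (e.g. at 3)."""
        t, a, peak, window, tau0 = self._window()
        model = lmfit.Model(onset_waveform)
        params = model.make_params()
        params["imax"].set(value=2 * abs(peak), min=0.5 * abs(peak),
                           max=10 * abs(peak))
        params["tau"].set(value=tau0, min=self.trace.dt, max=100.0)
        if fix_n is None:
            params["n"].set(value=3.0, min=0.5, max=40.0)
        else:
            params["n"].set(value=float(fix_n), vary=False)
        res = model.fit(a, params, t=t)
        bse = {name: float(res.params[name].stderr
                           if res.params[name].stderr is not None else np.nan)
               for name in ("imax", "tau", "n")}
        # a free fit pinned to a parameter bound is flagged: it is a
        # constrained optimum, not a trustworthy shape estimate
        at_bound = any(
            p.vary and (np.isclose(p.value, p.min) or np.isclose(p.value, p.max))
            for p in (res.params[name] for name in ("imax", "tau", "n"))
        )
        return OnsetFitResult(
            imax=float(res.params["imax"].value),
            tau=float(res.params["tau"].value),
            n=float(res.params["n"].value),
            window=window,
            residual_norm=float(np.sqrt(np.sum(res.residual**2))),
            converged=bool(res.success),
            fixed_n=fix_n is not None,
            at_bound=at_bound,
            bse=bse,
            peak=float(peak),
            n_points=t.size,
            lmfit_result=res,
        )


def fit_onset_sigmoidicity(trace: CurrentTrace, fix_n: float | None = None,
                           truncation: float | None = None) -> OnsetFitResult:
    """Convenience wrapper around :class:`OnsetSigmoidicityModel`."""
    return OnsetSigmoidicityModel(trace, truncation=truncation).fit(fix_n=fix_n)


# ---------------------------------------------------------------------------
# activation I-V fit


@dataclass
class ActivationCurveResult:
    """Boltzmann-times-driving-force fit of the normalized I-V relation."""

    b: float  # 1/mV
    e_rev: float  # mV
    v_half: float  # mV
    z: float  # mV
    bse: dict
    residual_norm: float
    converged: bool
    degenerate: bool = False
    lmfit_result: lmfit.model.ModelResult | None = None

    @property
    def params(self) -> dict:
        return {"b": self.b, "e_rev": self.e_rev, "v_half": self.v_half,
                "z": self.z}

    def predict(self, v):
        return activation_iv_curve(v, self.b, self.e_rev, self.v_half, self.z)

    def summary(self) -> str:
        lines = ["Activation curve fit: I/|Imax| = B (V - E_rev) / "
                 "(1 + exp(-(V - V1/2)/z))"]
        units = {"b": "1/mV", "e_rev": "mV", "v_half": "mV", "z": "mV"}
        for name, val in self.params.items():
            se = self.bse.get(name)
            se_s = f" +/- {se:.3g}" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {name:<7}: {val:.4g}{se_s} {units[name]}")
        lines.append(f"  residual norm: {self.residual_norm:.4g}")
        lines.append(f"  converged: {self.converged}"
                     + ("  [degenerate data]" if self.degenerate else ""))
        return "\n".join(lines)


class ActivationCurveModel:
    """Fit normalized peak currents versus test potential.

    Expects currents already normalized per patch (conventionally to the
    magnitude of the -10 mV response) and averaged; see
    :func:`normalize_dataset`.
    """

    def __init__(self, voltages, currents):
        self.voltages = np.asarray(voltages, dtype=float)
        self.currents = np.asarray(currents, dtype=float)
        if self.voltages.size != self.currents.size:
            raise ValueError("voltages and currents must have equal length")
        if self.voltages.size < 5:
            raise ValueError("need at least 5 voltage points")
        if np.ptp(self.voltages) < 20:
            raise ValueError("voltage range too narrow to constrain the fit")

    def fit(self) -> ActivationCurveResult:
        v, i = self.voltages, self.currents
        if np.all(np.abs(i) < 1e-12):
            return ActivationCurveResult(
                b=0.0, e_rev=np.nan, v_half=np.nan, z=np.nan,
                bse={}, residual_norm=0.0, converged=False, degenerate=True)
        model = lmfit.Model(activation_iv_curve)
        params = model.make_params()
        k_min = int(np.argmin(i))  # largest inward response
        b0 = abs(i[k_min]) / max(abs(v[k_min] - 75.0), 1.0)
        params["b"].set(value=b0, min=1e-6, max=10.0)
        params["e_rev"].set(value=70.0, min=20.0, max=150.0)
        params["v_half"].set(value=float(v[k_min]) - 15.0, min=-90.0, max=20.0)
        params["z"].set(value=6.0, min=0.5, max=50.0)
        res = model.fit(i, params, v=v)
        bse = {n: float(res.params[n].stderr if res.params[n].stderr is not None
                        else np.nan) for n in ("b", "e_rev", "v_half", "z")}
        return ActivationCurveResult(
            b=float(res.params["b"].value),
            e_rev=float(res.params["e_rev"].value),
            v_half=float(res.params["v_half"].value),
            z=float(res.params["z"].value),
            bse=bse,
            residual_norm=float(np.sqrt(np.sum(res.residual**2))),
            converged=bool(res.success),
            lmfit_result=res,
        )


def fit_activation_iv(voltages, currents) -> ActivationCurveResult:
    """Convenience wrapper around :class:`ActivationCurveModel`."""
    return ActivationCurveModel(voltages, currents).fit()


# ---------------------------------------------------------------------------
# steady-state inactivation fit


@dataclass
class InactivationFitResult:
    """Boltzmann fit of steady-state availability."""

    v_half: float  # mV
    z: float  # mV
    bse: dict
    residual_norm: float
    converged: bool
    monotone: bool = True
    lmfit_result: lmfit.model.ModelResult | None = None

    @property
    def params(self) -> dict:
        return {"v_half": self.v_half, "z": self.z}

    def predict(self, v):
        return boltzmann_availability(v, self.v_half, self.z)

    def summary(self) -> str:
        lines = ["Steady-state inactivation fit: 1 / (1 + exp((V - V1/2)/z))"]
        for name, val in self.params.items():
            se = self.bse.get(name)
            se_s = f" +/- {se:.3g}" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {name:<7}: {val:.4g}{se_s} mV")
        lines.append(f"  residual norm: {self.residual_norm:.4g}")
        lines.append(f"  converged: {self.converged}"
                     + ("" if self.monotone else "  [non-monotone data]"))
        return "\n".join(lines)


class InactivationCurveModel:
    """Fit normalized availability versus pre-pulse potential.

    Expects peaks normalized per patch to the response following the
    most hyperpolarized (-110 mV) pre-pulse, so the curve runs from ~1
    to ~0 as the pre-pulse is depolarized.
    """

    def __init__(self, voltages, availability):
        self.voltages = np.asarray(voltages, dtype=float)
        self.availability = np.asarray(availability, dtype=float)
        if self.voltages.size != self.availability.size:
            raise ValueError("voltages and availability must have equal length")
        if self.voltages.size < 4:
            raise ValueError("need at least 4 pre-pulse points")

    def fit(self) -> InactivationFitResult:
        v, a = self.voltages, self.availability
        order = np.argsort(v)
        # gross monotonicity check: availability should fall with depolarization
        monotone = bool(np.polyfit(v[order], a[order], 1)[0] < 0)
        model = lmfit.Model(boltzmann_availability)
        params = model.make_params()
        k_half = int(np.argmin(np.abs(a - 0.5)))
        params["v_half"].set(value=float(v[k_half]), min=v.min() - 50,
                             max=v.max() + 50)
        params["z"].set(value=8.0, min=0.5, max=60.0)
        res = model.fit(a, params, v=v)
        bse = {n: float(res.params[n].stderr if res.params[n].stderr is not None
                        else np.nan) for n in ("v_half", "z")}
        return InactivationFitResult(
            v_half=float(res.params["v_half"].value),
            z=float(res.params["z"].value),
            bse=bse,
            residual_norm=float(np.sqrt(np.sum(res.residual**2))),
            converged=bool(res.success),
            monotone=monotone,
            lmfit_result=res,
        )


def fit_inactivation_boltzmann(voltages, availability) -> InactivationFitResult:
    """Convenience wrapper around :class:`InactivationCurveModel`."""
    return InactivationCurveModel(voltages, availability).fit()


# ---------------------------------------------------------------------------
# dataset-level aggregation


def normalize_dataset(dataset: PatchDataset, mode: str | None = None,
                      reference_voltage: float | None = None) -> pd.DataFrame:
    """Per-patch peak normalization and across-patch averaging.

    Activation mode divides each patch's peaks by the *magnitude* of
    that patch's response at the reference test potential (-10 mV by
    default), preserving sign, so the reference point sits at -1 for an
    inward current.  Inactivation mode divides by the signed peak
    following the most hyperpolarized reference pre-pulse (-110 mV by
    default), yielding availabilities near 1 at the reference.

    Returns a DataFrame indexed by condition voltage with one column
    per patch plus ``mean``, ``sem`` and ``n``.
    """
    mode = dataset.mode if mode is None else mode
    if mode not in ("activation", "inactivation"):
        raise ValueError("mode must be 'activation' or 'inactivation'")
    if reference_voltage is None:
        reference_voltage = -10.0 if mode == "activation" else -110.0

    cols = {}
    for i, patch in enumerate(dataset.traces):
        peaks = {}
        for tr in patch:
            if tr.condition_voltage is None:
                raise ValueError("trace lacks a condition voltage")
            peaks[float(tr.condition_voltage)] = measure_peak(tr)[0]
        ref = [v for v in peaks if np.isclose(v, reference_voltage)]
        if not ref:
            raise ValueError(
                f"patch {i} lacks the reference condition {reference_voltage} mV"
            )
        denom = peaks[ref[0]]
        if mode == "activation":
            denom = abs(denom)
        if denom == 0:
            raise ValueError(f"patch {i} has zero reference-peak amplitude")
        cols[i] = pd.Series({v: p / denom for v, p in peaks.items()})
    table = pd.DataFrame(cols).sort_index()
    table.index.name = "voltage"
    patch_cols = list(table.columns)
    table["mean"] = table[patch_cols].mean(axis=1)
    n = len(patch_cols)
    table["sem"] = (table[patch_cols].std(axis=1, ddof=1) / np.sqrt(n)
                    if n > 1 else 0.0)
    table["n"] = n
    return table


def _condition_of(trace: CurrentTrace, condition: str | None) -> float:
    if trace.condition_voltage is not None:
        return float(trace.condition_voltage)
    if trace.protocol is None:
        raise ValueError("trace has neither condition voltage nor protocol")
    if condition == "prepulse":
        return float(trace.protocol.epochs[trace.protocol.test_epoch - 1][1])
    return float(trace.protocol.test_voltage)


def sigmoidicity_profile(traces, condition: str | None = None,
                         fix_n: float | None = None,
                         truncation: float | None = None) -> pd.DataFrame:
    """Fitted sigmoidicity N (mean +/- SEM) per condition voltage.

    ``traces`` is a :class:`PatchDataset` or any iterable of
    :class:`CurrentTrace`.  ``condition`` selects the swept voltage
    ("test" or "prepulse") when traces do not carry one explicitly.
    Fits that fail or do not converge are excluded and counted in the
    ``n_failed`` column; a condition with no converged fit has NaN
    statistics.

    Returns a DataFrame with columns ``voltage``, ``n_mean``, ``n_sem``,
    ``tau_mean``, ``n_reps``, ``n_failed``.
    """
    if isinstance(traces, PatchDataset):
        if condition is None:
            condition = "test" if traces.mode == "activation" else "prepulse"
        items = [tr for _, tr in traces.iter_traces()]
    else:
        items = list(traces)

    by_v: dict[float, dict] = {}
    for tr in items:
        v = _condition_of(tr, condition)
        rec = by_v.setdefault(v, {"n": [], "tau": [], "failed": 0})
        try:
            fit = OnsetSigmoidicityModel(tr, truncation=truncation).fit(fix_n=fix_n)
        except ValueError:
            rec["failed"] += 1
            continue
        if not fit.converged or fit.at_bound:
            rec["failed"] += 1
            continue
        rec["n"].append(fit.n)
        rec["tau"].append(fit.tau)

    rows = []
    for v in sorted(by_v):
        ns = np.array(by_v[v]["n"])
        taus = np.array(by_v[v]["tau"])
        k = ns.size
        rows.append({
            "voltage": v,
            "n_mean": ns.mean() if k else np.nan,
            "n_sem": (ns.std(ddof=1) / np.sqrt(k)) if k > 1 else
                     (0.0 if k == 1 else np.nan),
            "tau_mean": taus.mean() if k else np.nan,
            "n_reps": k,
            "n_failed": by_v[v]["failed"],
        })
    return pd.DataFrame(rows)
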