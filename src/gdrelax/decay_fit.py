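"""Relaxation-model fitting for time-domain echo traces.

Models
------
SE  (single stretched exponential):   y = A exp[-(t/Tm)^beta]
SSE (sum of two stretched exponents): y = A exp[-(t/Tm_f)^beta_f]
                                          + (1-A) exp[-(t/Tm_s)^beta_s]
IR  (inversion recovery):             y = y0 - 2 A exp[-(t/T1)^s]

For Hahn-echo traces the time axis is the total evolution time 2*tau; traces
recorded versus tau are doubled on ingestion.  For echo trains, t is the time
from the first pi/2 pulse to the observed echo.

Model selection between SE and SSE uses the corrected Akaike criterion; the
two-component model is accepted only on strong evidence (delta AICc > 10).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

__all__ = [
    "DecayTrace",
    "SEFit",
    "SSEFit",
    "IRFit",
    "se_model",
    "sse_model",
    "ir_model",
    "fit_se",
    "fit_sse",
    "fit_inversion_recovery",
    "select_model",
    "ModelSelection",
    "FitError",
]

BETA_BOUNDS = (0.3, 3.5)
TM_BOUNDS_US = (0.1, 500.0)


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""


@dataclass
class DecayTrace:
    """Time/amplitude record with sequence and sample metadata.

    time_us is the *total evolution time* (2*tau for Hahn echoes, time from
    the first pulse for trains); strictly increasing, non-negative.
    """

    time_us: np.ndarray
    amplitude: np.ndarray
    sequence: str = "hahn"  # hahn | cpn | full_train | inversion_recovery
    temperature_K: Optional[float] = None
    concentration_uM: Optional[float] = None
    field_label: str = ""
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_us = np.asarray(self.time_us, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time_us.ndim != 1 or self.time_us.shape != self.amplitude.shape:
            raise ValueError("time and amplitude must be matching 1-d arrays")
        if len(self.time_us) < 8:
            raise ValueError("at least 8 points are required for any fit")
        if np.any(self.time_us < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.time_us) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)

    @classmethod
    def from_tau(cls, tau_us, amplitude, **kw):
        """Build a Hahn trace from a tau axis (evolution time = 2 tau)."""
        return cls(2.0 * np.asarray(tau_us, dtype=float), amplitude, **kw)


def se_model(t, A, Tm, beta):
    return A * np.exp(-((t / Tm) ** beta))


def sse_model(t, A, Tm_f, beta_f, Tm_s, beta_s):
    return A * np.exp(-((t / Tm_f) ** beta_f)) + (1.0 - A) * np.exp(
        -((t / Tm_s) ** beta_s)
    )


def ir_model(t, y0, A, T1, stretch):
    return y0 - 2.0 * A * np.exp(-((t / T1) ** stretch))


@dataclass
class SEFit:
    A: float
    Tm: float
    beta: float
    A_err: float
    Tm_err: float
    beta_err: float
    ssq: float
    redchi: float
    n: int
    aicc: float

    @property
    def nvarys(self):
        return 3

    def evaluate(self, t):
        return se_model(np.asarray(t, float), self.A, self.Tm, self.beta)


@dataclass
class SSEFit:
    A: float  # fast fraction in [0, 1]
    Tm_f: float
    beta_f: float
    Tm_s: float
    beta_s: float
    amplitude: float
    A_err: float
    Tm_f_err: float
    beta_f_err: float
    Tm_s_err: float
    beta_s_err: float
    ssq: float
    redchi: float
    n: int
    aicc: float
    effectively_se: bool = False

    @property
    def nvarys(self):
        return 6

    def evaluate(self, t):
        return self.amplitude * sse_model(
            np.asarray(t, float), self.A, self.Tm_f, self.beta_f, self.Tm_s, self.beta_s
        )


@dataclass
class IRFit:
    T1: float
    stretch: float
    A: float
    y0: float
    T1_err: float
    stretch_err: float
    ssq: float
    n: int
    low_confidence: bool = False

    def evaluate(self, t):
        return ir_model(np.asarray(t, float), self.y0, self.A, self.T1, self.stretch)


def _aicc(ssq: float, n: int, k: int) -> float:
    ssq = max(ssq, 1e-300)
    aic = n * np.log(ssq / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _weights(trace: DecayTrace):
    if trace.sigma is not None:
        return 1.0 / np.clip(trace.sigma, 1e-12, None)
    return None


def _minimize(params, resid, starts, diagnostics):
    """Run lmfit over a list of start dicts; return the best result."""
    best = None
    for start in starts:
        p = params.copy()
        for k, v in start.items():
            lo, hi = p[k].min, p[k].max
            p[k].value = float(np.clip(v, lo, hi))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lmfit.minimize(resid, p, method="leastsq", nan_policy="omit")
        except Exception as exc:  # pragma: no cover - optimizer hiccups
            diagnostics.append(f"start {start}: {exc}")
            continue
        if not np.isfinite(res.chisqr):
            diagnostics.append(f"start {start}: non-finite chisqr")
            continue
        if best is None or res.chisqr < best.chisqr - 1e-15 * abs(best.chisqr):
            best = res
    return best


def _tm_starts(t):
    """Five log-spaced Tm initials spanning the observed time range."""
    t_max = t[-1]
    t_min = max(t[1], t_max / 200.0)
    return np.geomspace(max(t_min, 0.11), min(t_max, 499.0), 5)


def fit_se(trace: DecayTrace) -> SEFit:
    """Fit the single stretched exponential to a decay trace.

    Multi-start over 5 log-spaced Tm initials x 3 beta initials; the best
    sum-of-squares wins.  Uncertainties are covariance-derived.
    """
    t, y = trace.time_us, trace.amplitude
    w = _weights(trace)
    scale = max(abs(y).max(), 1e-30)

    params = lmfit.Parameters()
    params.add("A", value=scale, min=0.0, max=10.0 * scale)
    params.add("Tm", value=1.0, min=TM_BOUNDS_US[0], max=TM_BOUNDS_US[1])
    params.add("beta", value=1.0, min=BETA_BOUNDS[0], max=BETA_BOUNDS[1])

    def resid(p):
        r = se_model(t, p["A"], p["Tm"], p["beta"]) - y
        return r * w if w is not None else r

    diagnostics: list[str] = []
    starts = [
        {"Tm": tm, "beta": b}
        for tm, b in itertools.product(_tm_starts(t), (0.7, 1.0, 1.8))
    ]
    best = _minimize(params, resid, starts, diagnostics)
    if best is None:
        raise FitError("SE fit failed for all starts: " + "; ".join(diagnostics))

    def err(name):
        p = best.params[name]
        return float(p.stderr) if p.stderr is not None else float("nan")

    ssq = float(np.sum(np.square(se_model(t, *[best.params[k].value for k in ("A", "Tm", "beta")]) - y)))
    return SEFit(
        A=float(best.params["A"].value),
        Tm=float(best.params["Tm"].value),
        beta=float(best.params["beta"].value),
        A_err=err("A"),
        Tm_err=err("Tm"),
        beta_err=err("beta"),
        ssq=ssq,
        redchi=float(best.redchi),
        n=len(t),
        aicc=_aicc(ssq, len(t), 3),
    )


def fit_sse(trace: DecayTrace) -> SSEFit:
    """Fit the sum of two stretched exponentials (bounded, multi-start).

    Components are relabelled after the fit so that Tm_f < Tm_s; ties in
    sum-of-squares between starts are broken towards the smaller Tm_s.
    A fast fraction pinned near 0 or 1 is flagged ``effectively_se``.
    """
    t, y = trace.time_us, trace.amplitude
    if len(t) < 12:
        raise ValueError("SSE fit requires at least 12 points")
    w = _weights(trace)
    scale = max(abs(y).max(), 1e-30)

    params = lmfit.Parameters()
    params.add("amp", value=scale, min=0.0, max=10.0 * scale)
    params.add("A", value=0.3, min=0.0, max=1.0)
    params.add("Tm_f", value=1.0, min=TM_BOUNDS_US[0], max=TM_BOUNDS_US[1])
    params.add("beta_f", value=1.8, min=BETA_BOUNDS[0], max=BETA_BOUNDS[1])
    params.add("Tm_s", value=10.0, min=TM_BOUNDS_US[0], max=TM_BOUNDS_US[1])
    params.add("beta_s", value=0.8, min=BETA_BOUNDS[0], max=BETA_BOUNDS[1])

    def resid(p):
        r = p["amp"] * sse_model(t, p["A"], p["Tm_f"], p["beta_f"], p["Tm_s"], p["beta_s"]) - y
        return r * w if w is not None else r

    tms = _tm_starts(t)
    starts = []
    for tm_f, tm_s in itertools.product(tms[:3], tms[2:]):
        if tm_s <= tm_f:
            continue
        for bf, bs in ((1.8, 0.8), (1.0, 1.0)):
            starts.append(
                {"Tm_f": tm_f, "Tm_s": tm_s, "beta_f": bf, "beta_s": bs, "A": 0.3}
            )
    diagnostics: list[str] = []
    best = _minimize(params, resid, starts, diagnostics)
    if best is None:
        raise FitError("SSE fit failed for all starts: " + "; ".join(diagnostics))

    v = {k: float(best.params[k].value) for k in best.params}
    e = {
        k: (float(best.params[k].stderr) if best.params[k].stderr is not None else float("nan"))
        for k in best.params
    }
    if v["Tm_f"] > v["Tm_s"]:  # relabel so the fast component is first
        v["Tm_f"], v["Tm_s"] = v["Tm_s"], v["Tm_f"]
        v["beta_f"], v["beta_s"] = v["beta_s"], v["beta_f"]
        e["Tm_f"], e["Tm_s"] = e["Tm_s"], e["Tm_f"]
        e["beta_f"], e["beta_s"] = e["beta_s"], e["beta_f"]
        v["A"] = 1.0 - v["A"]

    ssq = float(
        np.sum(
            np.square(
                v["amp"] * sse_model(t, v["A"], v["Tm_f"], v["beta_f"], v["Tm_s"], v["beta_s"]) - y
            )
        )
    )
    return SSEFit(
        A=v["A"],
        Tm_f=v["Tm_f"],
        beta_f=v["beta_f"],
        Tm_s=v["Tm_s"],
        beta_s=v["beta_s"],
        amplitude=v["amp"],
        A_err=e["A"],
        Tm_f_err=e["Tm_f"],
        beta_f_err=e["beta_f"],
        Tm_s_err=e["Tm_s"],
        beta_s_err=e["beta_s"],
        ssq=ssq,
        redchi=float(best.redchi),
        n=len(t),
        aicc=_aicc(ssq, len(t), 6),
        effectively_se=(v["A"] < 0.02 or v["A"] > 0.98),
    )


@dataclass
class ModelSelection:
    chosen: str  # "SE" | "SSE"
    delta_aicc: float  # AICc(SE) - AICc(SSE); > threshold selects SSE
    threshold: float
    se: SEFit
    sse: SSEFit


def select_model(trace: DecayTrace, threshold: float = 10.0) -> ModelSelection:
    """Fit both SE and SSE and choose by corrected AIC.

    The two-component model is selected only on strong evidence
    (AICc improvement larger than ``threshold``) and only if it did not
    collapse onto a single component.
    """
    se = fit_se(trace)
    sse = fit_sse(trace)
    delta = se.aicc - sse.aicc
    chosen = "SSE" if (delta > threshold and not sse.effectively_se) else "SE"
    return ModelSelection(chosen=chosen, delta_aicc=float(delta), threshold=threshold, se=se, sse=sse)


def fit_inversion_recovery(trace: DecayTrace) -> IRFit:
    """Fit y = y0 - 2 A exp[-(t/T1)^s] to an inversion-recovery trace.

    The fit is flagged ``low_confidence`` when the trace does not span the
    recovery (relative T1 uncertainty above 10 % or span < 2 T1).
    """
    t, y = trace.time_us, trace.amplitude
    w = _weights(trace)
    scale = max(abs(y).max(), 1e-30)

    params = lmfit.Parameters()
    params.add("y0", value=float(y[-1]), min=-10 * scale, max=10 * scale)
    params.add("A", value=scale, min=0.0, max=10 * scale)
    params.add("T1", value=max(t[-1] / 3.0, 0.1), min=1e-3, max=1e4)
    params.add("stretch", value=0.8, min=0.05, max=2.0)

    def resid(p):
        r = ir_model(t, p["y0"], p["A"], p["T1"], p["stretch"]) - y
        return r * w if w is not None else r

    diagnostics: list[str] = []
    starts = [
        {"T1": t1, "stretch": s0}
        for t1 in np.geomspace(max(t[1], t[-1] / 100.0), t[-1], 4)
        for s0 in (0.75, 1.0)
    ]
    best = _minimize(params, resid, starts, diagnostics)
    if best is None:
        raise FitError("IR fit failed for all starts: " + "; ".join(diagnostics))

    T1 = float(best.params["T1"].value)
    T1_err = best.params["T1"].stderr
    T1_err = float(T1_err) if T1_err is not None else float("nan")
    s_err = best.params["stretch"].stderr
    ssq = float(best.chisqr) if w is None else float(
        np.sum(np.square(resid(best.params) / w))
    )
    low_conf = (not np.isfinite(T1_err)) or (T1_err / T1 > 0.10) or (t[-1] < 2.0 * T1)
    return IRFit(
        T1=T1,
        stretch=float(best.params["stretch"].value),
        A=float(best.params["A"].value),
        y0=float(best.params["y0"].value),
        T1_err=T1_err,
        stretch_err=float(s_err) if s_err is not None else float("nan"),
        ssq=ssq,
        n=len(t),
        low_confidence=bool(low_conf),
    )
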