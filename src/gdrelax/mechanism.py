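"""Decoherence-mechanism decomposition for Gd(III) phase relaxation.

The measured Hahn-echo rate 1/Tm at a given temperature is modelled as a sum
of mechanism contributions:

* direct spin-lattice relaxation of the observed (A) spins, bounded by
  1/Tm <= ... with the ceiling Tm = 2 T1, contributing 1/(2 T1);
* instantaneous diffusion (ID): microwave-pulse-driven redistribution of
  dipolar fields among excited A spins, strictly linear in concentration;
* indirect-T1 spectral diffusion (SD-T1): T1 flips of non-excited B spins
  modulate the dipolar field at the A spin, linear in concentration in the
  dilute regime;
* a concentration-independent residuum (transient-ZFS fluctuations and
  residual nuclear spin diffusion), obtained by elimination.

The concentration series 1/Tm = slope * C + intercept separates the
concentration-dependent mechanisms (slope) from Tm(0) = 1/intercept.

Rate models
-----------
Both dipolar rate predictions share the statistical (dilute-bath) Lorentzian
dipolar width  Delta_omega_1/2 = A_dd * C  with
A_dd = (4 pi^2 / 9 sqrt3) (mu0/4pi) g^2 mu_B^2 / hbar  per unit spin density.

Instantaneous diffusion:  1/T_ID = A_dd * C * <sin^2(theta_2/2)>, the classic
excitation-fraction-weighted form.

Indirect-T1 spectral diffusion:  1/T_SD,T1 = A_dd * C * p_flip * eta, where
p_flip = f_eq * [1 - exp(-t_obs/T1)] is the probability that a B spin has
left its initial level during the echo observation window t_obs (f_eq is the
equilibrium probability of being found away from the initial level: 2S/(2S+1)
for a high-spin bath, 1/2 for S=1/2) and eta = 1/2 is the mean loss of
refocusing caused by a single flip at a random time within the sequence.
All prefactors are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import G_GD_DEFAULT, dipolar_rate_constant

__all__ = [
    "ConcentrationSeries",
    "MechanismDecomposition",
    "GuideCurve",
    "LinearCorrelation",
    "fit_concentration",
    "guide_eval",
    "t1_correlation",
    "predict_sd_t1",
    "predict_id",
]

#: Default echo observation window (µs) entering the B-spin flip probability:
#: the full extent 2*tau_max over which the Hahn decays are recorded,
#: comparable to twice the zero-concentration phase memory time.
DEFAULT_OBSERVATION_WINDOW_US = 40.0


@dataclass
class ConcentrationSeries:
    """(concentration, Tm) entries at fixed temperature and field position."""

    concentration_uM: np.ndarray
    Tm_us: np.ndarray
    Tm_err_us: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    beta_err: Optional[np.ndarray] = None
    label: str = ""
    temperature_K: Optional[float] = None
    field_label: str = ""

    def __post_init__(self):
        self.concentration_uM = np.asarray(self.concentration_uM, dtype=float)
        self.Tm_us = np.asarray(self.Tm_us, dtype=float)
        if np.any(self.concentration_uM <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(self.concentration_uM)) != len(self.concentration_uM):
            raise ValueError("concentrations must be distinct")
        if self.Tm_err_us is not None:
            self.Tm_err_us = np.asarray(self.Tm_err_us, dtype=float)


@dataclass
class MechanismDecomposition:
    """Linear concentration fit of 1/Tm plus a named rate budget (µs^-1)."""

    slope: float  # µs^-1 µM^-1
    slope_err: float
    intercept: float  # µs^-1
    intercept_err: float
    Tm0_us: float
    Tm0_err_us: float
    budget: dict = field(default_factory=dict)

    def decompose(
        self,
        concentration_uM: float = 0.0,
        T1_us: Optional[float] = None,
        id_rate: float = 0.0,
    ) -> dict:
        """Assign the fitted rates to named mechanisms at a concentration.

        direct_T1 = 1/(2 T1) if T1 is known; SD_T1 = slope * C - ID;
        residual = intercept - direct_T1 (tZFS + residual NSD, by
        elimination).  Entries are clipped at zero.
        """
        direct = 1.0 / (2.0 * T1_us) if T1_us else 0.0
        sd = max(self.slope * concentration_uM - id_rate, 0.0)
        budget = {
            "direct_T1": direct,
            "SD_T1": sd,
            "ID": id_rate,
            "residual": max(self.intercept - direct, 0.0),
        }
        self.budget = budget
        return budget


def fit_concentration(series: ConcentrationSeries) -> MechanismDecomposition:
    """Weighted linear least squares of 1/Tm versus concentration.

    Weights follow from the propagated Tm uncertainties
    (sigma_rate = Tm_err / Tm^2) when supplied, else ordinary least squares.
    Tm(0) is the reciprocal intercept with first-order error propagation.
    """
    c = series.concentration_uM
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations")
    if np.ptp(c) == 0:
        raise ValueError("singular design: all concentrations equal")
    rate = 1.0 / series.Tm_us
    if series.Tm_err_us is not None:
        sig = series.Tm_err_us / series.Tm_us**2
        w = 1.0 / np.clip(sig, 1e-15, None) ** 2
    else:
        w = np.ones_like(rate)

    # weighted normal equations for y = a*C + b
    W = w.sum()
    cbar = (w * c).sum() / W
    ybar = (w * rate).sum() / W
    sxx = (w * (c - cbar) ** 2).sum()
    slope = (w * (c - cbar) * (rate - ybar)).sum() / sxx
    intercept = ybar - slope * cbar

    resid = rate - (slope * c + intercept)
    dof = len(c) - 2
    if series.Tm_err_us is not None:
        # scale covariance by reduced chi^2 only if > 1 (conservative)
        chi2 = float((w * resid**2).sum())
        s2 = max(chi2 / dof, 1.0) if dof > 0 else 1.0
    else:
        s2 = float((resid**2).sum() / dof) if dof > 0 else 0.0
    slope_var = s2 / sxx
    intercept_var = s2 * (1.0 / W + cbar**2 / sxx)

    tm0 = 1.0 / intercept
    tm0_err = np.sqrt(intercept_var) / intercept**2
    return MechanismDecomposition(
        slope=float(slope),
        slope_err=float(np.sqrt(slope_var)),
        intercept=float(intercept),
        intercept_err=float(np.sqrt(intercept_var)),
        Tm0_us=float(tm0),
        Tm0_err_us=float(tm0_err),
    )


@dataclass(frozen=True)
class GuideCurve:
    """Saturating exponential y = y0 + A exp(-C/T) used to summarize the
    concentration dependence of the stretch exponent beta."""

    y0: float
    A: float
    T_uM: float

    def __post_init__(self):
        if self.T_uM <= 0:
            raise ValueError("T must be positive")


def guide_eval(curve: GuideCurve, concentration_uM) -> np.ndarray | float:
    """Evaluate the guide curve at the given concentration(s)."""
    c = np.asarray(concentration_uM, dtype=float)
    out = curve.y0 + curve.A * np.exp(-c / curve.T_uM)
    return float(out) if out.ndim == 0 else out


@dataclass
class LinearCorrelation:
    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    r2: float
    n: int
    nonlinear: bool


def t1_correlation(
    pairs: Sequence[tuple[float, float]],
    temperatures_K: Optional[Sequence[float]] = None,
    window_K: Optional[tuple[float, float]] = None,
    r2_threshold: float = 0.98,
) -> LinearCorrelation:
    """Linear fit of 1/Tm versus 1/T1 with a linearity diagnostic.

    ``pairs`` holds (1/T1, 1/Tm) in µs^-1.  If temperatures are given,
    ``window_K`` restricts the fit to that temperature range (used to exclude
    the low-temperature plateau where 1/Tm no longer follows T1).  The fit is
    flagged ``nonlinear`` when R^2 falls below ``r2_threshold`` or when the
    slopes fitted separately on the lower and upper halves of the 1/T1 range
    disagree by more than 30 % of the global slope (the plateau spans only a
    small part of the 1/T1 range, so R^2 alone can miss it).
    """
    arr = np.asarray(pairs, dtype=float)
    if temperatures_K is not None and window_K is not None:
        temp = np.asarray(temperatures_K, dtype=float)
        mask = (temp >= window_K[0]) & (temp <= window_K[1])
        arr = arr[mask]
    if len(arr) < 3:
        raise ValueError("need at least 3 pairs in the window")
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)

    def line(xv, yv):
        xb, yb = xv.mean(), yv.mean()
        sxx_ = ((xv - xb) ** 2).sum()
        if sxx_ == 0:
            return None, None, 0.0
        sl = ((xv - xb) * (yv - yb)).sum() / sxx_
        return sl, yb - sl * xb, sxx_

    slope, intercept, sxx = line(x, y)
    if slope is None:
        raise ValueError("degenerate 1/T1 values")
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    s2 = ss_res / (n - 2) if n > 2 else 0.0

    nonlinear = bool(r2 < r2_threshold)
    half = np.median(x)
    lo, hi = x <= half, x > half
    if lo.sum() >= 3 and hi.sum() >= 3:
        sl_lo, _, _ = line(x[lo], y[lo])
        sl_hi, _, _ = line(x[hi], y[hi])
        if sl_lo is not None and sl_hi is not None:
            scale = max(abs(slope), 1e-15)
            if abs(sl_hi - sl_lo) > 0.3 * scale and ss_tot > 0:
                nonlinear = True
    return LinearCorrelation(
        slope=float(slope),
        intercept=float(intercept),
        slope_err=float(np.sqrt(s2 / sxx)),
        intercept_err=float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))),
        r2=float(r2),
        n=n,
        nonlinear=nonlinear,
    )


def predict_sd_t1(
    concentration_uM,
    T1_us: float,
    spin: float = 3.5,
    g: float = G_GD_DEFAULT,
    observation_window_us: float = DEFAULT_OBSERVATION_WINDOW_US,
    high_spin_bath: bool = True,
    flip_efficiency: float = 0.5,
) -> np.ndarray | float:
    """Predicted indirect-T1 spectral-diffusion rate 1/T_SD,T1 (µs^-1).

    1/T_SD,T1 = A_dd * C * f_eq * [1 - exp(-t_obs/T1)] * eta, linear in C.
    ``high_spin_bath`` selects f_eq = 2S/(2S+1) (all 2S+1 B-spin levels are
    thermally populated, so nearly every T1 event moves the spin to a new
    level); with ``high_spin_bath=False`` f_eq = 1/2 as for an S=1/2 bath.
    The per-µM slope is ``predict_sd_t1(1.0, ...)``.
    """
    if T1_us <= 0:
        raise ValueError("T1 must be positive")
    c = np.asarray(concentration_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    f_eq = (2.0 * spin) / (2.0 * spin + 1.0) if high_spin_bath else 0.5
    p_flip = f_eq * (1.0 - np.exp(-observation_window_us / T1_us))
    out = dipolar_rate_constant(g) * c * p_flip * flip_efficiency
    return float(out) if out.ndim == 0 else out


def predict_id(
    concentration_uM,
    mean_sin2_half_turn: float,
    g: float = G_GD_DEFAULT,
) -> np.ndarray | float:
    """Instantaneous-diffusion rate 1/T_ID = A_dd * C * <sin^2(theta_2/2)>.

    ``mean_sin2_half_turn`` is the excitation-fraction-weighted mean
    sin^2(theta_2/2) over the EPR line; for the narrow central transition of
    a broad Gd(III) spectrum it is small (<~0.1), which makes ID negligible
    next to the indirect-T1 spectral diffusion.
    """
    if not 0.0 <= mean_sin2_half_turn <= 1.0:
        raise ValueError("mean_sin2_half_turn must lie in [0, 1]")
    c = np.asarray(concentration_uM, dtype=float)
    out = dipolar_rate_constant(g) * c * mean_sin2_half_turn
    return float(out) if out.ndim == 0 else out
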