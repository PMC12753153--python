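"""Pulse-sequence simulation for a two-level (central-transition) subspace.

The observed Gd(III) central transition is propagated as an ensemble of
two-level spins in the rotating frame.  Each spin packet carries a resonance
offset drawn from a configurable ensemble; microwave pulses act as exact
rotations about the tilted effective field (so finite pulse bandwidth and the
resulting selectivity are captured), and Bloch relaxation (T1 longitudinal,
T2 transverse, optionally a stretched transverse kernel) acts during the free
delays.  Relaxation during the 15-30 ns pulses is neglected (pulses are three
orders of magnitude shorter than T2).  Because the full magnetization vector
is propagated, every coherence pathway - including the T1-stored
stimulated-echo pathways that contaminate Carr-Purcell echoes recorded with
selective pulses - is carried implicitly.

Also provided: phase cycling, the stimulated-echo Tm-bias experiment, the
Mims-ENDOR blind-spot response, powder ENDOR doublets, and point-dipole
electron-proton distances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence as Seq

import numpy as np

from .constants import G_ELECTRON, electron_proton_dipolar_constant
from .decay_fit import DecayTrace, select_model, SEFit

__all__ = [
    "Pulse",
    "PulseSequence",
    "RelaxationParams",
    "OffsetEnsemble",
    "EchoTrain",
    "HyperfineCoupling",
    "propagate",
    "phase_cycle",
    "cpn_phase_cycle",
    "train_phase_cycle",
    "load_phase_cycle",
    "stimulated_echo_bias",
    "StimulatedEchoBias",
    "mims_efficiency",
    "endor_spectrum",
    "dipole_distance",
    "dipole_coupling",
    "analytic_hahn_amplitude",
    "analytic_stimulated_amplitude",
]

_TWO_PI_MHZ_TO_RAD_PER_NS = 2.0 * math.pi * 1e-3


@dataclass(frozen=True)
class Pulse:
    """Rectangular microwave pulse.

    ``flip_rad`` is the nominal on-resonance flip angle; the field strength
    follows as omega_1 = flip / duration.  ``duration_ns = 0`` denotes an
    ideal (infinite-bandwidth) pulse.
    """

    duration_ns: float
    flip_rad: float
    phase_rad: float = 0.0

    def __post_init__(self):
        if self.duration_ns < 0:
            raise ValueError("pulse duration must be >= 0")

    @property
    def omega1_rad_per_ns(self) -> float:
        if self.duration_ns == 0:
            return math.inf
        return self.flip_rad / self.duration_ns

    def with_phase(self, phase_rad: float) -> "Pulse":
        return Pulse(self.duration_ns, self.flip_rad, phase_rad)


@dataclass
class RelaxationParams:
    """Bloch relaxation times (µs) with an optional stretched transverse
    kernel exp[-(t/T2)^stretch] accumulated over the transverse intervals."""

    T1_us: float
    T2_us: float
    stretch: float = 1.0

    def __post_init__(self):
        if self.T1_us <= 0 or self.T2_us <= 0:
            raise ValueError("relaxation times must be positive")
        if self.T2_us > 2.0 * self.T1_us + 1e-12:
            raise ValueError("T2 must not exceed 2*T1")


@dataclass
class OffsetEnsemble:
    """Resonance-offset distribution of the spin packets (MHz).

    Either a Gaussian spec (sigma_MHz, n_samples, seed) sampled
    reproducibly, or explicit offsets with optional weights.
    """

    sigma_MHz: float = 0.0
    n_samples: int = 1
    seed: int = 0
    offsets_MHz: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.offsets_MHz is None and self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @classmethod
    def gaussian(cls, sigma_MHz: float, n_samples: int, seed: int) -> "OffsetEnsemble":
        return cls(sigma_MHz=sigma_MHz, n_samples=n_samples, seed=seed)

    @classmethod
    def explicit(cls, offsets_MHz, weights=None) -> "OffsetEnsemble":
        return cls(
            offsets_MHz=np.asarray(offsets_MHz, dtype=float),
            weights=None if weights is None else np.asarray(weights, dtype=float),
        )

    def sample(self) -> tuple[np.ndarray, np.ndarray]:
        if self.offsets_MHz is not None:
            off = self.offsets_MHz
            w = self.weights if self.weights is not None else np.ones_like(off)
        else:
            rng = np.random.default_rng(self.seed)
            off = rng.normal(0.0, self.sigma_MHz, self.n_samples)
            w = np.ones_like(off)
        return off, w / w.sum()


@dataclass
class EchoTrain:
    """Echo times (µs from the first pulse) and ensemble-averaged amplitudes."""

    time_us: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self):
        self.time_us = np.asarray(self.time_us, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(np.diff(self.time_us) <= 0):
            raise ValueError("echo times must be increasing")

    def to_trace(self, **meta) -> DecayTrace:
        return DecayTrace(self.time_us, self.amplitude, **meta)


@dataclass
class PulseSequence:
    """Ordered pulses, delays (ns) and point-detection events.

    ``events`` items: ("pulse", Pulse), ("delay", t_ns) or ("detect", sign)
    where sign is the expected echo polarity (+/-1); detected signals are
    multiplied by it so that an ideal refocused echo reads +1.
    """

    events: list = field(default_factory=list)
    n_refocus: int = 0
    tau_ns: float = 0.0
    name: str = ""

    def __post_init__(self):
        prev = None
        for ev in self.events:
            kind = ev[0]
            if kind == "delay" and ev[1] < 0:
                raise ValueError("delays must be >= 0")
            if kind == "detect" and prev == "pulse":
                raise ValueError("detection window overlaps a pulse")
            prev = kind

    @property
    def pulses(self) -> list[Pulse]:
        return [ev[1] for ev in self.events if ev[0] == "pulse"]

    def with_pulse_phases(self, extra_phase: dict[int, float]) -> "PulseSequence":
        """Copy of the sequence with per-pulse phase increments (rad)."""
        out = []
        idx = 0
        for ev in self.events:
            if ev[0] == "pulse":
                p: Pulse = ev[1]
                if idx in extra_phase:
                    p = p.with_phase(p.phase_rad + extra_phase[idx])
                out.append(("pulse", p))
                idx += 1
            else:
                out.append(ev)
        return PulseSequence(out, self.n_refocus, self.tau_ns, self.name)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @staticmethod
    def hahn(tau_ns: float, p90: Pulse, p180: Pulse) -> "PulseSequence":
        """pi/2 - tau - pi - tau - echo."""
        return PulseSequence(
            [
                ("pulse", p90),
                ("delay", tau_ns),
                ("pulse", p180),
                ("delay", tau_ns),
                ("detect", +1),
            ],
            n_refocus=1,
            tau_ns=tau_ns,
            name="hahn",
        )

    @staticmethod
    def cpn(n: int, tau_ns: float, p90: Pulse, p180: Pulse) -> "PulseSequence":
        """pi/2 - (tau/n - pi - tau/n)^n - echo; first-pulse-to-echo time 2*tau."""
        if n < 1:
            raise ValueError("n must be >= 1")
        ev: list = [("pulse", p90)]
        sub = tau_ns / n
        for k in range(n):
            ev += [("delay", sub), ("pulse", p180), ("delay", sub)]
        # each pi pulse flips the echo axis y -> -y: last echo along +y for
        # odd n, -y for even n
        ev.append(("detect", +1 if n % 2 == 1 else -1))
        return PulseSequence(ev, n_refocus=n, tau_ns=tau_ns, name=f"cp{n}")

    @staticmethod
    def full_train(n_pairs: int, tau_ns: float, p90: Pulse, p180: Pulse) -> "PulseSequence":
        """pi/2_x - (tau - pi_x - tau - echo - tau - pi_-x - tau - echo)^n.

        Every echo is detected (2*n_pairs echoes, first at 2*tau).
        """
        if n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        ev: list = [("pulse", p90)]
        sign = +1
        for k in range(2 * n_pairs):
            phase = p180.phase_rad if k % 2 == 0 else p180.phase_rad + math.pi
            ev += [
                ("delay", tau_ns),
                ("pulse", Pulse(p180.duration_ns, p180.flip_rad, phase)),
                ("delay", tau_ns),
                ("detect", sign),
            ]
            sign = -sign
        return PulseSequence(ev, n_refocus=2 * n_pairs, tau_ns=tau_ns, name="full_train")


def _rotate(M: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of Bloch vectors M (n,3) about per-packet axes."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    k = axis
    kdotm = np.sum(k * M, axis=1, keepdims=True)
    return M * c + np.cross(k, M) * s + k * kdotm * (1.0 - c)


def propagate(
    sequence: PulseSequence,
    offsets: OffsetEnsemble,
    relax: Optional[RelaxationParams] = None,
) -> EchoTrain:
    """Propagate the offset ensemble through the sequence; return the echoes.

    Signal per detection event = ensemble-weighted in-phase (y) component at
    the echo center, multiplied by the event's expected polarity.
    """
    off, w = offsets.sample()
    dw = _TWO_PI_MHZ_TO_RAD_PER_NS * off  # rad/ns
    n = len(off)
    M = np.zeros((n, 3))
    M[:, 2] = 1.0

    t_now = 0.0  # ns
    times, amps = [], []

    if relax is not None:
        t1_ns = relax.T1_us * 1e3
        t2_ns = relax.T2_us * 1e3
        beta = relax.stretch

    for ev in sequence.events:
        kind = ev[0]
        if kind == "delay":
            dt = ev[1]
            if dt == 0:
                continue
            phi = dw * dt
            c, s = np.cos(phi), np.sin(phi)
            mx = M[:, 0] * c - M[:, 1] * s
            my = M[:, 0] * s + M[:, 1] * c
            M[:, 0], M[:, 1] = mx, my
            if relax is not None:
                # stretched transverse kernel accumulated on the global clock
                k2 = math.exp(-(((t_now + dt) / t2_ns) ** beta) + ((t_now / t2_ns) ** beta))
                k1 = math.exp(-dt / t1_ns)
                M[:, 0] *= k2
                M[:, 1] *= k2
                M[:, 2] = M[:, 2] * k1 + (1.0 - k1)
            t_now += dt
        elif kind == "pulse":
            p: Pulse = ev[1]
            cp, sp = math.cos(p.phase_rad), math.sin(p.phase_rad)
            if p.duration_ns == 0:  # ideal pulse
                axis = np.broadcast_to(np.array([cp, sp, 0.0]), (n, 3))
                angle = np.full(n, p.flip_rad)
            else:
                w1 = p.omega1_rad_per_ns
                omega_eff = np.sqrt(w1**2 + dw**2)
                axis = np.empty((n, 3))
                axis[:, 0] = w1 * cp / omega_eff
                axis[:, 1] = w1 * sp / omega_eff
                axis[:, 2] = dw / omega_eff
                angle = omega_eff * p.duration_ns
            M = _rotate(M, axis, angle)
        elif kind == "detect":
            times.append(t_now * 1e-3)  # µs
            amps.append(ev[1] * float(np.sum(w * M[:, 1])))
        else:  # pragma: no cover
            raise ValueError(f"unknown event {kind}")
    return EchoTrain(np.array(times), np.array(amps))


# ----------------------------------------------------------------------
# phase cycling
# ----------------------------------------------------------------------

def cpn_phase_cycle(n: int) -> dict:
    """Nested 2^n-step +/-x cycle on the n refocusing pulses of a CPn
    sequence (pulse index 0 is the pi/2).  The fully refocused pathway is
    invariant under a pi phase shift of any pi pulse, while pathways stored
    along z across a pi pulse change sign, so a plain average cancels them.
    """
    steps = []
    for bits in range(2**n):
        phases = {
            1 + k: math.pi if (bits >> k) & 1 else 0.0 for k in range(n)
        }
        steps.append({"pulse_phases": phases, "receiver": 1.0})
    return {"name": f"cp{n}", "steps": steps}


def train_phase_cycle() -> dict:
    """Two-step +/-x cycle on the initial pi/2 pulse of the full CP train."""
    return {
        "name": "full_train",
        "steps": [
            {"pulse_phases": {}, "receiver": 1.0},
            {"pulse_phases": {0: math.pi}, "receiver": -1.0},
        ],
    }


def load_phase_cycle(name: str) -> dict:
    """Load a phase-cycle table from the packaged JSON data file.

    Shipping the tables as data allows replacing them with a spectrometer's
    exact cycles without touching code.
    """
    text = resources.files("gdrelax.data").joinpath("phase_cycles.json").read_text()
    tables = json.loads(text)
    if name not in tables:
        raise KeyError(f"unknown phase cycle {name!r}; available: {sorted(tables)}")
    entry = tables[name]
    steps = [
        {
            "pulse_phases": {int(k): math.radians(v) for k, v in st["pulse_phases_deg"].items()},
            "receiver": float(st["receiver"]),
        }
        for st in entry["steps"]
    ]
    return {"name": name, "steps": steps}


def phase_cycle(
    sequence: PulseSequence,
    scheme: dict,
    offsets: OffsetEnsemble,
    relax: Optional[RelaxationParams] = None,
) -> EchoTrain:
    """Signed average of the sequence over the steps of a phase cycle."""
    steps = scheme.get("steps")
    if not steps:
        raise ValueError("malformed cycle table: no steps")
    acc = None
    times = None
    for st in steps:
        if "pulse_phases" not in st or "receiver" not in st:
            raise ValueError("malformed cycle table entry")
        seq = sequence.with_pulse_phases(st["pulse_phases"])
        train = propagate(seq, offsets, relax)
        if acc is None:
            acc = st["receiver"] * train.amplitude
            times = train.time_us
        else:
            acc = acc + st["receiver"] * train.amplitude
    return EchoTrain(times, acc / len(steps))


# ----------------------------------------------------------------------
# stimulated-echo Tm bias
# ----------------------------------------------------------------------

@dataclass
class StimulatedEchoBias:
    """Outcome of the selective-pulse CP-train bias experiment."""

    bias: float  # (Tm_fit - T2_input) / T2_input
    tm_fit_us: float
    beta_fit: float
    t2_input_us: float
    se_rms_residual: float  # RMS SE-fit residual / initial amplitude
    se_adequate: bool  # SSE offered no strong improvement over SE
    delta_aicc: float
    fit: SEFit
    train: EchoTrain


def stimulated_echo_bias(
    tau_ns: float,
    n_pairs: int,
    pulse_pi: Pulse,
    offsets: OffsetEnsemble,
    relax: RelaxationParams,
) -> StimulatedEchoBias:
    """Quantify the Tm overestimation caused by stimulated-echo pathways.

    A full CP train (2*n_pairs echoes, constant tau) is simulated with the
    given selective pi pulse (the pi/2 pulse has half its duration) and the
    two-step cycle on the first pulse, the echo decay is fitted with the
    single stretched exponential, and the relative overshoot of the fitted
    Tm with respect to the input T2 is returned.  The decay counts as
    adequately described by a single stretched exponential when the
    two-component model offers no strong AICc improvement.
    """
    p90 = Pulse(pulse_pi.duration_ns / 2.0, math.pi / 2.0, 0.0)
    seq = PulseSequence.full_train(n_pairs, tau_ns, p90, pulse_pi)
    train = phase_cycle(seq, train_phase_cycle(), offsets, relax)
    trace = train.to_trace(sequence="full_train")
    sel = select_model(trace)
    fit = sel.se
    resid = fit.evaluate(train.time_us) - train.amplitude
    rms = float(np.sqrt(np.mean(resid**2)) / max(abs(train.amplitude[0]), 1e-30))
    bias = (fit.Tm - relax.T2_us) / relax.T2_us
    return StimulatedEchoBias(
        bias=float(bias),
        tm_fit_us=float(fit.Tm),
        beta_fit=float(fit.beta),
        t2_input_us=relax.T2_us,
        se_rms_residual=rms,
        se_adequate=bool(sel.chosen == "SE"),
        delta_aicc=float(sel.delta_aicc),
        fit=fit,
        train=train,
    )


# ----------------------------------------------------------------------
# analytic pathway oracles (hard pulses)
# ----------------------------------------------------------------------

def analytic_hahn_amplitude(theta1_rad: float, theta2_rad: float) -> float:
    """Refocused two-pulse echo amplitude for hard pulses:
    sin(theta1) sin^2(theta2/2)."""
    return math.sin(theta1_rad) * math.sin(theta2_rad / 2.0) ** 2


def analytic_stimulated_amplitude(t1: float, t2: float, t3: float) -> float:
    """Stimulated-echo pathway amplitude for hard pulses:
    (1/2) sin(theta1) sin(theta2) sin(theta3)."""
    return 0.5 * math.sin(t1) * math.sin(t2) * math.sin(t3)


# ----------------------------------------------------------------------
# Mims ENDOR and point-dipole distances
# ----------------------------------------------------------------------

def mims_efficiency(a_MHz, tau_ns) -> np.ndarray | float:
    """Mims-ENDOR response 1/4 [1 - cos(2 pi a tau)] for coupling a.

    Zero at the blind spots a*tau integer, maximal (= 1/2) at a*tau
    half-integer.
    """
    x = np.asarray(a_MHz, dtype=float) * np.asarray(tau_ns, dtype=float) * 1e-3
    out = 0.25 * (1.0 - np.cos(2.0 * math.pi * x))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HyperfineCoupling:
    """Axial proton hyperfine coupling (kHz); pure point-dipole couplings
    have a_par = -2 a_perp (traceless)."""

    a_perp_kHz: float
    a_par_kHz: Optional[float] = None
    label: str = ""
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weights must be positive")
        if self.a_par_kHz is None:
            object.__setattr__(self, "a_par_kHz", -2.0 * self.a_perp_kHz)


def endor_spectrum(
    couplings: Seq[HyperfineCoupling],
    tau_ns: float,
    nuclear_larmor_MHz: float,
    freq_grid_MHz: Optional[np.ndarray] = None,
    n_theta: int = 721,
    linewidth_MHz: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Powder Mims-ENDOR spectrum of weakly coupled protons.

    Each coupling produces a doublet at nu_L +/- a(theta)/2 with the axial
    orientation dependence a(theta) = a_par cos^2 + a_perp sin^2, powder
    weight sin(theta), multiplied by the Mims response at the local coupling
    2|nu - nu_L|.  A small Gaussian line broadening is applied.  Without
    couplings a single matrix line remains at the Larmor frequency.
    """
    for cpl in couplings:
        if nuclear_larmor_MHz <= abs(cpl.a_perp_kHz) * 1e-3 / 2.0:
            raise ValueError("weak-coupling regime requires larmor > a/2")
    if freq_grid_MHz is None:
        amax = max([abs(c.a_perp_kHz) * 2e-3 for c in couplings], default=0.2)
        half = max(1.5 * amax, 0.3)
        freq_grid_MHz = nuclear_larmor_MHz + np.linspace(-half, half, 2001)
    amp = np.zeros_like(freq_grid_MHz)
    dg = freq_grid_MHz[1] - freq_grid_MHz[0]

    theta = np.linspace(0.0, math.pi / 2.0, n_theta)
    wtheta = np.sin(theta)
    for cpl in couplings:
        a_MHz = (cpl.a_par_kHz * np.cos(theta) ** 2 + cpl.a_perp_kHz * np.sin(theta) ** 2) * 1e-3
        eff = mims_efficiency(np.abs(a_MHz), tau_ns)
        for sign in (+1.0, -1.0):
            nu = nuclear_larmor_MHz + sign * a_MHz / 2.0
            idx = np.clip(np.round((nu - freq_grid_MHz[0]) / dg).astype(int), 0, len(amp) - 1)
            np.add.at(amp, idx, cpl.weight * wtheta * eff)
    if not couplings:
        idx = int(round((nuclear_larmor_MHz - freq_grid_MHz[0]) / dg))
        amp[np.clip(idx, 0, len(amp) - 1)] = 1.0
    if linewidth_MHz > 0:
        from scipy.ndimage import gaussian_filter1d

        amp = gaussian_filter1d(amp, sigma=max(linewidth_MHz / dg, 1e-6), mode="constant")
    return freq_grid_MHz, amp


def dipole_coupling(r_angstrom: float, g: float = G_ELECTRON) -> float:
    """Point-dipole perpendicular hyperfine coupling (kHz) of a proton at
    distance r (Å) from an electron spin with g-factor g."""
    if r_angstrom <= 0:
        raise ValueError("distance must be positive")
    return electron_proton_dipolar_constant(g) / r_angstrom**3 * 1e3


def dipole_distance(a_perp_kHz: float, g: float = G_ELECTRON) -> float:
    """Invert the point-dipole relation: distance (Å) from a_perp (kHz)."""
    if a_perp_kHz <= 0:
        raise ValueError("coupling must be positive")
    return (electron_proton_dipolar_constant(g) * 1e3 / a_perp_kHz) ** (1.0 / 3.0)
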