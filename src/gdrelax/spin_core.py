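"""Spin operators, ZFS + Zeeman Hamiltonian, and transition bookkeeping
for high-spin systems (S = 7/2 Gd(III) by default).

The zero-field-splitting convention is the community standard

    H_ZFS = D [Sz^2 - S(S+1)/3] + E (Sx^2 - Sy^2)      (MHz)

and the electron Zeeman term for an isotropic g is

    H_Z / h = g mu_B B (n . S) / h                      (B in mT, n unit vector)

Echo-detected intensities of the individual |mS> <-> |mS+1> transitions are
re-normalized by the pulse-turning-angle factor sin^3(pi alpha / 2) / alpha,
with alpha the relative nutation-frequency scale of the transition; the
central transition (mS = -1/2) has alpha = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import (
    BOHR_MHZ_PER_MT,
    BOLTZMANN_MHZ_PER_K,
    G_GD_DEFAULT,
)

__all__ = [
    "SpinSystem",
    "Orientation",
    "spin_operators",
    "hamiltonian",
    "zfs_hamiltonian",
    "transition_alpha",
    "boltzmann_weights",
    "resonance_fields",
]


def _validate_spin(spin: float) -> float:
    twos = 2.0 * spin
    if spin <= 0 or abs(twos - round(twos)) > 1e-9:
        raise ValueError(f"spin must be a positive half-integer, got {spin}")
    return float(spin)


@dataclass(frozen=True)
class SpinSystem:
    """Electron spin system with axial/rhombic ZFS and Gaussian strains.

    Parameters
    ----------
    spin : half-integer, default 7/2
    g : isotropic g-factor (dimensionless)
    D, E : axial and rhombic ZFS parameters, MHz
    strain_D, strain_E : widths of independent Gaussian distributions of
        D and E, MHz.  By convention these are FWHM values
        (``strain_is_fwhm=False`` switches to standard deviations).
    """

    spin: float = 3.5
    g: float = G_GD_DEFAULT
    D: float = 0.0
    E: float = 0.0
    strain_D: float = 0.0
    strain_E: float = 0.0
    strain_is_fwhm: bool = True

    def __post_init__(self):
        _validate_spin(self.spin)
        if self.strain_D < 0 or self.strain_E < 0:
            raise ValueError("strain widths must be non-negative")

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))

    def replace(self, **kw) -> "SpinSystem":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class Orientation:
    """Direction of the static field in the ZFS principal-axis frame."""

    theta: float = 0.0  # polar angle, rad, in [0, pi]
    phi: float = 0.0  # azimuth, rad

    def direction(self) -> np.ndarray:
        st, ct = np.sin(self.theta), np.cos(self.theta)
        return np.array([st * np.cos(self.phi), st * np.sin(self.phi), ct])

    def transverse_direction(self) -> np.ndarray:
        """A unit vector perpendicular to the field direction."""
        ct, st = np.cos(self.theta), np.sin(self.theta)
        return np.array([ct * np.cos(self.phi), ct * np.sin(self.phi), -st])


def spin_operators(spin: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Sx, Sy, Sz) matrices in the |S, m> basis ordered m = S ... -S.

    Satisfy [Sx, Sy] = i Sz (and cyclic); Sz is diagonal with entries S..-S.
    """
    s = _validate_spin(spin)
    dim = int(round(2 * s + 1))
    m = s - np.arange(dim)  # descending
    sz = np.diag(m).astype(complex)
    # <m+1|S+|m> = sqrt(S(S+1) - m(m+1)); basis descending -> S+ is superdiagonal
    raise_elems = np.sqrt(s * (s + 1) - m[1:] * (m[1:] + 1))
    sp = np.zeros((dim, dim), dtype=complex)
    sp[np.arange(dim - 1), np.arange(1, dim)] = raise_elems
    sm = sp.conj().T
    sx = 0.5 * (sp + sm)
    sy = -0.5j * (sp - sm)
    return sx, sy, sz


def zfs_hamiltonian(spin: float, D: float, E: float) -> np.ndarray:
    """Traceless ZFS Hamiltonian D[Sz^2 - S(S+1)/3] + E(Sx^2 - Sy^2), MHz."""
    sx, sy, sz = spin_operators(spin)
    s = float(spin)
    eye = np.eye(int(round(2 * s + 1)))
    return D * (sz @ sz - s * (s + 1) / 3.0 * eye) + E * (sx @ sx - sy @ sy)


def hamiltonian(system: SpinSystem, field_mT: float, orient: Orientation) -> np.ndarray:
    """Full Zeeman + ZFS Hamiltonian (MHz) for a field along ``orient``.

    ``field_mT`` must be non-negative.
    """
    if field_mT < 0:
        raise ValueError("field must be non-negative")
    sx, sy, sz = spin_operators(system.spin)
    n = orient.direction()
    h_zee = system.g * BOHR_MHZ_PER_MT * field_mT * (n[0] * sx + n[1] * sy + n[2] * sz)
    return h_zee + zfs_hamiltonian(system.spin, system.D, system.E)


def transition_alpha(spin: float, mS: float) -> tuple[float, float]:
    """Relative nutation scale alpha and echo-intensity factor for the
    |mS> <-> |mS+1> transition.

    alpha = sqrt[(S(S+1) - mS(mS+1)) / (S(S+1) + 0.25)]; the intensity
    renormalization is sin^3(pi alpha / 2) / alpha, equal to 1 for the
    central transition mS = -1/2.
    """
    s = _validate_spin(spin)
    # valid lower levels: -S, -S+1, ..., S-1
    if mS < -s - 1e-9 or mS > s - 1 + 1e-9 or abs((mS + s) - round(mS + s)) > 1e-9:
        raise ValueError(f"mS={mS} is not a valid lower level for S={spin}")
    alpha = np.sqrt((s * (s + 1) - mS * (mS + 1)) / (s * (s + 1) + 0.25))
    factor = np.sin(np.pi * alpha / 2.0) ** 3 / alpha
    return float(alpha), float(factor)


def boltzmann_weights(energies_MHz, temperature_K: float) -> np.ndarray:
    """Normalized Boltzmann populations of levels with the given energies."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    e = np.asarray(energies_MHz, dtype=float)
    x = -(e - e.min()) / (BOLTZMANN_MHZ_PER_K * temperature_K)
    w = np.exp(x)
    return w / w.sum()


@dataclass
class TransitionTable:
    """Per-transition resonance data for one orientation and parameter set.

    ``table`` has one row per allowed |mS> <-> |mS+1> transition found in the
    field window, with columns: mS (lower-level label), resonance_field_mT,
    transition_moment, alpha, intensity_factor, population_difference.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self):
        return len(self.table)


def resonance_fields(
    system: SpinSystem,
    orient: Orientation,
    mw_freq_GHz: float,
    field_window_mT: tuple[float, float],
    temperature_K: float = 10.0,
    xtol_mT: float = 1e-4,
) -> TransitionTable:
    """Solve for the resonance fields of all |mS> <-> |mS+1> transitions.

    Levels are labelled by sorting eigenvalues in ascending order (valid in
    the high-field regime used here); for each adjacent pair the field at
    which the level splitting equals the microwave quantum is found by
    bracketed root search inside ``field_window_mT``.  Transitions without a
    root in the window are omitted.
    """
    nu = mw_freq_GHz * 1e3  # MHz
    s = system.spin
    dim = system.multiplicity
    b_lo, b_hi = field_window_mT
    if not (0 <= b_lo < b_hi):
        raise ValueError("invalid field window")

    sx, sy, sz = spin_operators(s)
    n = orient.direction()
    h_dir = system.g * BOHR_MHZ_PER_MT * (n[0] * sx + n[1] * sy + n[2] * sz)
    h_zfs = zfs_hamiltonian(s, system.D, system.E)

    def levels(b):
        return np.linalg.eigvalsh(b * h_dir + h_zfs)

    def gap(b, i):
        e = levels(b)
        return e[i + 1] - e[i] - nu

    e1 = orient.transverse_direction()
    s_perp = e1[0] * sx + e1[1] * sy + e1[2] * sz

    rows = []
    for i in range(dim - 1):
        f_lo, f_hi = gap(b_lo, i), gap(b_hi, i)
        if f_lo * f_hi > 0:
            continue  # no root in window: omit
        b_res = brentq(gap, b_lo, b_hi, args=(i,), xtol=xtol_mT)
        evals, evecs = np.linalg.eigh(b_res * h_dir + h_zfs)
        moment = abs(evecs[:, i + 1].conj() @ s_perp @ evecs[:, i])
        pops = boltzmann_weights(evals, temperature_K)
        mS = i - s
        alpha, factor = transition_alpha(s, mS)
        rows.append(
            dict(
                mS=mS,
                resonance_field_mT=b_res,
                transition_moment=moment,
                alpha=alpha,
                intensity_factor=factor,
                population_difference=pops[i] - pops[i + 1],
            )
        )
    return TransitionTable(pd.DataFrame(rows))
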