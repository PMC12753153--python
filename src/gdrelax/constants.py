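"""Physical constants and unit conventions.

Unit conventions used throughout the package (declared once, enforced at
module boundaries):

* energies / couplings : MHz
* magnetic fields      : mT
* microwave/RF freqs   : GHz (MHz for nuclear/hyperfine quantities)
* relaxation times     : µs
* pulse-sequence times : ns
"""

from __future__ import annotations

import math

# CODATA 2018
BOHR_MAGNETON = 9.2740100783e-24  # J/T
NUCLEAR_MAGNETON = 5.0507837461e-27  # J/T
PLANCK = 6.62607015e-34  # J s
HBAR = PLANCK / (2.0 * math.pi)
BOLTZMANN = 1.380649e-23  # J/K
MU0_OVER_4PI = 1.0e-7  # T m / A (== H/m / 4pi)
G_ELECTRON = 2.00231930436256
G_PROTON = 5.5856946893
AVOGADRO = 6.02214076e23

# Bohr magneton in frequency units: mu_B/h [MHz/mT] (== GHz/T)
BOHR_MHZ_PER_MT = BOHR_MAGNETON / PLANCK * 1e-9  # 13.996... MHz/mT

# Boltzmann constant in frequency units: k/h [MHz/K]
BOLTZMANN_MHZ_PER_K = BOLTZMANN / PLANCK * 1e-6  # 20836.6 MHz/K

#: Default isotropic g-factor for Gd(III) complexes.
G_GD_DEFAULT = 1.992

#: Default microwave frequency (GHz) for W-band simulations.
MW_FREQ_DEFAULT_GHZ = 94.9

# Prefactor of the statistical (dilute, Lorentzian) dipolar broadening of a
# randomly distributed spin bath: 4 pi^2 / (9 sqrt(3)).
DIPOLAR_STATISTICAL_PREFACTOR = 4.0 * math.pi**2 / (9.0 * math.sqrt(3.0))


def spins_per_cm3(concentration_uM: float) -> float:
    """Convert a molar concentration in µM to a number density in cm^-3."""
    return concentration_uM * 1e-6 * AVOGADRO * 1e-3


def dipolar_rate_constant(g: float = G_GD_DEFAULT) -> float:
    """Dipolar line-broadening constant A such that the Lorentzian half-width
    of the dipolar field distribution is ``A * C`` for concentration C in µM.

    Returns A in rad µs^-1 µM^-1; the underlying expression is
    (4 pi^2 / 9 sqrt3) * (mu0/4pi) * g^2 mu_B^2 / hbar * n  with n the spin
    number density.
    """
    per_density = (
        DIPOLAR_STATISTICAL_PREFACTOR
        * MU0_OVER_4PI
        * (g * BOHR_MAGNETON) ** 2
        / HBAR
    )  # m^3 rad/s
    per_uM = per_density * 1e6 * spins_per_cm3(1.0)  # cm^3 rad/s * cm^-3/µM
    return per_uM * 1e-6  # rad/s -> rad/µs


def electron_proton_dipolar_constant(g: float = G_ELECTRON) -> float:
    """Point-dipole electron-proton coupling constant K (MHz Å^3).

    The perpendicular hyperfine component of a proton at distance r from a
    point electron spin is ``a_perp = K / r^3`` (r in Å, a_perp in MHz).
    For g = g_e, K ≈ 79 MHz Å^3.
    """
    k_hz_m3 = MU0_OVER_4PI * (g * BOHR_MAGNETON) * (G_PROTON * NUCLEAR_MAGNETON) / PLANCK
    return k_hz_m3 * 1e-6 / 1e-30  # Hz m^3 -> MHz Å^3


FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
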