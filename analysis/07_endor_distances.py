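#!/usr/bin/env python
"""Mims ENDOR of the ligand protons: blind spots and point-dipole distances.

Simulates the powder proton ENDOR spectrum for the pyridine-ring (440 kHz)
and phenyl-ring (170 kHz) couplings at the two tau values used to cover
large and small couplings, reads the doublet splittings back from the
spectra, and converts the couplings to electron-proton distances under the
point-dipole approximation.  Writes results/endor.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy.signal import argrelextrema

from gdrelax.pulse_sim import (HyperfineCoupling, dipole_distance,
                               endor_spectrum, mims_efficiency)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

LARMOR = 144.7  # 1H at ~3400 mT, MHz
couplings = [HyperfineCoupling(440.0, label="pyridine"),
             HyperfineCoupling(170.0, weight=2.0, label="phenyl")]

report = {"larmor_MHz": LARMOR, "tau_ns": {}, "distances_A": {}}
for tau in (280.0, 600.0):
    freq, amp = endor_spectrum(couplings, tau, LARMOR)
    peaks = freq[argrelextrema(amp, np.greater, order=8)[0]] - LARMOR
    report["tau_ns"][str(int(tau))] = {
        "peak_offsets_MHz": [round(float(p), 4) for p in peaks],
        "efficiency_440kHz": mims_efficiency(0.44, tau),
        "efficiency_170kHz": mims_efficiency(0.17, tau),
    }
    print(f"tau = {tau:.0f} ns: doublet peaks at {np.round(peaks, 3)} MHz "
          f"(response 440 kHz: {mims_efficiency(0.44, tau):.3f}, "
          f"170 kHz: {mims_efficiency(0.17, tau):.3f})")

for cpl in couplings:
    r = dipole_distance(cpl.a_perp_kHz, g=1.992)
    report["distances_A"][cpl.label] = r
    print(f"{cpl.label}: a_perp = {cpl.a_perp_kHz:.0f} kHz -> "
          f"r = {r:.2f} Å (point dipole)")

with open(OUT / "endor.json", "w") as f:
    json.dump(report, f, indent=1)
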