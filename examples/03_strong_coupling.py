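"""Plasmon-vibration strong coupling: polaritons and Rabi splittings.

Diagonalizes the three-oscillator model, evaluates the linewidth-
corrected Rabi formula, and extracts the anticrossing gaps from a
simulated antenna-length sweep.
"""

import numpy as np

from seiralab import (AbsorberConfig, LinewidthPair, MixtureSpec,
                      ThreeOscillatorSystem, hybrid_energies, length_sweep,
                      rabi_splitting, splitting_from_anticrossing)
from seiralab.coupling import BAND_ENERGIES_MEV
from seiralab.pca import build_grid

# polaritons of the lipid pair with the plasmon tuned between the bands
system = ThreeOscillatorSystem(
    E_p=358.3, E_1=BAND_ENERGIES_MEV["lipid1"], E_2=BAND_ENERGIES_MEV["lipid2"],
    hbar_omega_1=11.3, hbar_omega_2=11.3)
ps = hybrid_energies(system)
print("three-oscillator polaritons (hbar Omega = 11.3 meV):")
for e, w in zip(ps.energies, ps.weights):
    print(f"  E={e:7.2f} meV   weights plasmon/band1/band2 = "
          f"{w[0]:.2f}/{w[1]:.2f}/{w[2]:.2f}")

print(f"\nRabi formula, equal widths, g=5.65 meV: "
      f"{rabi_splitting(LinewidthPair(10.0, 10.0, 5.65)):.2f} meV (= 2g)")

# anticrossing gaps of the default calibrated device
sweep = length_sweep(AbsorberConfig(), MixtureSpec(0.5, 1.0),
                     np.linspace(1.23, 1.43, 41), build_grid(3000, 7000, 5.0))
for band in ("lipid1", "lipid2", "protein1", "protein2"):
    res = splitting_from_anticrossing(sweep, band)
    print(f"anticrossing gap {band:9s}: {res.gap_mev:5.2f} meV "
          f"(resolved at {res.n_valid} sweep points)")
print("\nthe calibrated device reproduces splittings of 11.3 meV (lipid/P1)")
print("and 12.8 meV (protein/P2) at L = 1.33 um and standard loading")
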