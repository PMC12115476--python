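"""One-time calibration of the coupled-mode base couplings g0.

Root-finds the per-mode base coupling so that the length-sweep
anticrossing gap at the standard equal mixture (f = 0.5, c = 1)
reproduces the reference splittings: 11.3 meV on P1/lipid and
12.8 meV on P2/protein, with the plasmon half-rates fixed at
gamma_rad = gamma_nr = 3.0 meV (P1) and 1.5 meV (P2), i.e. critical
coupling on both modes.

Run from the repository root:  python scripts/calibrate.py
The printed constants are frozen into
seiralab.absorber.CalibrationConstants.
"""

import numpy as np
from scipy.optimize import brentq

from seiralab.absorber import (AbsorberConfig, CalibrationConstants,
                               length_sweep)
from seiralab.coupling import splitting_from_anticrossing
from seiralab.pca import build_grid
from seiralab.permittivity import MixtureSpec

TARGETS = {"P1": ("lipid1", 11.3), "P2": ("protein1", 12.8)}
L_VALUES = np.linspace(1.23, 1.43, 41)
GRID = build_grid(3000.0, 7000.0, 5.0)


def measured_gap(g0_p1: float, g0_p2: float, band: str) -> float:
    cal = CalibrationConstants(g0={"P1": g0_p1, "P2": g0_p2})
    sweep = length_sweep(AbsorberConfig(), MixtureSpec(0.5, 1.0),
                         L_VALUES, GRID, cal)
    return splitting_from_anticrossing(sweep, band).gap_mev


def main():
    g0 = {"P1": 9.0, "P2": 9.0}
    for mode, (band, target) in TARGETS.items():
        def objective(g):
            trial = dict(g0)
            trial[mode] = g
            return measured_gap(trial["P1"], trial["P2"], band) - target
        g0[mode] = brentq(objective, 4.0, 20.0, xtol=1e-4)
        print(f"{mode}: g0 = {g0[mode]:.4f} meV "
              f"(gap {measured_gap(g0['P1'], g0['P2'], band):.3f} meV, "
              f"target {target} meV)")
    print("\nfrozen defaults:")
    print(f'    g0 = {{"P1": {g0["P1"]:.4f}, "P2": {g0["P2"]:.4f}}}')
    for mode, (band, target) in TARGETS.items():
        gap = measured_gap(g0["P1"], g0["P2"], band)
        print(f"check {mode}/{band}: {gap:.3f} meV vs target {target}")


if __name__ == "__main__":
    main()
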