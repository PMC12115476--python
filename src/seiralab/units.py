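"""Unit conversions between wavenumber, wavelength, and photon energy.

Vibrational band parameters are tabulated in wavenumbers (cm^-1),
absorption spectra live on a wavelength grid (nm), and the coupled-mode
algebra runs in photon energy (meV).  All three scales are reciprocal /
proportional, so every conversion here is a single division; the helpers
exist to keep the factors (10^7 nm cm^-1, hc) in one place.

Scalars in give scalars out; numpy arrays broadcast elementwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HC_MEV_NM",
    "wavenumber_to_wavelength_nm",
    "wavelength_nm_to_wavenumber",
    "wavelength_to_energy_mev",
    "energy_mev_to_wavelength_nm",
    "wavenumber_to_energy_mev",
]

#: Planck constant times vacuum speed of light, in meV * nm.
HC_MEV_NM = 1.239841984e6


def _validated(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be positive and finite, got {x!r}")
    return arr


def _as_input(result: np.ndarray, template):
    return float(result) if np.isscalar(template) or np.ndim(template) == 0 else result


def wavenumber_to_wavelength_nm(nu_cm1):
    """Vacuum wavelength (nm) of a wavenumber (cm^-1): 10^7 / nu."""
    nu = _validated(nu_cm1, "wavenumber")
    return _as_input(1.0e7 / nu, nu_cm1)


def wavelength_nm_to_wavenumber(lambda_nm):
    """Wavenumber (cm^-1) of a vacuum wavelength (nm): 10^7 / lambda."""
    lam = _validated(lambda_nm, "wavelength")
    return _as_input(1.0e7 / lam, lambda_nm)


def wavelength_to_energy_mev(lambda_nm):
    """Photon energy (meV) of a vacuum wavelength (nm): hc / lambda."""
    lam = _validated(lambda_nm, "wavelength")
    return _as_input(HC_MEV_NM / lam, lambda_nm)


def energy_mev_to_wavelength_nm(energy_mev):
    """Vacuum wavelength (nm) of a photon energy (meV): hc / E."""
    e = _validated(energy_mev, "energy")
    return _as_input(HC_MEV_NM / e, energy_mev)


def wavenumber_to_energy_mev(nu_cm1):
    """Photon energy (meV) of a wavenumber (cm^-1)."""
    nu = _validated(nu_cm1, "wavenumber")
    return _as_input(HC_MEV_NM * 1.0e-7 * nu, nu_cm1)
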