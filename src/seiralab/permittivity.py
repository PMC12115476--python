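"""Lorentz-oscillator dielectric models for the analyte molecules.

A molecular film is described by a non-dispersive background index
``n_inf**2`` plus a sum of damped Lorentz resonances, one per infrared
vibrational band:

    eps(nu) = n_inf_eff**2 + amount * sum_k A_k w_k**2 / (w_k**2 - nu**2 - i nu g_k)

with all frequencies in wavenumbers (cm^-1).  ``amount`` is a
dimensionless quantity of material (1.0 = the standard loading); the
background is interpolated between vacuum and the full film,
``n_inf_eff**2 = 1 + amount * (n_inf**2 - 1)``, so that ``amount = 0``
recovers vacuum exactly and plasmon detuning by loading is well defined.

Two built-in models ship with the package:

* ``lipid`` — acyl-chain CH stretches at 2930 and 2850 cm^-1,
* ``protein`` — amide I (C=O stretch, 1668 cm^-1) and amide II
  (N-H bend, 1532 cm^-1),

both over a shared background n_inf**2 = 2.36.  Mixtures are f-weighted
sums of the resonant terms over that single shared background, so the
off-resonant real part of the mixture depends only on the total amount,
never on the composition f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VibrationalBand",
    "MolecularModel",
    "MixtureSpec",
    "mixture_permittivity",
    "LIPID",
    "PROTEIN",
    "MODEL_REGISTRY",
    "get_model",
    "model_from_dict",
]


@dataclass(frozen=True)
class VibrationalBand:
    """One Lorentzian vibrational resonance.

    Parameters
    ----------
    center_wavenumber : float
        Band center w_k in cm^-1.
    linewidth : float
        Damping rate g_k in cm^-1 (equals the FWHM of the
        absorption line of the isolated oscillator).
    amplitude : float
        Dimensionless oscillator strength A_k.
    label : str
        Human-readable assignment, e.g. ``"amide I"``.
    """

    center_wavenumber: float
    linewidth: float
    amplitude: float
    label: str = ""

    def __post_init__(self):
        if not self.center_wavenumber > 0:
            raise ValueError("center_wavenumber must be > 0")
        if not self.linewidth > 0:
            raise ValueError("linewidth must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class MolecularModel:
    """Lorentzian dielectric description of one analyte."""

    name: str
    background_eps: float
    bands: tuple[VibrationalBand, ...]

    def __post_init__(self):
        if self.background_eps < 1:
            raise ValueError("background_eps must be >= 1")
        if len(self.bands) == 0:
            raise ValueError("a MolecularModel needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))

    def resonant_susceptibility(self, nu_cm1):
        """Sum of the Lorentz resonance terms at unit amount (complex)."""
        nu = np.asarray(nu_cm1, dtype=float)
        if np.any(nu <= 0):
            raise ValueError("wavenumber must be positive")
        chi = np.zeros(nu.shape, dtype=complex)
        for b in self.bands:
            wk2 = b.center_wavenumber**2
            chi += b.amplitude * wk2 / (wk2 - nu**2 - 1j * nu * b.linewidth)
        return complex(chi) if np.ndim(nu_cm1) == 0 else chi

    def permittivity(self, nu_cm1, amount: float = 1.0):
        """Complex permittivity at wavenumber ``nu_cm1`` for a given amount.

        The background interpolates linearly between vacuum (amount 0)
        and the full film (amount 1); resonant terms scale linearly.
        """
        if amount < 0:
            raise ValueError("amount must be >= 0")
        background = 1.0 + amount * (self.background_eps - 1.0)
        return background + amount * self.resonant_susceptibility(nu_cm1)


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of a lipid/protein mixture.

    ``lipid_fraction`` is the ratio f of lipid in the mixture and
    ``total_amount`` the dimensionless total quantity c, with c = 1 the
    standard loading.  The per-analyte amounts are c*f and c*(1-f).
    """

    lipid_fraction: float
    total_amount: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.lipid_fraction <= 1.0:
            raise ValueError("lipid_fraction must lie in [0, 1]")
        if self.total_amount < 0:
            raise ValueError("total_amount must be >= 0")

    @property
    def lipid_amount(self) -> float:
        return self.total_amount * self.lipid_fraction

    @property
    def protein_amount(self) -> float:
        return self.total_amount * (1.0 - self.lipid_fraction)


def mixture_permittivity(lipid: MolecularModel, protein: MolecularModel,
                         mix: MixtureSpec, nu_cm1):
    """Permittivity of an f-weighted lipid/protein mixture.

    Uses a single shared background (f-weighted between the two models'
    backgrounds, which coincide for the built-in pair) scaled by the
    total amount, plus amount-weighted resonant terms.  At total amount
    1 this equals f*eps_L + (1-f)*eps_P exactly.
    """
    f = mix.lipid_fraction
    shared_bg = f * lipid.background_eps + (1.0 - f) * protein.background_eps
    background = 1.0 + mix.total_amount * (shared_bg - 1.0)
    return (background
            + mix.lipid_amount * lipid.resonant_susceptibility(nu_cm1)
            + mix.protein_amount * protein.resonant_susceptibility(nu_cm1))


LIPID = MolecularModel(
    name="lipid",
    background_eps=2.36,
    bands=(
        VibrationalBand(2930.0, 13.3, 0.0048, "CH2 stretch"),
        VibrationalBand(2850.0, 9.56, 0.0048, "CH3 stretch"),
    ),
)

PROTEIN = MolecularModel(
    name="protein",
    background_eps=2.36,
    bands=(
        VibrationalBand(1668.0, 78.1, 0.016, "amide I"),
        VibrationalBand(1532.0, 101.0, 0.017, "amide II"),
    ),
)

MODEL_REGISTRY: dict[str, MolecularModel] = {m.name: m for m in (LIPID, PROTEIN)}


def get_model(name: str) -> MolecularModel:
    """Look up a built-in molecular model by name."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown molecular model {name!r}; "
            f"available: {sorted(MODEL_REGISTRY)}") from None


def model_from_dict(spec: dict) -> MolecularModel:
    """Build a custom model from a config mapping.

    Expected keys: ``name``, ``n_inf_sq``, ``bands`` (each with
    ``center_cm1``, ``gamma_cm1``, ``amplitude``, optional ``label``).
    """
    bands = tuple(
        VibrationalBand(b["center_cm1"], b["gamma_cm1"], b["amplitude"],
                        b.get("label", ""))
        for b in spec["bands"]
    )
    return MolecularModel(spec["name"], spec["n_inf_sq"], bands)
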