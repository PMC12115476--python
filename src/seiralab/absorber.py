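"""Two-mode coupled-mode-theory model of the dual-band perfect absorber.

The device is an asymmetric cross antenna array over a mirror: a one-port
reflector supporting two plasmonic modes, P1 near 3450 nm (short arm,
L1 = L/2 - s) and P2 near 6280 nm (long arm, L2 = L/2 + s).  With the
mirror suppressing transmission, absorption is A = 1 - |r|^2, and the
reflection amplitude of the port-coupled modes is

    r(w) = -1 + sum_j 2*g_rad_j / (i(E_j - w) + g_rad_j + g_nr_j + S_j(w))
    S_j(w) = sum_k g_jk^2 / (i(E_k - w) + g_m_k)

with everything in photon energy (meV).  Each plasmon mode carries a
self-energy S_j from the molecular oscillators it couples to (lipid
bands to P1, protein bands to P2); g_jk follows the collective
sqrt(amount) coupling law.  At critical coupling (g_rad = g_nr) and no
molecules the device absorbs perfectly at each mode center.

Molecular loading adds background refractive index, which detunes the
plasmon centers linearly in the total amount c around the standard
loading c = 1; oblique incidence mildly reduces the radiative rate and
the coupling (a phenomenological surrogate for the full-wave physics,
tuned to keep absorption above 90% out to 60 degrees).

The default rates and base couplings are calibration constants: the
plasmon half-rates are 3 meV (critical coupling), and the base couplings
were root-found once so that the length-sweep anticrossing gaps at the
standard mixture reproduce splittings of 11.3 meV (P1/lipid) and
12.8 meV (P2/protein); see scripts/calibrate.py.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .permittivity import LIPID, PROTEIN, MixtureSpec, MolecularModel, VibrationalBand
from .units import wavelength_to_energy_mev, wavenumber_to_energy_mev

__all__ = [
    "AbsorberConfig",
    "ScalingLaw",
    "PlasmonMode",
    "MolecularOscillator",
    "Spectrum",
    "CalibrationConstants",
    "DEFAULT_CALIBRATION",
    "L_REFERENCE_UM",
    "ANCHOR_WAVELENGTH_NM",
    "SCALING_ENDPOINTS",
    "ConsistencyError",
    "calibrate_scaling_law",
    "default_scaling_laws",
    "effective_arm_length",
    "plasmon_center_wavelength_nm",
    "build_modes",
    "build_oscillators",
    "detune_by_loading",
    "coupling_strengths",
    "band_modulation_depth",
    "reflection_coefficient",
    "absorption_spectrum",
    "length_sweep",
    "angle_sweep",
    "fraction_sweep",
    "add_noise",
]

#: Antenna length at which the default device is anchored (um).
L_REFERENCE_UM = 1.33

#: Mode-center wavelengths of the default device at L = 1.33 um, c = 1.
ANCHOR_WAVELENGTH_NM = {"P1": 3450.0, "P2": 6280.0}

#: Length-sweep endpoints (L um, center wavelength um) used to calibrate
#: the linear scaling law lambda = 2 L_eff n_eff / m + C per mode.
SCALING_ENDPOINTS = {
    "P1": ((1.23, 3.16), (1.43, 3.79)),
    "P2": ((1.23, 5.86), (1.43, 6.76)),
}


class ConsistencyError(RuntimeError):
    """Raised when computed absorption leaves [0, 1] beyond numerical slack."""


@dataclass(frozen=True)
class AbsorberConfig:
    """Geometry of the dual-band absorber (defaults: the reference device)."""

    L: float = 1.33        # antenna length, um
    W: float = 0.24        # antenna width, um
    s: float = 0.265       # asymmetry offset, um
    P: float = 1.6         # array period, um
    h: float = 70.0        # top metal thickness, nm
    t: float = 90.0        # dielectric spacer thickness, nm
    delta_l: float = 0.05  # spacer undercut, um (metadata only)
    theta: float = 0.0     # incidence angle, degrees

    def __post_init__(self):
        if not 0 < self.s < self.L / 2:
            raise ValueError("asymmetry must satisfy 0 < s < L/2")
        if not 0 <= self.theta < 90:
            raise ValueError("incidence angle must lie in [0, 90) degrees")


@dataclass(frozen=True)
class ScalingLaw:
    """First-order antenna resonance law lambda = 2 L_eff n_eff / m + C (um)."""

    n_eff: float
    C_um: float
    m: int = 1

    def __post_init__(self):
        if self.n_eff <= 0:
            raise ValueError("n_eff must be positive")
        if self.m != 1:
            raise ValueError("only the first-order mode (m = 1) is modelled")

    def wavelength_um(self, L_eff_um: float) -> float:
        return 2.0 * L_eff_um * self.n_eff / self.m + self.C_um


def effective_arm_length(L_um: float, s_um: float, arm: str) -> float:
    """Effective arm length: L/2 - s for the short arm, L/2 + s for the long."""
    if arm == "short":
        return L_um / 2.0 - s_um
    if arm == "long":
        return L_um / 2.0 + s_um
    raise ValueError("arm must be 'short' or 'long'")


def calibrate_scaling_law(point_a: tuple[float, float],
                          point_b: tuple[float, float],
                          arm: str, s_um: float = 0.265) -> ScalingLaw:
    """Fit the linear scaling law exactly through two (L, lambda) endpoints.

    Inputs are in um.  Raises on coincident L values.
    """
    (La, lam_a), (Lb, lam_b) = point_a, point_b
    ea = effective_arm_length(La, s_um, arm)
    eb = effective_arm_length(Lb, s_um, arm)
    if ea == eb:
        raise ValueError("scaling-law fit is singular: identical L values")
    n_eff = (lam_b - lam_a) / (2.0 * (eb - ea))
    C = lam_a - 2.0 * ea * n_eff
    return ScalingLaw(n_eff=n_eff, C_um=C)


def default_scaling_laws(s_um: float = 0.265) -> dict[str, ScalingLaw]:
    """Scaling laws of both modes from the reference length-sweep endpoints."""
    return {
        "P1": calibrate_scaling_law(*SCALING_ENDPOINTS["P1"], arm="short", s_um=s_um),
        "P2": calibrate_scaling_law(*SCALING_ENDPOINTS["P2"], arm="long", s_um=s_um),
    }


@dataclass(frozen=True)
class CalibrationConstants:
    """Rate/coupling constants of the coupled-mode surrogate (meV, nm)."""

    gamma_rad: dict[str, float] = field(
        default_factory=lambda: {"P1": 3.0, "P2": 1.5})
    gamma_nr: dict[str, float] = field(
        default_factory=lambda: {"P1": 3.0, "P2": 1.5})
    #: base coupling g0 per mode at unit analyte amount (meV); frozen
    #: output of scripts/calibrate.py
    g0: dict[str, float] = field(
        default_factory=lambda: {"P1": 15.7800, "P2": 10.7189})
    #: plasmon center shift per unit of total amount c (nm)
    sensitivity_nm: dict[str, float] = field(
        default_factory=lambda: {"P1": 450.0, "P2": 900.0})
    #: oblique-incidence radiative-rate reduction coefficient
    beta: float = 0.35


DEFAULT_CALIBRATION = CalibrationConstants()

#: Which analyte couples to which mode.
MODE_ANALYTE = {"P1": "lipid", "P2": "protein"}


@dataclass(frozen=True)
class PlasmonMode:
    """One port-coupled plasmon resonance."""

    name: str
    center_energy_mev: float
    gamma_rad_mev: float
    gamma_nr_mev: float
    arm: str = "short"

    def __post_init__(self):
        if self.gamma_rad_mev <= 0 or self.gamma_nr_mev <= 0:
            raise ValueError("decay rates must be positive")

    @property
    def fwhm_mev(self) -> float:
        """Uncoupled FWHM Gamma_p = 2 (gamma_rad + gamma_nr)."""
        return 2.0 * (self.gamma_rad_mev + self.gamma_nr_mev)


@dataclass(frozen=True)
class MolecularOscillator:
    """A vibrational band as seen by the coupled-mode model."""

    energy_mev: float
    gamma_half_mev: float  # HWHM of the molecular line
    coupling_mev: float    # g_jk
    label: str = ""


@dataclass
class Spectrum:
    """Absorption vs. wavelength on a strictly increasing grid."""

    wavelength_nm: np.ndarray
    absorption: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise ValueError("grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorption.shape != self.wavelength_nm.shape:
            raise ValueError("absorption and grid shapes differ")

    @property
    def grid_step_nm(self) -> float:
        return float(self.wavelength_nm[1] - self.wavelength_nm[0])


def plasmon_center_wavelength_nm(mode_name: str, L_um: float,
                                 total_amount: float = 1.0,
                                 cal: CalibrationConstants = DEFAULT_CALIBRATION,
                                 s_um: float = 0.265) -> float:
    """Center wavelength of a mode for a given antenna length and loading.

    Anchored to the reference device (3450 / 6280 nm at L = 1.33 um,
    c = 1); the length dependence carries the scaling-law slope
    d lambda / d L = n_eff, and loading shifts the center by
    S_j (c - 1) nm (blue for sub-standard amounts, red above).
    """
    law = default_scaling_laws(s_um)[mode_name]
    anchor = ANCHOR_WAVELENGTH_NM[mode_name]
    length_shift_nm = 1000.0 * law.n_eff * (L_um - L_REFERENCE_UM)
    loading_shift_nm = cal.sensitivity_nm[mode_name] * (total_amount - 1.0)
    return anchor + length_shift_nm + loading_shift_nm


def detune_by_loading(mode: PlasmonMode, total_amount: float,
                      sensitivity_nm: float) -> PlasmonMode:
    """Shift a mode's center wavelength by S (c - 1) nm; c = 1 is neutral."""
    if total_amount < 0:
        raise ValueError("total_amount must be >= 0")
    lam = 1.239841984e6 / mode.center_energy_mev
    lam_shifted = lam + sensitivity_nm * (total_amount - 1.0)
    return replace(mode, center_energy_mev=wavelength_to_energy_mev(lam_shifted))


def build_modes(config: AbsorberConfig, total_amount: float = 0.0,
                cal: CalibrationConstants = DEFAULT_CALIBRATION) -> list[PlasmonMode]:
    """Both plasmon modes for a geometry, loading, and incidence angle."""
    cos_t = math.cos(math.radians(config.theta))
    angle_factor = 1.0 - cal.beta * (1.0 - cos_t)
    modes = []
    for name, arm in (("P1", "short"), ("P2", "long")):
        lam = plasmon_center_wavelength_nm(name, config.L, total_amount,
                                           cal=cal, s_um=config.s)
        modes.append(PlasmonMode(
            name=name,
            center_energy_mev=wavelength_to_energy_mev(lam),
            gamma_rad_mev=cal.gamma_rad[name] * angle_factor,
            gamma_nr_mev=cal.gamma_nr[name],
            arm=arm,
        ))
    return modes


def coupling_strengths(analyte_amount: float, g0_mev: float,
                       bands: tuple[VibrationalBand, ...]) -> list[float]:
    """Per-band couplings g_jk = g0 sqrt(amount * A_k / A_ref) (meV).

    Collective coupling scales with the square root of the number of
    oscillators; A_ref is the first band's amplitude so that unit amount
    of the analyte gives g = g0 for that band.
    """
    if analyte_amount < 0:
        raise ValueError("analyte amount must be >= 0")
    a_ref = bands[0].amplitude
    return [g0_mev * math.sqrt(analyte_amount * b.amplitude / a_ref)
            for b in bands]


def build_oscillators(mix: MixtureSpec, config: AbsorberConfig,
                      cal: CalibrationConstants = DEFAULT_CALIBRATION,
                      lipid: MolecularModel = LIPID,
                      protein: MolecularModel = PROTEIN,
                      ) -> dict[str, list[MolecularOscillator]]:
    """Molecular oscillators attached to each mode for a given mixture."""
    cos_t = math.cos(math.radians(config.theta))
    angle_g = math.sqrt(cos_t)
    out: dict[str, list[MolecularOscillator]] = {}
    amounts = {"lipid": mix.lipid_amount, "protein": mix.protein_amount}
    models = {"lipid": lipid, "protein": protein}
    for mode_name, analyte in MODE_ANALYTE.items():
        model = models[analyte]
        gs = coupling_strengths(amounts[analyte], cal.g0[mode_name], model.bands)
        out[mode_name] = [
            MolecularOscillator(
                energy_mev=wavenumber_to_energy_mev(b.center_wavenumber),
                gamma_half_mev=wavenumber_to_energy_mev(b.linewidth) / 2.0,
                coupling_mev=g * angle_g,
                label=f"{analyte}:{b.label}" if b.label else analyte,
            )
            for b, g in zip(model.bands, gs)
        ]
    return out


def reflection_coefficient(energy_mev: np.ndarray, modes: list[PlasmonMode],
                           oscillators: dict[str, list[MolecularOscillator]] | None = None,
                           ) -> np.ndarray:
    """Complex reflection amplitude of the one-port, multi-mode absorber."""
    w = np.asarray(energy_mev, dtype=float)
    r = np.full(w.shape, -1.0 + 0.0j)
    oscillators = oscillators or {}
    for mode in modes:
        denom = (1j * (mode.center_energy_mev - w)
                 + mode.gamma_rad_mev + mode.gamma_nr_mev)
        for osc in oscillators.get(mode.name, ()):
            if osc.coupling_mev != 0.0:
                denom = denom + osc.coupling_mev**2 / (
                    1j * (osc.energy_mev - w) + osc.gamma_half_mev)
        r = r + 2.0 * mode.gamma_rad_mev / denom
    return r


_ABS_TOL = 1e-7


def _absorption_from_modes(grid_nm: np.ndarray, modes, oscillators) -> np.ndarray:
    energy = wavelength_to_energy_mev(grid_nm)
    r = reflection_coefficient(energy, modes, oscillators)
    a = 1.0 - np.abs(r) ** 2
    if np.any(a < -_ABS_TOL) or np.any(a > 1.0 + _ABS_TOL):
        raise ConsistencyError(
            f"absorption left [0,1]: range [{a.min():.3e}, {a.max():.3e}]")
    return np.clip(a, 0.0, 1.0)


def absorption_spectrum(config: AbsorberConfig,
                        mix: MixtureSpec | None = None,
                        grid_nm: np.ndarray | None = None,
                        cal: CalibrationConstants = DEFAULT_CALIBRATION,
                        lipid: MolecularModel = LIPID,
                        protein: MolecularModel = PROTEIN) -> Spectrum:
    """Absorption spectrum A(lambda) = 1 - |r|^2 of the loaded absorber.

    ``mix=None`` simulates the bare device in vacuum (no oscillators,
    no background loading).  The default grid is the standard
    3000-7000 nm, 20 nm acquisition grid.
    """
    if grid_nm is None:
        from .pca import build_grid
        grid_nm = build_grid()
    grid_nm = np.asarray(grid_nm, dtype=float)
    if grid_nm.min() < 2000 or grid_nm.max() > 8000:
        import warnings
        warnings.warn("grid extends outside the validated 2000-8000 nm range")
    total = 0.0 if mix is None else mix.total_amount
    modes = build_modes(config, total, cal)
    oscillators = None
    if mix is not None:
        oscillators = build_oscillators(mix, config, cal, lipid, protein)
    absorption = _absorption_from_modes(grid_nm, modes, oscillators)
    meta = {
        "L_um": config.L, "theta_deg": config.theta,
        "lipid_fraction": None if mix is None else mix.lipid_fraction,
        "total_amount": None if mix is None else mix.total_amount,
    }
    return Spectrum(grid_nm, absorption, meta)


def _require_params(values, name):
    values = list(values)
    if not values:
        raise ValueError(f"empty {name} list")
    return values


def length_sweep(config: AbsorberConfig, mix: MixtureSpec | None,
                 L_values, grid_nm=None,
                 cal: CalibrationConstants = DEFAULT_CALIBRATION) -> list[Spectrum]:
    """Spectra as the antenna length L sweeps both modes across the bands."""
    spectra = []
    for L in _require_params(L_values, "L"):
        sp = absorption_spectrum(replace(config, L=L), mix, grid_nm, cal)
        sp.metadata["sweep"] = "L"
        spectra.append(sp)
    return spectra


def angle_sweep(config: AbsorberConfig, mix: MixtureSpec | None,
                theta_values, grid_nm=None,
                cal: CalibrationConstants = DEFAULT_CALIBRATION) -> list[Spectrum]:
    """Spectra versus incidence angle theta (degrees)."""
    spectra = []
    for theta in _require_params(theta_values, "theta"):
        sp = absorption_spectrum(replace(config, theta=theta), mix, grid_nm, cal)
        sp.metadata["sweep"] = "theta"
        spectra.append(sp)
    return spectra


def fraction_sweep(config: AbsorberConfig, fractions, total_amount: float = 1.0,
                   grid_nm=None,
                   cal: CalibrationConstants = DEFAULT_CALIBRATION) -> list[Spectrum]:
    """Spectra versus lipid fraction f at fixed geometry and total amount."""
    spectra = []
    for f in _require_params(fractions, "fraction"):
        mix = MixtureSpec(lipid_fraction=f, total_amount=total_amount)
        sp = absorption_spectrum(config, mix, grid_nm, cal)
        sp.metadata["sweep"] = "f"
        spectra.append(sp)
    return spectra


def band_modulation_depth(config: AbsorberConfig, mix: MixtureSpec,
                          band_wavelength_nm: float,
                          cal: CalibrationConstants = DEFAULT_CALIBRATION) -> float:
    """Absorption suppression at a band center due to plasmon-vibration coupling.

    Returns A_uncoupled - A_coupled evaluated exactly at the band
    wavelength, where the uncoupled reference carries the same
    background loading (same plasmon detuning) but no oscillators.
    This is the modulation depth of the vibrational signature; unlike a
    local max-minus-min, it grows monotonically with the analyte amount
    even deep in the strong-coupling regime where the dip bottoms out
    and the polariton structure keeps spreading.
    """
    energy = np.array([wavelength_to_energy_mev(band_wavelength_nm)])
    modes = build_modes(config, mix.total_amount, cal)
    osc = build_oscillators(mix, config, cal)
    a_coupled = 1.0 - np.abs(reflection_coefficient(energy, modes, osc)) ** 2
    a_bare = 1.0 - np.abs(reflection_coefficient(energy, modes, None)) ** 2
    return float(a_bare[0] - a_coupled[0])


def add_noise(spectrum: Spectrum, sigma: float, seed) -> Spectrum:
    """Additive i.i.d. Gaussian measurement noise, clipped to [0, 1].

    ``seed`` may be an int or a numpy Generator/SeedSequence; a fixed
    seed reproduces the same noisy spectrum exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Spectrum(spectrum.wavelength_nm.copy(), spectrum.absorption.copy(),
                        dict(spectrum.metadata))
    rng = np.random.default_rng(seed)
    noisy = spectrum.absorption + rng.normal(0.0, sigma, spectrum.absorption.shape)
    meta = dict(spectrum.metadata)
    meta["noise_sigma"] = sigma
    return Spectrum(spectrum.wavelength_nm.copy(), np.clip(noisy, 0.0, 1.0), meta)
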