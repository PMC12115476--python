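"""Chemometric stage: the ten-condition spectral design and mean-centered PCA.

The quantification experiment acquires absorption spectra for ten
lipid:protein loading conditions — five below the standard total amount,
(80:0), (60:20), (40:40), (20:60), (0:80), and five above, (120:0),
(90:30), (60:60), (30:90), (0:120), in arbitrary concentration units
with the standard total at 100 — on the 3000-7000 nm, 20 nm grid (201
points).  The resulting 10 x 201 matrix X is decomposed as

    X = SC . PC + u

(mean-centered covariance PCA, two retained components).  The first
score axis tracks the total amount (through the loading-induced plasmon
shift) and the second the lipid/protein composition (through the
opposite-signed vibrational signatures), so the ten spectra collapse to
ten interpretable points in the score plane.

Sign conventions are fixed deterministically: PC1 is oriented so
above-standard totals score positive, PC2 so lipid-dominant mixtures
score positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .absorber import (AbsorberConfig, CalibrationConstants, DEFAULT_CALIBRATION,
                       Spectrum, absorption_spectrum, add_noise)
from .coupling import find_extrema
from .permittivity import MixtureSpec
from .units import wavenumber_to_wavelength_nm

__all__ = [
    "SpectraDataset",
    "PCAResult",
    "ZoningReport",
    "RobustnessReport",
    "DEFAULT_DESIGN_PAIRS",
    "build_grid",
    "build_design",
    "simulate_design",
    "run_pca",
    "reconstruct",
    "interpret_scores",
    "detect_band_dips",
    "robustness_experiment",
]

#: The ten (lipid : protein) amount pairs of the default design.
DEFAULT_DESIGN_PAIRS = (
    (80, 0), (60, 20), (40, 40), (20, 60), (0, 80),
    (120, 0), (90, 30), (60, 60), (30, 90), (0, 120),
)

#: Band-center wavelengths (nm) where dips are expected.
BAND_WAVELENGTHS_NM = {
    "lipid1": wavenumber_to_wavelength_nm(2930.0),
    "lipid2": wavenumber_to_wavelength_nm(2850.0),
    "protein1": wavenumber_to_wavelength_nm(1668.0),
    "protein2": wavenumber_to_wavelength_nm(1532.0),
}


def build_grid(start_nm: float = 3000.0, stop_nm: float = 7000.0,
               step_nm: float = 20.0) -> np.ndarray:
    """Inclusive uniform wavelength grid; the default has 201 points.

    The step must divide the span exactly — no silent truncation.
    """
    if stop_nm <= start_nm:
        raise ValueError("stop must exceed start")
    if step_nm <= 0:
        raise ValueError("step must be positive")
    n_steps = (stop_nm - start_nm) / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"step {step_nm} does not divide the span {stop_nm - start_nm}")
    n = int(round(n_steps)) + 1
    return np.linspace(start_nm, stop_nm, n)


def build_design(standard_total: float = 100.0
                 ) -> list[tuple[str, MixtureSpec]]:
    """The ten labelled mixture conditions of the quantification design.

    Amounts are scaled by ``standard_total`` so that e.g. (80:0) maps to
    total c = 0.8 at lipid fraction f = 1.
    """
    if standard_total <= 0:
        raise ValueError("standard_total must be positive")
    design = []
    for lip, prot in DEFAULT_DESIGN_PAIRS:
        total = (lip + prot) / standard_total
        f = lip / (lip + prot)
        design.append((f"{lip}:{prot}", MixtureSpec(f, total)))
    return design


@dataclass
class SpectraDataset:
    """Labelled collection of spectra forming the PCA matrix X."""

    X: np.ndarray                     # conditions x grid points
    labels: list[str]
    mixtures: list[MixtureSpec]
    grid_nm: np.ndarray
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self):
        if self.X.shape[0] != len(self.labels) or self.X.shape[0] != len(self.mixtures):
            raise ValueError("rows of X must align with labels and mixtures")
        if self.X.shape[1] != self.grid_nm.size:
            raise ValueError("columns of X must match the grid")


def simulate_design(config: AbsorberConfig | None = None,
                    design: list[tuple[str, MixtureSpec]] | None = None,
                    grid_nm: np.ndarray | None = None,
                    sigma: float = 0.0, seed: int | None = None,
                    scale: float = 1.0,
                    cal: CalibrationConstants = DEFAULT_CALIBRATION
                    ) -> SpectraDataset:
    """Simulate the design's absorption spectra into a dataset.

    ``scale`` multiplies every amount (the low-concentration
    experiments); noise of standard deviation ``sigma`` is drawn from
    independent per-row substreams spawned from ``seed``.
    """
    config = config or AbsorberConfig()
    design = design if design is not None else build_design()
    grid_nm = grid_nm if grid_nm is not None else build_grid()
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    child_seeds = np.random.SeedSequence(seed).spawn(len(design))
    rows, labels, mixtures, spectra = [], [], [], []
    for (label, mix), child in zip(design, child_seeds):
        scaled = MixtureSpec(mix.lipid_fraction, mix.total_amount * scale)
        sp = absorption_spectrum(config, scaled, grid_nm, cal)
        if sigma > 0:
            sp = add_noise(sp, sigma, child)
        sp.metadata["label"] = label
        rows.append(sp.absorption)
        labels.append(label)
        mixtures.append(scaled)
        spectra.append(sp)
    return SpectraDataset(np.array(rows), labels, mixtures, grid_nm, spectra)


@dataclass
class PCAResult:
    """Mean u, orthonormal components PC, scores SC and variance fractions."""

    mean: np.ndarray                  # u, per wavelength
    components: np.ndarray            # retained_k x grid points
    scores: np.ndarray                # conditions x retained_k
    explained_variance_ratio: np.ndarray
    labels: list[str] = field(default_factory=list)


def run_pca(dataset: SpectraDataset, retained_k: int = 2,
            orient: bool = True) -> PCAResult:
    """Mean-centered (covariance) PCA of the dataset, ``retained_k`` components.

    With ``orient`` the sign ambiguity is resolved from the labels:
    above-median totals score positive on axis 1, lipid-dominant rows
    positive on axis 2 (when those axes exist).
    """
    n_rows = dataset.X.shape[0]
    if n_rows < 2:
        raise ValueError("PCA needs at least 2 rows")
    max_k = min(n_rows - 1, dataset.X.shape[1])
    if retained_k > max_k:
        raise ValueError(f"retained_k = {retained_k} exceeds the rank bound {max_k}")
    model = _SkPCA(n_components=retained_k, svd_solver="full")
    scores = model.fit_transform(dataset.X)
    components = model.components_.copy()
    result = PCAResult(model.mean_, components, scores,
                       model.explained_variance_ratio_,
                       list(dataset.labels))
    if orient:
        _orient(result, dataset.mixtures)
    return result


def _orient(result: PCAResult, mixtures) -> None:
    """Fix PCA sign ambiguity: PC1 by total amount, PC2 by lipid fraction."""
    totals = np.array([m.total_amount for m in mixtures])
    fracs = np.array([m.lipid_fraction for m in mixtures])
    keys = [totals - np.median(totals), fracs - 0.5]
    for axis, key in enumerate(keys[: result.scores.shape[1]]):
        mask_hi = key > 0
        if mask_hi.any() and (~mask_hi).any():
            if result.scores[mask_hi, axis].mean() < 0:
                result.scores[:, axis] *= -1.0
                result.components[axis] *= -1.0


def reconstruct(result: PCAResult) -> np.ndarray:
    """X_hat = SC . PC + u (exact at full retained rank)."""
    return result.scores @ result.components + result.mean


@dataclass
class ZoningReport:
    """Score-plane zoning checks of the quantification design."""

    sign_separation: bool          # (a) SC1 sign splits low/high totals
    sign_margin: float
    rank_order: dict[str, bool]    # (b) SC2 orders f within each total group
    equal_ratio_ok: bool           # (c) equal-f pairs share SC2
    equal_ratio_pairs: list[dict]  # per-pair |dSC2| / SC2 range
    sc2_range: float
    warnings: list[str] = field(default_factory=list)

    @property
    def rank_order_ok(self) -> bool:
        return all(self.rank_order.values())


def interpret_scores(result: PCAResult, mixtures,
                     equal_ratio_tol: float = 0.10) -> ZoningReport:
    """Verify the score-plane zoning of the ten-condition design.

    (a) the first score's sign separates below- from above-standard
    totals, (b) within each total group the second score rank-orders
    the lipid fraction, (c) pairs with equal f across the two groups
    have |delta SC2| below ``equal_ratio_tol`` of the SC2 range.
    """
    if result.scores.shape[1] < 2:
        raise ValueError("zoning needs at least two score axes")
    sc1, sc2 = result.scores[:, 0], result.scores[:, 1]
    totals = np.array([m.total_amount for m in mixtures])
    fracs = np.array([m.lipid_fraction for m in mixtures])
    warnings = []
    for axis, sc in (("SC1", sc1), ("SC2", sc2)):
        if np.ptp(sc) == 0:
            warnings.append(f"{axis} has zero variance: uninformative axis")

    med = np.median(totals)
    low, high = totals < med, totals > med
    sign_sep = bool(np.all(sc1[low] < 0) and np.all(sc1[high] > 0))
    margin = float(sc1[high].min() - sc1[low].max()) if low.any() and high.any() else 0.0

    rank_order = {}
    for name, mask in (("low", low), ("high", high)):
        if mask.sum() >= 2:
            order_f = np.argsort(fracs[mask], kind="stable")
            order_sc = np.argsort(sc2[mask], kind="stable")
            rank_order[name] = bool(np.array_equal(order_f, order_sc))

    sc2_range = float(np.ptp(sc2))
    pairs = []
    ok = True
    for f in np.unique(fracs):
        idx_low = np.flatnonzero(low & (fracs == f))
        idx_high = np.flatnonzero(high & (fracs == f))
        for i in idx_low:
            for j in idx_high:
                frac_of_range = (abs(sc2[i] - sc2[j]) / sc2_range
                                 if sc2_range > 0 else 0.0)
                within = frac_of_range <= equal_ratio_tol
                ok = ok and within
                pairs.append({
                    "rows": (result.labels[i] if result.labels else int(i),
                             result.labels[j] if result.labels else int(j)),
                    "lipid_fraction": float(f),
                    "delta_sc2_fraction": float(frac_of_range),
                    "within_tolerance": bool(within),
                })
    return ZoningReport(sign_sep, margin, rank_order, ok, pairs, sc2_range,
                        warnings)


def detect_band_dips(spectrum: Spectrum, mix: MixtureSpec,
                     tolerance_nm: float = 60.0,
                     **extrema_kwargs) -> dict[str, bool]:
    """Which of the expected vibrational dips are detected in a spectrum.

    Only bands of analytes actually present (nonzero amount) are
    expected; each must show a dip within ``tolerance_nm`` of its band
    center.
    """
    res = find_extrema(spectrum, **extrema_kwargs)
    dip_pos = np.array([d.position_nm for d in res.dips]) if res.dips else np.array([])
    out = {}
    for name, lam in BAND_WAVELENGTHS_NM.items():
        amount = mix.lipid_amount if name.startswith("lipid") else mix.protein_amount
        if amount <= 0:
            continue
        found = bool(dip_pos.size and np.min(np.abs(dip_pos - lam)) <= tolerance_nm)
        out[name] = found
    return out


@dataclass
class RobustnessReport:
    """Low-concentration / noise rerun of the full pipeline."""

    scale: float
    sigma: float
    per_seed: list[dict]

    @property
    def all_dips_detected(self) -> bool:
        return all(s["dips_all_detected"] for s in self.per_seed)

    @property
    def zoning_holds(self) -> bool:
        return all(s["sign_separation"] and s["rank_order_ok"]
                   for s in self.per_seed)


def robustness_experiment(scale: float, sigma: float, seeds,
                          config: AbsorberConfig | None = None,
                          cal: CalibrationConstants = DEFAULT_CALIBRATION,
                          equal_ratio_tol: float = 0.10,
                          **extrema_kwargs) -> RobustnessReport:
    """Rerun the design with all amounts scaled down and noise added.

    Reports, per seed, whether every expected dip is still detected and
    whether the zoning criteria (a)-(b) of the score plane still hold.
    """
    seeds = list(seeds)
    per_seed = []
    for seed in seeds:
        ds = simulate_design(config=config, sigma=sigma, seed=seed,
                             scale=scale, cal=cal)
        dips_ok = []
        for sp, mix in zip(ds.spectra, ds.mixtures):
            found = detect_band_dips(sp, mix, **extrema_kwargs)
            dips_ok.append(all(found.values()))
        result = run_pca(ds)
        zoning = interpret_scores(result, ds.mixtures, equal_ratio_tol)
        per_seed.append({
            "seed": seed,
            "dips_per_spectrum": dips_ok,
            "dips_all_detected": all(dips_ok),
            "sign_separation": zoning.sign_separation,
            "rank_order_ok": zoning.rank_order_ok,
            "equal_ratio_ok": zoning.equal_ratio_ok,
        })
    return RobustnessReport(scale, sigma, per_seed)
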