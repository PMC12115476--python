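import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seiralab.absorber import (ANCHOR_WAVELENGTH_NM, AbsorberConfig,
                               CalibrationConstants, MolecularOscillator,
                               PlasmonMode, Spectrum, absorption_spectrum,
                               add_noise, angle_sweep, band_modulation_depth,
                               build_modes, calibrate_scaling_law,
                               coupling_strengths, default_scaling_laws,
                               detune_by_loading, fraction_sweep, length_sweep,
                               plasmon_center_wavelength_nm,
                               reflection_coefficient)
from seiralab.coupling import find_extrema
from seiralab.pca import BAND_WAVELENGTHS_NM, build_grid
from seiralab.permittivity import LIPID, MixtureSpec
from seiralab.units import wavelength_to_energy_mev


class TestScalingLaw:
    def test_exact_through_endpoints(self):
        for mode, arm in (("P1", "short"), ("P2", "long")):
            law = default_scaling_laws()[mode]
            from seiralab.absorber import SCALING_ENDPOINTS, effective_arm_length
            for L, lam in SCALING_ENDPOINTS[mode]:
                eff = effective_arm_length(L, 0.265, arm)
                assert law.wavelength_um(eff) == pytest.approx(lam, rel=1e-12)

    def test_p1_fitted_constants(self):
        law = calibrate_scaling_law((1.23, 3.16), (1.43, 3.79), "short")
        assert law.n_eff == pytest.approx(3.15, rel=1e-12)
        assert law.C_um == pytest.approx(3.16 - 2 * (1.23 / 2 - 0.265) * 3.15,
                                         rel=1e-12)
        # reference length falls mid-sweep: the linear law reads 3.475 um
        # there (the anchored model pins 3.450 um instead)
        assert law.wavelength_um(1.33 / 2 - 0.265) == pytest.approx(3.475,
                                                                    abs=1e-3)

    def test_singular_fit_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scaling_law((1.33, 3.4), (1.33, 3.5), "short")


class TestDetuning:
    def test_standard_amount_is_anchor(self, config, cal):
        for mode in ("P1", "P2"):
            lam = plasmon_center_wavelength_nm(mode, 1.33, 1.0, cal)
            assert lam == pytest.approx(ANCHOR_WAVELENGTH_NM[mode])

    def test_shift_symmetric_about_standard(self, cal):
        hi = plasmon_center_wavelength_nm("P1", 1.33, 1.5, cal)
        lo = plasmon_center_wavelength_nm("P1", 1.33, 0.5, cal)
        anchor = ANCHOR_WAVELENGTH_NM["P1"]
        assert hi - anchor == pytest.approx(anchor - lo)
        assert hi > anchor > lo  # red above standard, blue below

    def test_detune_by_loading_example(self):
        mode = PlasmonMode("P1", wavelength_to_energy_mev(3450.0), 3.0, 3.0)
        shifted = detune_by_loading(mode, 1.25, sensitivity_nm=120.0)
        lam = 1.239841984e6 / shifted.center_energy_mev
        assert lam == pytest.approx(3480.0, abs=1e-9)
        assert detune_by_loading(mode, 1.0, 120.0) == mode


class TestCouplingStrengths:
    def test_zero_amount_gives_zero(self):
        gs = coupling_strengths(0.0, 10.0, LIPID.bands)
        assert gs == [0.0, 0.0]

    def test_sqrt_scaling(self):
        g1 = coupling_strengths(1.0, 10.0, LIPID.bands)
        g4 = coupling_strengths(4.0, 10.0, LIPID.bands)
        assert g4 == pytest.approx([2 * g for g in g1])

    def test_half_amount(self):
        gs = coupling_strengths(0.5, 10.0, LIPID.bands)
        assert gs[0] == pytest.approx(10.0 * np.sqrt(0.5))

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            coupling_strengths(-0.1, 10.0, LIPID.bands)


class TestAbsorption:
    def test_critical_coupling_unity_at_center(self):
        mode = PlasmonMode("P1", 360.0, 3.0, 3.0)
        r = reflection_coefficient(np.array([360.0]), [mode])
        assert 1 - abs(r[0]) ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_rate_mismatch_lowers_peak(self):
        mode = PlasmonMode("P1", 360.0, 5.0, 2.0)
        r = reflection_coefficient(np.array([360.0]), [mode])
        assert 1 - abs(r[0]) ** 2 < 1.0

    def test_pure_lipid_dips_near_band_centers(self, config, cal):
        sp = absorption_spectrum(config, MixtureSpec(1.0, 1.0), cal=cal)
        res = find_extrema(sp)
        dips = np.array([d.position_nm for d in res.dips])
        step = sp.grid_step_nm
        for band in ("lipid1", "lipid2"):
            lam = BAND_WAVELENGTHS_NM[band]
            assert np.min(np.abs(dips - lam)) <= 1.5 * step
        # protein region featureless without protein
        for band in ("protein1", "protein2"):
            lam = BAND_WAVELENGTHS_NM[band]
            assert np.min(np.abs(dips - lam)) > 60.0

    def test_single_mode_passivity_exact(self):
        # one port-coupled mode with lossy molecular self-energy is
        # strictly passive for any rates
        rng = np.random.default_rng(7)
        energy = np.linspace(150.0, 450.0, 1500)
        for _ in range(300):
            mode = PlasmonMode("P1", rng.uniform(200, 400),
                               rng.uniform(0.1, 15.0), rng.uniform(0.1, 15.0))
            osc = {"P1": [MolecularOscillator(rng.uniform(200, 400),
                                              rng.uniform(0.1, 10.0),
                                              rng.uniform(0.0, 20.0))]}
            a = 1 - np.abs(reflection_coefficient(energy, [mode], osc)) ** 2
            assert a.min() >= -1e-12 and a.max() <= 1 + 1e-12

    def test_energy_bound_on_random_device_draws(self, cal):
        # random physical settings of the device: geometry, mixture,
        # loading and angle
        rng = np.random.default_rng(8)
        grid = build_grid(2500.0, 7500.0, 10.0)
        for _ in range(100):
            cfg = AbsorberConfig(L=rng.uniform(1.23, 1.43),
                                 theta=rng.uniform(0.0, 60.0))
            mix = MixtureSpec(rng.uniform(0.0, 1.0), rng.uniform(0.0, 1.5))
            sp = absorption_spectrum(cfg, mix, grid, cal)
            assert sp.absorption.min() >= 0.0
            assert sp.absorption.max() <= 1.0

    def test_far_detuned_additivity(self):
        # the one-port superposition error scales like gamma_rad / mode
        # separation; with narrow modes ~160 meV apart the two-mode
        # spectrum equals the sum of singles to better than 1% of peak
        grid = build_grid(3000.0, 7000.0, 5.0)
        energy = wavelength_to_energy_mev(grid)
        m1 = PlasmonMode("P1", 360.0, 0.3, 0.3)
        m2 = PlasmonMode("P2", 197.0, 0.15, 0.15)
        both = 1 - np.abs(reflection_coefficient(energy, [m1, m2])) ** 2
        single = sum(1 - np.abs(reflection_coefficient(energy, [m])) ** 2
                     for m in (m1, m2))
        assert np.max(np.abs(both - single)) < 0.01 * both.max()

    def test_grid_outside_validated_range_warns(self, config):
        with pytest.warns(UserWarning):
            absorption_spectrum(config, None, np.linspace(1500, 2500, 50))


class TestSweeps:
    def test_length_sweep_red_shifts_both_modes(self, config, cal):
        # bare device (vacuum): both modes sit blue of the anchors, so
        # use a wider grid that covers the full swept range
        grid = build_grid(2500.0, 7500.0, 5.0)
        sweep = length_sweep(config, None, np.linspace(1.23, 1.43, 5), grid, cal)
        p1_pos, p2_pos = [], []
        for sp in sweep:
            peaks = sorted(find_extrema(sp).peaks, key=lambda p: p.position_nm)
            assert len(peaks) >= 2
            p1_pos.append(peaks[0].position_nm)
            p2_pos.append(peaks[-1].position_nm)
        assert np.all(np.diff(p1_pos) > 0)
        assert np.all(np.diff(p2_pos) > 0)

    def test_fraction_sweep_f0_has_no_lipid_dips(self, config, cal):
        sweep = fraction_sweep(config, [0.0, 1.0], 1.0, cal=cal)
        dips_f0 = [d.position_nm for d in find_extrema(sweep[0]).dips]
        for band in ("lipid1", "lipid2"):
            lam = BAND_WAVELENGTHS_NM[band]
            assert not dips_f0 or min(abs(p - lam) for p in dips_f0) > 60.0

    def test_angle_sweep_absorption_stays_high(self, config, cal):
        sweep = angle_sweep(config, None, np.arange(0.0, 61.0, 10.0), cal=cal)
        for sp in sweep:
            assert sp.absorption.max() >= 0.90

    def test_empty_parameter_list_rejected(self, config):
        with pytest.raises(ValueError):
            length_sweep(config, None, [])


class TestSpectrumAndNoise:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([3000.0, 2990.0, 3020.0]), np.zeros(3))

    def test_sigma_zero_is_identity(self, config):
        sp = absorption_spectrum(config, None)
        noisy = add_noise(sp, 0.0, 1)
        np.testing.assert_array_equal(noisy.absorption, sp.absorption)

    def test_same_seed_reproduces(self, config):
        sp = absorption_spectrum(config, None)
        a = add_noise(sp, 0.01, 42)
        b = add_noise(sp, 0.01, 42)
        np.testing.assert_array_equal(a.absorption, b.absorption)
        c = add_noise(sp, 0.01, 43)
        assert not np.array_equal(a.absorption, c.absorption)

    def test_noise_magnitude_and_clipping(self, config):
        sp = absorption_spectrum(config, MixtureSpec(0.5, 1.0))
        noisy = add_noise(sp, 0.01, 5)
        interior = (sp.absorption > 0.05) & (sp.absorption < 0.95)
        sd = np.std(noisy.absorption[interior] - sp.absorption[interior], ddof=1)
        assert 0.007 <= sd <= 0.013    # chi-square bounds at n ~ 201
        assert noisy.absorption.min() >= 0.0
        assert noisy.absorption.max() <= 1.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.floats(min_value=0.05, max_value=0.45),
       st.floats(min_value=0.0, max_value=89.0))
def test_config_validation_bounds(s, theta):
    cfg = AbsorberConfig(s=s, theta=theta)
    assert 0 < cfg.s < cfg.L / 2


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        AbsorberConfig(s=0.7)
    with pytest.raises(ValueError):
        AbsorberConfig(theta=95.0)


class TestModulationDepth:
    def test_lipid_depth_nondecreasing_in_f(self, config, cal):
        lam = BAND_WAVELENGTHS_NM["lipid1"]
        depths = [band_modulation_depth(config, MixtureSpec(f, 1.0), lam, cal)
                  for f in np.arange(0.0, 1.001, 0.1)]
        # only the far protein tails reach the lipid band at f = 0
        assert depths[0] == pytest.approx(0.0, abs=2e-3)
        assert np.all(np.diff(depths) >= -1e-9)

    def test_protein_depth_vanishes_without_protein(self, config, cal):
        lam = BAND_WAVELENGTHS_NM["protein1"]
        d0 = band_modulation_depth(config, MixtureSpec(1.0, 1.0), lam, cal)
        d1 = band_modulation_depth(config, MixtureSpec(0.0, 1.0), lam, cal)
        # only the far Lorentz tail of the lipid bands reaches 6 um
        assert d0 == pytest.approx(0.0, abs=2e-3)
        assert abs(d1) > 0.01
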