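"""Thin-film optics: Fresnel/Airy oracles, dispersion sanity, SPR dip."""

import numpy as np
import pytest

from plasmoncam import optics
from plasmoncam.exceptions import ConfigurationError, RangeError
from plasmoncam.optics import (
    NIR_BAND,
    VIS_BAND,
    LayerStack,
    SensorGeometry,
    SpectralBand,
    TransmissionSpectrum,
    band_intensity,
    fiber_transmission,
    metal_permittivity,
    resonance_wavelength,
    stack_reflectance,
)


# ---------------------------------------------------------------- dispersion
class TestMetalPermittivity:
    def test_drude_limit_low_frequency(self):
        """With damping off, eps -> eps_inf - wp^2/w^2 and Im eps -> 0."""
        params = {"Au": (9.0, 9.02, 0.0)}
        wl = 1200.0
        w = 1239.841984 / wl
        eps = metal_permittivity(wl, "Au", params)
        assert eps.imag == pytest.approx(0.0)
        assert eps.real == pytest.approx(9.0 - 9.02**2 / w**2)

    def test_gold_matches_tabulated_values(self):
        """Drude gold vs. tabulated optical constants (~-16.5 at 700 nm)."""
        eps = metal_permittivity(700.0, "Au")
        assert eps.real < -10.0
        assert abs(eps.real - (-16.5)) / 16.5 < 0.30

    def test_chromium_absorbs(self):
        assert metal_permittivity(633.0, "Cr").imag > 0.0

    def test_unknown_material_rejected(self):
        with pytest.raises(ConfigurationError):
            metal_permittivity(633.0, "Pt")


# ------------------------------------------------------------- reflectance
def _fresnel_rp(n0: float, n1: float, angle_deg: float) -> float:
    """Two-medium p-polarization power reflectance (closed form)."""
    theta = np.radians(angle_deg)
    s = n0 * np.sin(theta) / n1
    cos_t = np.sqrt(complex(1.0 - s**2))
    r = (n1 * np.cos(theta) - n0 * cos_t) / (n1 * np.cos(theta) + n0 * cos_t)
    return float(abs(r) ** 2)


def _airy_rp(wavelength: float, angle_deg: float, n0: float, eps_film: complex,
             d_nm: float, n2: float) -> float:
    """Independent three-medium (Airy summation) p reflectance for one film."""
    k0 = 2 * np.pi / wavelength
    kx = n0 * np.sin(np.radians(angle_deg)) * k0

    def kz(eps):
        v = np.sqrt(complex(eps * k0**2 - kx**2))
        return -v if v.imag < 0 else v

    def rp(eps_i, eps_j):
        kzi, kzj = kz(eps_i), kz(eps_j)
        return (eps_j * kzi - eps_i * kzj) / (eps_j * kzi + eps_i * kzj)

    e0, e1, e2 = complex(n0**2), eps_film, complex(n2**2)
    r01, r12 = rp(e0, e1), rp(e1, e2)
    phase = np.exp(2j * kz(e1) * d_nm)
    r = (r01 + r12 * phase) / (1 + r01 * r12 * phase)
    return float(abs(r) ** 2)


class TestStackReflectance:
    def test_index_matched_normalish_incidence(self):
        stack = LayerStack(substrate_index=1.4, layers=(), analyte_index=1.4)
        assert stack_reflectance(633.0, 1e-6, stack) == pytest.approx(0.0, abs=1e-10)

    def test_total_internal_reflection(self):
        stack = LayerStack(substrate_index=1.457, layers=(), analyte_index=1.333)
        assert stack_reflectance(633.0, 80.0, stack) == pytest.approx(1.0, abs=1e-12)

    def test_fresnel_reduction_without_metals(self):
        """No films: transfer matrix equals the two-medium Fresnel formula."""
        stack = LayerStack(substrate_index=1.457, layers=(), analyte_index=1.333)
        for wl in np.linspace(300, 1200, 10):
            for ang in np.linspace(5, 85, 10):
                got = stack_reflectance(wl, ang, stack)
                assert got == pytest.approx(_fresnel_rp(1.457, 1.333, ang), abs=1e-12)

    def test_airy_oracle_single_gold_film(self):
        """Transfer matrix vs. independently coded Airy summation, 1e-8."""
        stack = LayerStack(substrate_index=1.457, layers=(("Au", 50.0),), analyte_index=1.333)
        for wl in np.linspace(400, 1100, 15):
            eps = metal_permittivity(wl, "Au")
            for ang in (45.0, 70.0, 78.0, 85.0):
                got = stack_reflectance(float(wl), ang, stack)
                want = _airy_rp(float(wl), ang, 1.457, eps, 50.0, 1.333)
                assert got == pytest.approx(want, abs=1e-8)

    def test_energy_bounds(self):
        stack = LayerStack()
        rng = np.random.default_rng(0)
        for _ in range(50):
            wl = rng.uniform(300, 1200)
            ang = rng.uniform(1, 89)
            r = stack_reflectance(wl, ang, stack)
            assert 0.0 <= r <= 1.0

    def test_spr_dip_exists_and_unique(self):
        """Fine wavelength scan at one angle: single pronounced minimum."""
        stack = LayerStack(analyte_index=1.33)
        wl = np.arange(500.0, 900.0, 1.0)
        r = stack_reflectance(wl, 78.0, stack)
        i = int(np.argmin(r))
        assert 0 < i < len(wl) - 1
        assert r[0] - r[i] > 0.1 and r[-1] - r[i] > 0.1
        # unique: strictly below everything outside a +/- 60 nm neighbourhood
        outside = np.abs(wl - wl[i]) > 60
        assert r[i] < r[outside].min() - 0.05

    def test_angle_domain_validated(self):
        with pytest.raises(ConfigurationError):
            stack_reflectance(633.0, 90.0, LayerStack())


# ---------------------------------------------------------- fiber transmission
class TestFiberTransmission:
    def test_unit_reflectance_gives_unit_transmission(self):
        """Bare TIR interface (no metals): R = 1 so T = 1 at every wavelength."""
        stack = LayerStack(substrate_index=1.457, layers=(), analyte_index=1.0)
        spectrum = fiber_transmission(stack, SensorGeometry())
        assert np.allclose(spectrum.transmittance, 1.0, atol=1e-12)

    def test_single_angle_single_reflection(self):
        """With N = 1 the model reduces to T = (R_p + 1) / 2 exactly."""
        angle = 75.0
        core_um = 400.0
        length_mm = core_um * np.tan(np.radians(angle)) / 1000.0
        geom = SensorGeometry(core_diameter=core_um, sensing_length=length_mm, angle_grid=(angle,))
        stack = LayerStack()
        wl = np.arange(500.0, 801.0, 50.0)
        spectrum = fiber_transmission(stack, geom, wl)
        want = (stack_reflectance(wl, angle, stack) + 1.0) / 2.0
        assert np.allclose(spectrum.transmittance, want, atol=1e-12)

    def test_dip_redshifts_with_ri(self):
        """Resonance wavelength strictly increases with the analyte RI."""
        geom = SensorGeometry()
        dips = [
            resonance_wavelength(fiber_transmission(LayerStack(analyte_index=ri), geom))
            for ri in (1.323, 1.33, 1.34, 1.347, 1.356)
        ]
        assert all(a < b for a, b in zip(dips, dips[1:]))

    def test_transmission_bounded(self):
        spectrum = fiber_transmission(LayerStack(), SensorGeometry())
        assert spectrum.transmittance.min() >= 0.0
        assert spectrum.transmittance.max() <= 1.0

    def test_empty_angle_grid_rejected(self):
        geom = SensorGeometry()
        object.__setattr__(geom, "angle_grid", ())  # bypass auto-fill
        with pytest.raises(ConfigurationError):
            fiber_transmission(LayerStack(), geom)

    def test_angles_below_critical_angle_rejected(self):
        geom = SensorGeometry(angle_grid=(50.0, 80.0))  # 50 deg < critical angle
        with pytest.raises(ConfigurationError):
            fiber_transmission(LayerStack(analyte_index=1.333), geom)

    def test_wavelengths_outside_domain_rejected(self):
        with pytest.raises(RangeError):
            fiber_transmission(LayerStack(), SensorGeometry(), np.array([200.0, 500.0]))


# ----------------------------------------------------------------- bands
class TestBandIntensity:
    def test_flat_half_transmission(self):
        wl = np.arange(300.0, 1201.0, 1.0)
        sp = TransmissionSpectrum(wl, np.full_like(wl, 0.5))
        assert band_intensity(sp, VIS_BAND) == pytest.approx(0.5)

    def test_unit_transmission(self):
        wl = np.arange(300.0, 1201.0, 1.0)
        sp = TransmissionSpectrum(wl, np.ones_like(wl))
        assert band_intensity(sp, NIR_BAND) == pytest.approx(1.0)

    def test_band_outside_grid_rejected(self):
        wl = np.arange(400.0, 701.0, 1.0)
        sp = TransmissionSpectrum(wl, np.ones_like(wl))
        with pytest.raises(RangeError):
            band_intensity(sp, NIR_BAND)

    def test_ri_sensitivity_of_both_bands(self):
        """1.323 vs 1.356: both band intensities shift by > 0.1 % relative."""
        geom = SensorGeometry()
        lo = fiber_transmission(LayerStack(analyte_index=1.323), geom)
        hi = fiber_transmission(LayerStack(analyte_index=1.356), geom)
        for band in (VIS_BAND, NIR_BAND):
            a, b = band_intensity(lo, band), band_intensity(hi, band)
            assert abs(a - b) / a > 0.001

    def test_invalid_band_tag(self):
        with pytest.raises(ConfigurationError):
            SpectralBand(300.0, 700.0, "UV")
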