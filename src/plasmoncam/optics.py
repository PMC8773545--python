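"""Thin-film optics forward model for a gold-coated fiber SPR sensor.

The sensing element is a multimode silica fiber whose cladding has been
stripped over a short length and replaced by a Cr adhesion layer, a gold
film and the external analyte.  p-polarized rays guided above the critical
angle excite a surface plasmon at the gold/analyte interface, producing a
wavelength-dependent absorption dip in the transmitted power whose position
shifts to the red as the analyte refractive index (RI) rises.

The model is a classical ray/transfer-matrix hybrid:

* metal permittivities follow a three-parameter Drude dispersion
  ``eps(w) = eps_inf - wp**2 / (w**2 + i*gamma*w)``;
* the planar stack silica / Cr / Au / analyte is solved with the standard
  2x2 characteristic-matrix method for p polarization;
* a guided ray at internal incidence angle ``theta`` undergoes
  ``N(theta) = L / (D * tan(theta))`` reflections over a sensing length
  ``L`` and core diameter ``D``, so its p-power transmission is
  ``R_p(lambda, theta) ** N``;
* unpolarized launch is modelled as an equal split between p rays and
  lossless s rays, ``T = (R_p**N + 1) / 2``, averaged over a meridional
  ray-power distribution truncated to the fiber numerical aperture.

Skew rays, cladding modes and vector-mode effects are outside the model;
only the existence of the resonance dip and the direction of its shift
with RI are claimed quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, RangeError

__all__ = [
    "DRUDE_PARAMETERS",
    "LayerStack",
    "SensorGeometry",
    "SpectralBand",
    "TransmissionSpectrum",
    "VIS_BAND",
    "NIR_BAND",
    "metal_permittivity",
    "stack_reflectance",
    "fiber_transmission",
    "angular_band_transmission",
    "band_intensity",
    "resonance_wavelength",
    "default_wavelength_grid",
]

# h*c in eV*nm, to convert vacuum wavelength to photon energy.
_HC_EV_NM = 1239.841984

#: Drude parameters (eps_inf, plasma energy eV, damping energy eV) per metal.
#: Literature free-electron fits; gold reproduces tabulated optical
#: constants to a few tens of percent above ~550 nm (and makes the
#: VIS-band response mildly non-monotone in analyte RI, so distinct RIs
#: can share a VIS brightness, as observed on the physical sensor);
#: chromium is a coarse absorbing proxy (a 5 nm adhesion layer, so its
#: dispersion barely matters).
DRUDE_PARAMETERS: dict[str, tuple[float, float, float]] = {
    "Au": (9.0, 9.02, 0.027),
    "Cr": (3.0, 6.7, 1.4),
}

#: Detection bands of the dual CMOS camera (nm).
VIS_RANGE = (300.0, 700.0)
NIR_RANGE = (700.0, 1200.0)


@dataclass(frozen=True)
class SpectralBand:
    """A detection band ``[low, high]`` in nm with a ``tag`` of VIS or NIR."""

    low: float
    high: float
    tag: str

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(f"band low must be < high, got {self.low}..{self.high}")
        if self.tag not in ("VIS", "NIR"):
            raise ConfigurationError(f"band tag must be VIS or NIR, got {self.tag!r}")


VIS_BAND = SpectralBand(*VIS_RANGE, "VIS")
NIR_BAND = SpectralBand(*NIR_RANGE, "NIR")


@dataclass(frozen=True)
class LayerStack:
    """Planar thin-film stack seen by a guided ray.

    Parameters
    ----------
    substrate_index : float
        Real RI of the silica core (dispersion-free).
    layers : tuple of (material tag, thickness in nm)
        Ordered metal films between core and analyte.  Default Cr 5 nm /
        Au 50 nm.
    analyte_index : float
        Real RI of the external medium, in refractive index units (RIU).
    """

    substrate_index: float = 1.457
    layers: tuple[tuple[str, float], ...] = (("Cr", 5.0), ("Au", 50.0))
    analyte_index: float = 1.333

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple((str(m), float(d)) for m, d in self.layers))
        for material, thickness in self.layers:
            if thickness <= 0:
                raise ConfigurationError(f"layer {material!r} thickness must be > 0 nm, got {thickness}")
            if material not in DRUDE_PARAMETERS:
                raise ConfigurationError(f"unknown layer material {material!r}")
        if not 1.0 <= self.analyte_index <= 1.6:
            raise ConfigurationError(f"analyte index {self.analyte_index} outside [1.0, 1.6]")

    def with_analyte(self, analyte_index: float) -> "LayerStack":
        """Copy of the stack with a different external RI."""
        return LayerStack(self.substrate_index, self.layers, float(analyte_index))

    def critical_angle(self) -> float:
        """Critical angle (deg) for total internal reflection against the analyte."""
        return float(np.degrees(np.arcsin(self.analyte_index / self.substrate_index)))


@dataclass(frozen=True)
class SensorGeometry:
    """Ray-optics geometry of the stripped sensing region.

    ``angle_grid`` holds internal incidence angles in degrees, measured from
    the normal of the core/film interface.  Guided rays satisfy
    ``90 - arcsin(NA / n_core) <= theta < 90``; the default grid spans that
    acceptance cone for NA 0.37 and silica.
    """

    core_diameter: float = 400.0  # um
    sensing_length: float = 10.0  # mm
    numerical_aperture: float = 0.37
    angle_grid: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.core_diameter <= 0 or self.sensing_length <= 0:
            raise ConfigurationError("core_diameter and sensing_length must be > 0")
        if not 0 < self.numerical_aperture < 1:
            raise ConfigurationError("numerical_aperture must lie in (0, 1)")
        if not self.angle_grid:
            object.__setattr__(self, "angle_grid", self._default_grid())
        object.__setattr__(self, "angle_grid", tuple(float(a) for a in self.angle_grid))
        if any(not 0 < a < 90 for a in self.angle_grid):
            raise ConfigurationError("angle_grid entries must lie strictly in (0, 90) deg")

    def _default_grid(self, n_core: float = 1.457, n_angles: int = 25) -> tuple[float, ...]:
        theta_min = 90.0 - float(np.degrees(np.arcsin(self.numerical_aperture / n_core)))
        return tuple(np.linspace(theta_min + 0.1, 89.6, n_angles))

    def reflections(self, angle_deg: np.ndarray | float) -> np.ndarray | float:
        """Number of film reflections ``N = L / (D tan(theta))`` for a ray."""
        length_um = self.sensing_length * 1000.0
        return length_um / (self.core_diameter * np.tan(np.radians(angle_deg)))

    def angle_weights(self) -> np.ndarray:
        """Meridional ray-power weights ``w ∝ sin(theta) cos(theta)``, normalized."""
        theta = np.radians(np.asarray(self.angle_grid))
        w = np.sin(theta) * np.cos(theta)
        return w / w.sum()


@dataclass(frozen=True)
class TransmissionSpectrum:
    """Transmittance on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        if wl.ndim != 1 or wl.shape != t.shape:
            raise ConfigurationError("wavelengths and transmittance must be equal-length 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "transmittance", t)

    def to_csv(self, path) -> None:
        """Write (wavelength_nm, transmittance) as a two-column CSV."""
        import pandas as pd

        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "transmittance": self.transmittance}
        ).to_csv(path, index=False)


def default_wavelength_grid() -> np.ndarray:
    """1 nm grid over the camera's 300-1200 nm sensitivity window."""
    return np.arange(300.0, 1200.0 + 0.5, 1.0)


def metal_permittivity(
    wavelength: np.ndarray | float,
    material: str,
    parameters: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray | complex:
    """Complex relative permittivity of a metal film at ``wavelength`` (nm).

    Drude model ``eps = eps_inf - wp**2 / (w**2 + 1j*gamma*w)`` with photon
    energies in eV.  The sign convention is absorbing: ``Im(eps) > 0``.

    Raises
    ------
    ConfigurationError
        If ``material`` has no configured Drude parameters.
    """
    params = parameters if parameters is not None else DRUDE_PARAMETERS
    try:
        eps_inf, wp, gamma = params[material]
    except KeyError:
        raise ConfigurationError(f"unknown metal material {material!r}") from None
    w = _HC_EV_NM / np.asarray(wavelength, dtype=float)
    eps = eps_inf - wp**2 / (w**2 + 1j * gamma * w)
    return complex(eps) if np.isscalar(wavelength) else eps


def _kz(eps: np.ndarray | complex, k0: np.ndarray | float, kx: np.ndarray | float) -> np.ndarray:
    """Normal wavevector component with the decaying branch (Im >= 0)."""
    kz = np.sqrt(np.asarray(eps * k0**2 - kx**2, dtype=complex))
    return np.where(kz.imag < 0, -kz, kz)


def stack_reflectance(
    wavelength: np.ndarray | float,
    angle: float,
    stack: LayerStack,
    parameters: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray | float:
    """p-polarization power reflectance of the stack at internal ``angle`` (deg).

    Characteristic-matrix (transfer-matrix) solution for the planar stack
    core / films / analyte.  With an empty film list the expression reduces
    exactly to the two-medium Fresnel formula, returning 1 beyond the
    critical angle (total internal reflection) rather than raising.

    Parameters
    ----------
    wavelength : float or array
        Vacuum wavelength(s) in nm; vectorized.
    angle : float
        Internal incidence angle in degrees, strictly inside (0, 90).
    stack : LayerStack
    """
    if not 0.0 < angle < 90.0:
        raise ConfigurationError(f"incidence angle must lie strictly in (0, 90) deg, got {angle}")
    wl = np.asarray(wavelength, dtype=float)
    scalar = wl.ndim == 0
    wl = np.atleast_1d(wl)

    k0 = 2.0 * np.pi / wl
    n0 = stack.substrate_index
    eps0 = complex(n0**2)
    eps_sub = complex(stack.analyte_index**2)
    kx = n0 * np.sin(np.radians(angle)) * k0

    kz0 = _kz(eps0, k0, kx)
    kzs = _kz(eps_sub, k0, kx)
    q0 = kz0 / eps0  # p-polarization admittance
    qs = kzs / eps_sub

    # Characteristic matrix product over the films.
    m00 = np.ones_like(wl, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for material, thickness in stack.layers:
        eps = metal_permittivity(wl, material, parameters)
        kz = _kz(eps, k0, kx)
        q = kz / eps
        delta = kz * thickness
        c, s = np.cos(delta), np.sin(delta)
        a00, a01 = c, -1j * s / q
        a10, a11 = -1j * q * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )

    num = (m00 + m01 * qs) * q0 - (m10 + m11 * qs)
    den = (m00 + m01 * qs) * q0 + (m10 + m11 * qs)
    r = num / den
    reflectance = np.clip(np.abs(r) ** 2, 0.0, 1.0)
    return float(reflectance[0]) if scalar else reflectance


def _per_angle_transmission(
    stack: LayerStack,
    geometry: SensorGeometry,
    wavelengths: np.ndarray,
    parameters: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Unpolarized single-ray transmission, shape (n_angles, n_wavelengths)."""
    t = np.empty((len(geometry.angle_grid), len(wavelengths)))
    for i, angle in enumerate(geometry.angle_grid):
        r_p = stack_reflectance(wavelengths, angle, stack, parameters)
        t[i] = (r_p ** geometry.reflections(angle) + 1.0) / 2.0
    return t


def fiber_transmission(
    stack: LayerStack,
    geometry: SensorGeometry,
    wavelengths: np.ndarray | None = None,
    parameters: dict[str, tuple[float, float, float]] | None = None,
) -> TransmissionSpectrum:
    """Transmission spectrum of the sensing region under unpolarized launch.

    ``T(lambda) = sum_theta w(theta) * (R_p(lambda, theta)**N(theta) + 1) / 2``
    with ``N(theta) = L / (D tan(theta))``.  The s component is treated as
    lossless (reflectance 1): s rays do not excite the plasmon, so their
    only effect is a constant intensity offset shared by all analytes.

    Raises
    ------
    ConfigurationError
        If the angle grid is empty or any angle does not exceed the
        analyte's critical angle.
    RangeError
        If wavelengths stray outside the 300-1200 nm model domain.
    """
    if wavelengths is None:
        wavelengths = default_wavelength_grid()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if len(geometry.angle_grid) == 0:
        raise ConfigurationError("angle grid is empty")
    if wavelengths.min() < 300.0 or wavelengths.max() > 1200.0:
        raise RangeError("wavelengths must lie within [300, 1200] nm")
    theta_c = stack.critical_angle()
    if min(geometry.angle_grid) <= theta_c:
        raise ConfigurationError(
            f"all angles must exceed the critical angle {theta_c:.2f} deg for analyte "
            f"{stack.analyte_index}"
        )

    weights = geometry.angle_weights()
    per_angle = _per_angle_transmission(stack, geometry, wavelengths, parameters)
    transmittance = weights @ per_angle
    return TransmissionSpectrum(wavelengths, np.clip(transmittance, 0.0, 1.0))


def angular_band_transmission(
    stack: LayerStack,
    geometry: SensorGeometry,
    band: SpectralBand,
    source_model: str = "blackbody3000",
    wavelengths: np.ndarray | None = None,
    parameters: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Source-weighted band transmission of each guided ray angle.

    Returns one value per entry of ``geometry.angle_grid``: the transmission
    of that ray integrated against the lamp spectrum over ``band``.  Because
    the resonance condition is angle-dependent, SPR absorption redistributes
    power across ray angles as the analyte RI changes — and ray angle maps
    to radial position in the imaged spot, so this is what drives the
    RI-dependent spot shape.
    """
    if wavelengths is None:
        wavelengths = default_wavelength_grid()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if band.low < wavelengths[0] or band.high > wavelengths[-1]:
        raise RangeError("band outside wavelength grid")
    theta_c = stack.critical_angle()
    if len(geometry.angle_grid) == 0:
        raise ConfigurationError("angle grid is empty")
    if min(geometry.angle_grid) <= theta_c:
        raise ConfigurationError("all angles must exceed the analyte's critical angle")
    mask = (wavelengths >= band.low) & (wavelengths <= band.high)
    wl_band = wavelengths[mask]
    if source_model == "blackbody3000":
        source = _planck(wl_band, 3000.0)
    elif source_model == "flat":
        source = np.ones(wl_band.shape)
    else:
        raise ConfigurationError(f"unknown source model {source_model!r}")
    per_angle = _per_angle_transmission(stack, geometry, wl_band, parameters)
    norm = np.trapezoid(source, wl_band)
    return np.trapezoid(source * per_angle, wl_band, axis=1) / norm


def _planck(wavelength_nm: np.ndarray, temperature: float) -> np.ndarray:
    """Blackbody spectral radiance (arbitrary units) vs wavelength in nm."""
    # hc/k_B = 1.438777e7 nm*K ; prefactor constants cancel in normalization.
    x = 1.438777e7 / (wavelength_nm * temperature)
    return wavelength_nm**-5 / np.expm1(x)


def band_intensity(
    spectrum: TransmissionSpectrum,
    band: SpectralBand,
    source_model: str = "blackbody3000",
) -> float:
    """Source-weighted mean transmittance of ``spectrum`` over ``band``.

    The transmission is integrated against the lamp spectrum (a 3000 K
    blackbody as a halogen proxy, or ``"flat"``) and normalized by the
    source integral over the same band, so a unit-transmittance sensor
    yields intensity 1 regardless of the source.

    Raises
    ------
    RangeError
        If the band is not fully inside the spectrum's wavelength grid.
    ConfigurationError
        For an unknown source model tag.
    """
    wl, t = spectrum.wavelengths, spectrum.transmittance
    if band.low < wl[0] or band.high > wl[-1]:
        raise RangeError(f"band {band.low}-{band.high} nm outside spectrum grid {wl[0]}-{wl[-1]} nm")
    mask = (wl >= band.low) & (wl <= band.high)
    if source_model == "blackbody3000":
        source = _planck(wl[mask], 3000.0)
    elif source_model == "flat":
        source = np.ones(mask.sum())
    else:
        raise ConfigurationError(f"unknown source model {source_model!r}")
    wl_band = wl[mask]
    return float(np.trapezoid(source * t[mask], wl_band) / np.trapezoid(source, wl_band))


def resonance_wavelength(
    spectrum: TransmissionSpectrum,
    window: tuple[float, float] = (450.0, 1000.0),
) -> float:
    """Wavelength of the SPR dip: the transmission minimum inside ``window`` (nm).

    The default window brackets the plasmonic band; below ~450 nm the Drude
    metals are broadly absorbing at every analyte RI, which would otherwise
    mask the resonance with an RI-insensitive blue-edge minimum.
    """
    mask = (spectrum.wavelengths >= window[0]) & (spectrum.wavelengths <= window[1])
    if not mask.any():
        raise RangeError("search window does not intersect the wavelength grid")
    wl, t = spectrum.wavelengths[mask], spectrum.transmittance[mask]
    return float(wl[int(np.argmin(t))])
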