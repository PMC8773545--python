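"""Synthetic dual-band spot-image rendering and simulation campaigns.

The dual-lens camera records the fiber end face as a bright spot on two
CMOS sensors: an 8-bit-per-channel RGB VIS sensor (300-700 nm filter) and a
10-bit monochrome NIR sensor (700-1200 nm filter), both 640x480.  The
renderer maps a band-integrated transmitted intensity to a flat-top radial
spot, applies lamp-power fluctuation, photon (shot) noise, read noise,
quantization and clipping.

Two mechanisms matter downstream:

* **common-mode fluctuation** — one multiplicative AR(1) lamp-power factor
  is shared by the VIS and NIR frames of a pair, which is the physical
  basis for the network's self-compensation of source drift;
* **saturation blooming** — when the spot core clips at the sensor's
  maximum digital number, the apparent (half-maximum) spot diameter grows
  with intensity, so edge-content features carry intensity information even
  where the grayscale mean has compressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import ClassVar

import numpy as np

from . import optics
from .exceptions import ConfigurationError
from .optics import NIR_BAND, VIS_BAND, LayerStack, SensorGeometry

__all__ = [
    "ImageFrame",
    "NoiseModel",
    "SpotProfile",
    "BindingKinetics",
    "FramePair",
    "default_profiles",
    "render_spot",
    "band_intensities",
    "simulate_calibration_set",
    "simulate_stability_run",
    "simulate_binding_series",
    "half_max_diameter",
    "DEFAULT_RI_LEVELS",
]

#: Calibration RI levels (RIU).  1.323 (ultra-pure water), 1.338, 1.347 and
#: 1.356 (12 % NaCl) are the reported solution points; 1.330 and 1.352 fill
#: the series to six levels.
DEFAULT_RI_LEVELS = (1.323, 1.330, 1.338, 1.347, 1.352, 1.356)

_BIT_DEPTH = {"VIS": 8, "NIR": 10}
_CHANNELS = {"VIS": 3, "NIR": 1}


@dataclass(frozen=True)
class ImageFrame:
    """One camera frame: integer digital numbers, bit depth and band tag."""

    pixels: np.ndarray  # H x W x C, integer DN
    bit_depth: int
    band: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ConfigurationError("pixels must be an H x W x C array")
        if self.band not in _BIT_DEPTH:
            raise ConfigurationError(f"band must be VIS or NIR, got {self.band!r}")
        if px.shape[2] != _CHANNELS[self.band]:
            raise ConfigurationError(
                f"{self.band} frames carry {_CHANNELS[self.band]} channel(s), got {px.shape[2]}"
            )
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ConfigurationError("pixel values exceed the bit-depth range")
        object.__setattr__(self, "pixels", px.astype(np.uint16))

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def max_dn(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class NoiseModel:
    """Sensor and source noise configuration.

    ``fluctuation_sigma``/``fluctuation_rho`` parametrize the stationary
    AR(1) multiplicative lamp-power factor: relative std, and lag-1
    autocorrelation *at the reference frame interval* (300 s, the
    calibration cadence).  Lamp drift is a slow physical process, so runs
    sampled faster see a more correlated series: the per-step correlation
    is ``rho ** (dt / 300)``, the exact discretization of an
    Ornstein-Uhlenbeck drift.  Shot noise is Gaussian with variance
    ``shot_scale * expected DN``; read noise is additive Gaussian in DN.
    """

    fluctuation_sigma: float = 0.005
    fluctuation_rho: float = 0.8
    shot_scale: float = 0.05
    read_sigma: float = 1.0
    seed: int = 0

    #: frame interval (s) at which fluctuation_rho is specified
    REFERENCE_INTERVAL: ClassVar[float] = 300.0

    def __post_init__(self) -> None:
        if self.fluctuation_sigma < 0:
            raise ConfigurationError("fluctuation_sigma must be >= 0")
        if not abs(self.fluctuation_rho) < 1:
            raise ConfigurationError("|fluctuation_rho| must be < 1")
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ConfigurationError("noise scales must be >= 0")

    def off(self) -> "NoiseModel":
        """Copy with every noise source disabled (deterministic rendering)."""
        return NoiseModel(0.0, 0.0, 0.0, 0.0, self.seed)

    def fluctuation_series(self, n: int, rng: np.random.Generator, dt: float = 300.0) -> np.ndarray:
        """Stationary AR(1) multiplicative factors ``f_t = 1 + x_t`` for a
        run sampled every ``dt`` seconds."""
        if self.fluctuation_sigma == 0.0 or n == 0:
            return np.ones(n)
        rho = float(self.fluctuation_rho)
        if rho != 0.0 and dt != self.REFERENCE_INTERVAL:
            rho = np.sign(rho) * abs(rho) ** (dt / self.REFERENCE_INTERVAL)
        x = np.empty(n)
        innov = rng.standard_normal(n)
        x[0] = self.fluctuation_sigma * innov[0]
        c = np.sqrt(1.0 - rho**2) * self.fluctuation_sigma
        for t in range(1, n):
            x[t] = rho * x[t - 1] + c * innov[t]
        return 1.0 + x


@dataclass(frozen=True)
class SpotProfile:
    """Expected-value model of the transmitted spot on one sensor.

    The spot is a superposition of concentric flat-top components, one per
    entry of ``ring_scales``: component ``b`` contributes
    ``peak_gain * intensity_b * channel_gain * exp(-(rho/(base_radius*s_b))**softness)``
    before noise and clipping.  ``softness`` 4 gives the flat-top profile
    of a defocused fiber end face.

    The components model the mapping from guided-ray angle to radial
    position on the sensor: steep (near-critical-angle) rays exit with the
    largest divergence and paint the outer part of the spot, so
    ``ring_scales`` is ordered from the largest component (smallest
    internal angle) downwards.  Feeding the components with per-angle
    transmitted power makes the spot *shape* respond to RI, not just its
    brightness — the physical origin of the edge-feature signal.
    """

    center: tuple[float, float] = (320.0, 240.0)  # (x, y) pixels
    base_radius: float = 90.0
    softness: float = 4.0
    peak_gain: float = 420.0
    channel_gains: tuple[float, ...] = (1.0,)
    frame_shape: tuple[int, int] = (480, 640)  # (H, W)
    ring_scales: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ConfigurationError("base_radius must be > 0")
        object.__setattr__(self, "ring_scales", tuple(float(s) for s in self.ring_scales))
        if not self.ring_scales or any(not 0 < s <= 1 for s in self.ring_scales):
            raise ConfigurationError("ring_scales must be non-empty with entries in (0, 1]")
        h, w = self.frame_shape
        x, y = self.center
        if not (self.base_radius <= x <= w - 1 - self.base_radius and self.base_radius <= y <= h - 1 - self.base_radius):
            raise ConfigurationError("spot (center +/- base_radius) must lie fully inside the frame")

    def component_basis(self) -> np.ndarray:
        """Unit-peak radial component images, shape (n_rings, H, W); cached."""
        return _component_basis(self)

    def expected_image(self, intensity) -> np.ndarray:
        """Noise-free, unclipped expected DN image, H x W x C float.

        ``intensity`` may be a scalar — a plain flat-top disk of the full
        ``base_radius`` (the whole launch cone carries the same
        transmission) — or a per-component vector matching ``ring_scales``.
        """
        gains = np.asarray(self.channel_gains, dtype=float)
        if np.ndim(intensity) == 0:
            h, w = self.frame_shape
            yy, xx = np.mgrid[0:h, 0:w]
            rho = np.hypot(xx - self.center[0], yy - self.center[1])
            radial = float(intensity) * np.exp(-((rho / self.base_radius) ** self.softness))
        else:
            coeffs = np.asarray(intensity, dtype=float)
            if coeffs.shape != (len(self.ring_scales),):
                raise ConfigurationError(
                    f"expected {len(self.ring_scales)} component intensities, got shape {coeffs.shape}"
                )
            radial = np.einsum("b,bhw->hw", coeffs, self.component_basis())
        return self.peak_gain * radial[:, :, None] * gains[None, None, :]


@lru_cache(maxsize=8)
def _component_basis(profile: SpotProfile) -> np.ndarray:
    h, w = profile.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(xx - profile.center[0], yy - profile.center[1])
    scales = np.asarray(profile.ring_scales)
    return np.exp(-((rho[None] / (profile.base_radius * scales[:, None, None])) ** profile.softness))


def default_profiles(frame_shape: tuple[int, int] = (480, 640)) -> dict[str, SpotProfile]:
    """Default VIS/NIR spot profiles, scaled to ``frame_shape``.

    The operating point mirrors the described instrument: the VIS spot is
    dimmer but its red channel clips at typical transmitted intensities
    (supersaturation → blooming), while the NIR spot is bright yet stays
    just below the 10-bit ceiling.
    """
    h, w = frame_shape
    scale = min(h / 480.0, w / 640.0)
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    return {
        # The VIS spot is rendered with strongly overlapping components
        # (narrow ring-scale spread): its edge is comparatively fuzzy, as on
        # the physical sensor, so VIS edge features are the weaker shape
        # readout.  The NIR spot is brighter with a crisper ring structure.
        "VIS": SpotProfile(
            center=center,
            base_radius=130.0 * scale,
            softness=4.0,
            peak_gain=420.0,
            channel_gains=(1.0, 0.82, 0.55),
            frame_shape=frame_shape,
            ring_scales=tuple(np.linspace(1.0, 0.8, 6)),
        ),
        "NIR": SpotProfile(
            center=center,
            base_radius=115.0 * scale,
            softness=4.0,
            peak_gain=1250.0,
            channel_gains=(1.0,),
            frame_shape=frame_shape,
            ring_scales=tuple(np.linspace(1.0, 0.55, 6)),
        ),
    }


@dataclass(frozen=True)
class BindingKinetics:
    """Pseudo-first-order surface binding of an analyte (e.g. IgG on anti-IgG).

    After ``injection_time`` the surface RI rises as
    ``delta_ri_max * (1 - exp(-k_obs * (t - injection_time)))``.
    """

    delta_ri_max: float = 9.0e-4  # RIU at saturation of the available sites
    k_obs: float = 0.01  # 1/s
    injection_time: float = 100.0  # s
    frame_interval: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.delta_ri_max < 0:
            raise ConfigurationError("delta_ri_max must be >= 0")
        if self.k_obs <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("k_obs and frame_interval must be > 0")

    @classmethod
    def from_concentration(
        cls,
        concentration_pm: float,
        ri_per_pm: float = 1e-5 / 46.0,
        **kwargs,
    ) -> "BindingKinetics":
        """Kinetics whose saturation step equals the RI shift of the given
        analyte concentration, via the linear low-concentration conversion
        (default 1e-5 RIU per 46 pM of IgG)."""
        return cls(delta_ri_max=concentration_pm * ri_per_pm, **kwargs)

    def true_ri(self, t: np.ndarray | float, baseline_ri: float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        dt = np.clip(t - self.injection_time, 0.0, None)
        ri = baseline_ri + self.delta_ri_max * (1.0 - np.exp(-self.k_obs * dt))
        return float(ri) if ri.ndim == 0 else ri


@dataclass(frozen=True)
class FramePair:
    """Simultaneously captured VIS/NIR frames with ground truth annotations."""

    vis: ImageFrame
    nir: ImageFrame
    true_ri: float
    time_s: float
    fluctuation: float = 1.0


def render_spot(
    intensity,
    profile: SpotProfile,
    noise: NoiseModel,
    band: str,
    rng: np.random.Generator | None = None,
) -> ImageFrame:
    """Render one frame for a band-integrated ``intensity`` in [0, 1.5].

    ``intensity`` is either the total band intensity (scalar) or its
    decomposition over the profile's radial components; the lamp
    fluctuation, if any, must already be folded in.  Shot and read noise
    are added, then values are rounded and clipped to the band's bit
    depth.  Clipping is what produces saturation blooming.
    """
    total = float(np.sum(intensity))
    if not 0.0 <= total <= 1.5:
        raise ConfigurationError(f"total intensity {total} outside [0, 1.5]")
    if band not in _BIT_DEPTH:
        raise ConfigurationError(f"band must be VIS or NIR, got {band!r}")
    if len(profile.channel_gains) != _CHANNELS[band]:
        raise ConfigurationError(
            f"profile has {len(profile.channel_gains)} channel gain(s) but {band} needs {_CHANNELS[band]}"
        )
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    expected = profile.expected_image(intensity)
    if noise.shot_scale > 0.0:
        expected = expected + rng.standard_normal(expected.shape) * np.sqrt(noise.shot_scale * expected)
    if noise.read_sigma > 0.0:
        expected = expected + noise.read_sigma * rng.standard_normal(expected.shape)
    max_dn = 2 ** _BIT_DEPTH[band] - 1
    pixels = np.clip(np.rint(expected), 0, max_dn).astype(np.uint16)
    return ImageFrame(pixels, _BIT_DEPTH[band], band)


@lru_cache(maxsize=4096)
def angular_intensities(stack: LayerStack, geometry: SensorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle transmitted power coefficients (VIS, NIR) for a stack.

    Entry ``i`` is ``w(theta_i) * t_band(theta_i)``: launch power times
    source-weighted band transmission of that ray angle, so the sum over
    angles is the band-integrated intensity.  Cached: campaigns revisit
    the same RI levels many times.
    """
    weights = geometry.angle_weights()
    c_vis = weights * optics.angular_band_transmission(stack, geometry, VIS_BAND)
    c_nir = weights * optics.angular_band_transmission(stack, geometry, NIR_BAND)
    c_vis.setflags(write=False)
    c_nir.setflags(write=False)
    return c_vis, c_nir


def band_intensities(stack: LayerStack, geometry: SensorGeometry) -> tuple[float, float]:
    """(VIS, NIR) band-integrated transmitted intensities for a stack."""
    c_vis, c_nir = angular_intensities(stack, geometry)
    return float(c_vis.sum()), float(c_nir.sum())


def ring_binned(coefficients: np.ndarray, n_rings: int) -> np.ndarray:
    """Collapse per-angle coefficients onto the profile's radial components.

    Angles are in ascending order; the smallest internal angles exit with
    the largest divergence and feed the outermost (first, largest-scale)
    component.
    """
    return np.array([c.sum() for c in np.array_split(np.asarray(coefficients), n_rings)])


def _render_pair(
    ri: float,
    t: float,
    fluct: float,
    stack: LayerStack,
    geometry: SensorGeometry,
    profiles: dict[str, SpotProfile],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> FramePair:
    c_vis, c_nir = angular_intensities(stack.with_analyte(round(ri, 9)), geometry)
    vis_coeffs = ring_binned(c_vis, len(profiles["VIS"].ring_scales)) * fluct
    nir_coeffs = ring_binned(c_nir, len(profiles["NIR"].ring_scales)) * fluct
    vis = render_spot(vis_coeffs, profiles["VIS"], noise, "VIS", rng)
    nir = render_spot(nir_coeffs, profiles["NIR"], noise, "NIR", rng)
    return FramePair(vis, nir, ri, t, fluct)


def _campaign(
    ri_of_t: np.ndarray,
    times: np.ndarray,
    stack: LayerStack,
    geometry: SensorGeometry,
    profiles: dict[str, SpotProfile] | None,
    noise: NoiseModel,
    seed: int | None,
) -> list[FramePair]:
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    dt = float(times[1] - times[0]) if len(times) > 1 else NoiseModel.REFERENCE_INTERVAL
    flucts = noise.fluctuation_series(len(times), rng, dt)
    return [
        _render_pair(ri, t, f, stack, geometry, profiles, noise, rng)
        for ri, t, f in zip(ri_of_t, times, flucts)
    ]


def simulate_calibration_set(
    ri_levels=DEFAULT_RI_LEVELS,
    frames_per_level: int = 10,
    stack: LayerStack | None = None,
    geometry: SensorGeometry | None = None,
    profiles: dict[str, SpotProfile] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    frame_interval: float = 300.0,
) -> list[FramePair]:
    """Labeled calibration campaign: ``frames_per_level`` VIS/NIR pairs per RI.

    Frames are time-ordered level by level (the solutions are exchanged
    sequentially in the flow cell) with one AR(1) lamp-fluctuation chain
    across the whole run; both frames of a pair share a fluctuation draw.
    Defaults reproduce the six-level, ten-frame, 60-pair study design.
    """
    ri_levels = tuple(float(r) for r in ri_levels)
    if len(ri_levels) == 0:
        raise ConfigurationError("ri_levels must be non-empty")
    if any(not 1.30 <= r <= 1.40 for r in ri_levels):
        raise ConfigurationError("calibration RI levels must lie in [1.30, 1.40]")
    stack = stack or LayerStack()
    geometry = geometry or SensorGeometry()
    noise = noise or NoiseModel()
    ri_of_t = np.repeat(ri_levels, frames_per_level)
    times = np.arange(len(ri_of_t)) * frame_interval
    return _campaign(ri_of_t, times, stack, geometry, profiles, noise, seed)


def simulate_stability_run(
    ri: float = 1.352,
    n_frames: int = 60,
    stack: LayerStack | None = None,
    geometry: SensorGeometry | None = None,
    profiles: dict[str, SpotProfile] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    frame_interval: float = 10.0,
) -> list[FramePair]:
    """Time-ordered frame pairs at one constant RI, for noise assessment."""
    stack = stack or LayerStack()
    geometry = geometry or SensorGeometry()
    noise = noise or NoiseModel()
    times = np.arange(n_frames) * frame_interval
    return _campaign(np.full(n_frames, float(ri)), times, stack, geometry, profiles, noise, seed)


def simulate_binding_series(
    kinetics: BindingKinetics | None = None,
    baseline_ri: float = 1.350,
    duration: float = 700.0,
    stack: LayerStack | None = None,
    geometry: SensorGeometry | None = None,
    profiles: dict[str, SpotProfile] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> list[FramePair]:
    """Binding experiment: frames every ``frame_interval`` s while the surface
    RI follows the saturating association kinetics after injection."""
    kinetics = kinetics or BindingKinetics()
    if duration <= kinetics.injection_time:
        raise ConfigurationError("duration must exceed injection_time")
    stack = stack or LayerStack()
    geometry = geometry or SensorGeometry()
    noise = noise or NoiseModel()
    times = np.arange(0.0, duration, kinetics.frame_interval)
    ri_of_t = np.asarray(kinetics.true_ri(times, baseline_ri))
    return _campaign(ri_of_t, times, stack, geometry, profiles, noise, seed)


def half_max_diameter(frame: ImageFrame, channel: int = 0) -> float:
    """Apparent spot diameter: equivalent-circle diameter (pixels) of the
    region at or above half the frame's maximum DN in ``channel``."""
    px = frame.pixels[:, :, channel].astype(float)
    count = int((px >= px.max() / 2.0).sum())
    return 2.0 * np.sqrt(count / np.pi)
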