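"""Spot rendering, noise model and simulation campaigns."""

import numpy as np
import pytest

from plasmoncam import features as feats
from plasmoncam import imaging
from plasmoncam.exceptions import ConfigurationError
from plasmoncam.imaging import (
    BindingKinetics,
    ImageFrame,
    NoiseModel,
    SpotProfile,
    default_profiles,
    half_max_diameter,
    render_spot,
)

from conftest import SMALL_SHAPE, small_profiles


def _vis_profile():
    return small_profiles()["VIS"]


def _nir_profile():
    return small_profiles()["NIR"]


class TestRenderSpot:
    def test_seeded_determinism(self):
        noise = NoiseModel(seed=42)
        a = render_spot(0.7, _vis_profile(), noise, "VIS", np.random.default_rng(5))
        b = render_spot(0.7, _vis_profile(), noise, "VIS", np.random.default_rng(5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_dark_frame(self):
        """Zero intensity: almost every pixel within 3 read-noise DN."""
        frame = render_spot(0.0, _nir_profile(), NoiseModel(), "NIR", np.random.default_rng(0))
        frac = (frame.pixels <= 3).mean()
        assert frac >= 0.99

    def test_quantization_ranges(self):
        rng = np.random.default_rng(1)
        vis = render_spot(1.2, _vis_profile(), NoiseModel(), "VIS", rng)
        nir = render_spot(1.2, _nir_profile(), NoiseModel(), "NIR", rng)
        assert vis.pixels.max() <= 255 and vis.bit_depth == 8 and vis.channels == 3
        assert nir.pixels.max() <= 1023 and nir.bit_depth == 10 and nir.channels == 1
        assert np.issubdtype(vis.pixels.dtype, np.integer)

    def test_saturation_blooming(self):
        """Noise off: apparent half-max diameter grows with over-range intensity."""
        noise = NoiseModel().off()
        dim = render_spot(0.8, _vis_profile(), noise, "VIS")
        bright = render_spot(1.2, _vis_profile(), noise, "VIS")
        assert half_max_diameter(bright) > half_max_diameter(dim)

    def test_radial_monotone_expected_value(self):
        """Expected (pre-noise) profile never increases away from the center."""
        profile = _nir_profile()
        img = profile.expected_image(0.9)[:, :, 0]
        cy = int(profile.center[1])
        row = img[cy, int(profile.center[0]):]
        assert np.all(np.diff(row) <= 1e-9)

    def test_out_of_range_intensity_rejected(self):
        with pytest.raises(ConfigurationError):
            render_spot(1.7, _vis_profile(), NoiseModel(), "VIS")

    def test_spot_must_fit_frame(self):
        with pytest.raises(ConfigurationError):
            SpotProfile(center=(5.0, 5.0), base_radius=50.0, frame_shape=SMALL_SHAPE)

    def test_channel_gain_band_mismatch(self):
        with pytest.raises(ConfigurationError):
            render_spot(0.5, _vis_profile(), NoiseModel(), "NIR")


class TestNoiseModel:
    def test_fluctuation_autocorrelation_orders(self):
        """rho = 0.9 yields a higher lag-1 autocorrelation than rho = 0."""

        def lag1(x):
            x = x - x.mean()
            return float(np.sum(x[1:] * x[:-1]) / np.sum(x * x))

        rng = np.random.default_rng(3)
        white = NoiseModel(fluctuation_rho=0.0).fluctuation_series(500, rng)
        rng = np.random.default_rng(3)
        red = NoiseModel(fluctuation_rho=0.9).fluctuation_series(500, rng)
        assert lag1(red) > lag1(white) + 0.3

    def test_slow_drift_scaling_with_frame_interval(self):
        """Sampled faster than the reference cadence, the lamp factor is more
        correlated step-to-step (drift is a slow process)."""
        noise = NoiseModel(fluctuation_rho=0.8)
        rng = np.random.default_rng(0)
        fast = noise.fluctuation_series(400, rng, dt=10.0)
        rng = np.random.default_rng(0)
        ref = noise.fluctuation_series(400, rng, dt=300.0)
        lag1 = lambda x: float(np.corrcoef(x[1:], x[:-1])[0, 1])
        assert lag1(fast) > lag1(ref)

    def test_stationary_sigma(self):
        series = NoiseModel().fluctuation_series(20000, np.random.default_rng(0))
        assert np.std(series) == pytest.approx(0.005, rel=0.1)

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            NoiseModel(fluctuation_rho=1.0)
        with pytest.raises(ConfigurationError):
            NoiseModel(fluctuation_sigma=-0.1)


class TestCalibrationSet:
    def test_sixty_labeled_pairs(self):
        pairs = imaging.simulate_calibration_set(
            frames_per_level=10, profiles=small_profiles(), seed=0
        )
        assert len(pairs) == 60
        labels = sorted({p.true_ri for p in pairs})
        assert labels == sorted(imaging.DEFAULT_RI_LEVELS)

    def test_zero_frames_empty(self):
        assert imaging.simulate_calibration_set(frames_per_level=0, profiles=small_profiles()) == []

    def test_noiseless_features_identical_within_level(self, small_noiseless_pairs):
        by_level = {}
        for p in small_noiseless_pairs:
            by_level.setdefault(p.true_ri, []).append(feats.extract_features(p.vis, p.nir).as_array())
        for vectors in by_level.values():
            assert np.array_equal(vectors[0], vectors[1])

    def test_seeded_determinism(self):
        a = imaging.simulate_calibration_set(frames_per_level=2, profiles=small_profiles(), seed=9)
        b = imaging.simulate_calibration_set(frames_per_level=2, profiles=small_profiles(), seed=9)
        assert all(np.array_equal(x.vis.pixels, y.vis.pixels) for x, y in zip(a, b))
        assert all(np.array_equal(x.nir.pixels, y.nir.pixels) for x, y in zip(a, b))

    def test_level_range_validated(self):
        with pytest.raises(ConfigurationError):
            imaging.simulate_calibration_set(ri_levels=(1.45,), profiles=small_profiles())


class TestStabilityRun:
    def test_common_mode_correlation(self):
        """VIS and NIR brightness co-fluctuate (shared lamp factor)."""
        pairs = imaging.simulate_stability_run(
            n_frames=200, profiles=small_profiles(), seed=11
        )
        gm_vis = [feats.grayscale_mean(feats.to_grayscale(p.vis)) for p in pairs]
        gm_nir = [feats.grayscale_mean(feats.to_grayscale(p.nir)) for p in pairs]
        assert np.corrcoef(gm_vis, gm_nir)[0, 1] > 0.5

    def test_noiseless_zero_variance(self):
        pairs = imaging.simulate_stability_run(
            n_frames=5, profiles=small_profiles(), noise=NoiseModel().off(), seed=0
        )
        table = feats.features_table(pairs)
        assert table[list(feats.FEATURE_NAMES)].std().max() < 1e-9


class TestBinding:
    def test_ri_trajectory(self):
        k = BindingKinetics(delta_ri_max=9e-4, k_obs=0.01, injection_time=100.0)
        assert k.true_ri(50.0, 1.334) == pytest.approx(1.334)
        assert k.true_ri(1e7, 1.334) == pytest.approx(1.334 + 9e-4)
        t = np.array([0.0, 100.0, 200.0, 400.0, 1000.0])
        ri = k.true_ri(t, 1.334)
        assert np.all(np.diff(ri) >= 0.0)

    def test_concentration_conversion(self):
        """46 pM of IgG shifts the surface RI by 1e-5 RIU."""
        k = BindingKinetics.from_concentration(46.0)
        assert k.delta_ri_max == pytest.approx(1e-5)

    def test_series_respects_frame_interval(self):
        k = BindingKinetics(frame_interval=10.0, injection_time=30.0)
        pairs = imaging.simulate_binding_series(
            k, duration=100.0, profiles=small_profiles(), seed=2
        )
        times = [p.time_s for p in pairs]
        assert times == list(np.arange(0.0, 100.0, 10.0))
        assert min(p.true_ri for p in pairs) == pytest.approx(1.350)

    def test_duration_must_exceed_injection(self):
        with pytest.raises(ConfigurationError):
            imaging.simulate_binding_series(
                BindingKinetics(injection_time=500.0), duration=100.0, profiles=small_profiles()
            )


class TestImageFrame:
    def test_band_channel_validation(self):
        with pytest.raises(ConfigurationError):
            ImageFrame(np.zeros((4, 4, 3), dtype=np.uint16), 10, "NIR")
        with pytest.raises(ConfigurationError):
            ImageFrame(np.full((4, 4, 3), 300, dtype=np.uint16), 8, "VIS")
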