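"""Shared fixtures.

The default-scale benchmark artifacts (simulated campaigns, feature
tables, trained networks) are expensive, so they are computed once per
session and shared by the acceptance tests; unit tests use miniature
160x120 campaigns instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from plasmoncam import features as feats
from plasmoncam import imaging, metrics, model, network

SMALL_SHAPE = (120, 160)

#: Seeds of the stochastic acceptance benchmark.
BENCHMARK_SEEDS = tuple(range(1, 21))


def small_profiles():
    return imaging.default_profiles(SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_noiseless_pairs():
    """6 levels x 3 pairs, 160x120, all noise off."""
    return imaging.simulate_calibration_set(
        frames_per_level=3,
        profiles=small_profiles(),
        noise=imaging.NoiseModel().off(),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_noisy_table():
    """6 levels x 10 pairs, 160x120, default noise, as a feature table."""
    pairs = imaging.simulate_calibration_set(
        frames_per_level=10, profiles=small_profiles(), seed=7
    )
    return feats.features_table(pairs)


@pytest.fixture(scope="session")
def noiseless_table():
    """6 levels x 10 pairs at 160x120 with noise off: clean feature table."""
    pairs = imaging.simulate_calibration_set(
        frames_per_level=10,
        profiles=small_profiles(),
        noise=imaging.NoiseModel().off(),
        seed=0,
    )
    return feats.features_table(pairs)


class BenchmarkRun:
    """Per-seed artifacts of the default-scale synthetic benchmark."""

    def __init__(self, seed: int):
        self.seed = seed
        pairs = imaging.simulate_calibration_set(seed=seed)
        self.table = feats.features_table(pairs)
        self.results = model.RICalibration.from_dataframe(self.table).fit(seed=seed)
        self._arm_cache: dict[tuple, float] = {}

    def arm_r2(self, arm) -> float:
        arm = tuple(arm)
        if arm == feats.FEATURE_NAMES:
            return self.results.rsquared
        if arm not in self._arm_cache:
            cal = model.RICalibration.from_dataframe(self.table, features=arm)
            self._arm_cache[arm] = cal.fit(seed=self.seed).rsquared
        return self._arm_cache[arm]

    def stability_resolution(self, n_frames: int = 60) -> float:
        pairs = imaging.simulate_stability_run(n_frames=n_frames, seed=10_000 + self.seed)
        table = feats.features_table(pairs)
        preds = self.results.predict(table[list(feats.FEATURE_NAMES)].to_numpy())
        return metrics.resolution_from_stability(preds)

    def binding_step(self) -> float:
        kinetics = imaging.BindingKinetics()
        pairs = imaging.simulate_binding_series(kinetics, seed=20_000 + self.seed)
        table = feats.features_table(pairs)
        preds = self.results.predict(table[list(feats.FEATURE_NAMES)].to_numpy())
        sg = metrics.build_sensorgram(table["time"], preds, kinetics.injection_time)
        return sg.step()


@pytest.fixture(scope="session")
def benchmark_runs():
    """The 20-seed default-noise benchmark shared by the stochastic checks."""
    return [BenchmarkRun(seed) for seed in BENCHMARK_SEEDS]
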