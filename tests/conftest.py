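"""Shared fixtures: small surrogate data sets and short plate simulations.

Everything is generated at test time with fixed seeds; simulations are
session-scoped because the plate solve is the expensive step.
"""

import numpy as np
import pytest

from wingsense import (EncoderParams, FlappingKinematics, RotationCondition,
                       SensorGrid, SurrogateSpec, WingParams,
                       compute_norm_constant, filter_strain,
                       first_spike_features, generate_spikes, nonlinearity,
                       simulate_strain, surrogate_strain)
from wingsense.encoding import FirstSpikeMatrix


SMALL_GRID = SensorGrid(chordwise_count=6, spanwise_count=11)


def surrogate_features(twist_a: float, twist_b: float, seed: int = 0,
                       noise_sd: float = 0.01, duration: float = 1.2,
                       n_repeats: int = 10) -> FirstSpikeMatrix:
    """Two-class first-spike features from the analytic surrogate."""
    params = EncoderParams(beta=0.2)
    blocks, labels = [], []
    ss = np.random.SeedSequence(seed).generate_state(4)
    for cls, twist in enumerate((twist_a, twist_b)):
        spec = SurrogateSpec(bend_amp=1.0, twist_amp=twist, noise_sd=noise_sd)
        strain = surrogate_strain(spec, grid=SMALL_GRID, duration=duration,
                                  seed=int(ss[cls] % (2**31)))
        if cls == 0:
            params = params.with_norm(compute_norm_constant(strain, params))
        g = filter_strain(strain, params)
        raster = generate_spikes(nonlinearity(g, params), params.refractory,
                                 n_repeats=n_repeats,
                                 seed=int(ss[2 + cls] % (2**31)))
        feats = first_spike_features(raster)
        blocks.append(feats.data)
        labels.append(np.full(feats.data.shape[0], cls))
    return FirstSpikeMatrix(np.concatenate(blocks), np.concatenate(labels))


@pytest.fixture(scope="session")
def separable_features() -> FirstSpikeMatrix:
    return surrogate_features(0.05, 0.45, seed=1)


@pytest.fixture(scope="session")
def chance_features() -> FirstSpikeMatrix:
    return surrogate_features(0.2, 0.2, seed=2)


@pytest.fixture(scope="session")
def flap_strain():
    """Noise-free flapping-only strain at reference stiffness, 5 wingbeats."""
    return simulate_strain(WingParams(), FlappingKinematics(),
                           RotationCondition(axis="none", rate=0.0),
                           duration=0.2, seed=0, noise=False)


@pytest.fixture(scope="session")
def yaw_strain():
    """Noise-free yaw-rotation strain matched to ``flap_strain``."""
    return simulate_strain(WingParams(), FlappingKinematics(),
                           RotationCondition(axis="yaw", rate=10.0),
                           duration=0.2, seed=0, noise=False)
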