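"""Helper: build a labeled first-spike feature matrix from a fixture pair."""

import numpy as np

from wingsense import (EncoderParams, compute_norm_constant, filter_strain,
                       first_spike_features, generate_spikes, nonlinearity)
from wingsense.encoding import FirstSpikeMatrix


def features_from_fixture_pair(a, b, beta: float = 0.2, n_repeats: int = 10,
                               seed: int = 0) -> FirstSpikeMatrix:
    params = EncoderParams(beta=beta)
    params = params.with_norm(compute_norm_constant(a, params))
    blocks, labels = [], []
    ss = np.random.SeedSequence(seed).generate_state(2)
    for cls, field in enumerate((a, b)):
        g = filter_strain(field, params)
        raster = generate_spikes(nonlinearity(g, params), params.refractory,
                                 n_repeats=n_repeats,
                                 seed=int(ss[cls] % (2**31)))
        feats = first_spike_features(raster)
        blocks.append(feats.data)
        labels.append(np.full(feats.data.shape[0], cls))
    return FirstSpikeMatrix(np.concatenate(blocks), np.concatenate(labels))
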