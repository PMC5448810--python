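import numpy as np
import pytest

from epiwalk import GenotypeFitnessMap, MapSpec, generate_map


@pytest.fixture
def additive_map_2s():
    """L=2 map with equal beneficial effects: F = 1 + 0.1 * (#mutations)."""
    return GenotypeFitnessMap(
        n_sites=2, fitness_mean=np.array([1.0, 1.1, 1.1, 1.2]), name="add2"
    )


@pytest.fixture
def staircase_map():
    """L=3 purely additive map F = 1 + 0.1 * (#mutations)."""
    counts = np.array([bin(i).count("1") for i in range(8)], dtype=float)
    return GenotypeFitnessMap(n_sites=3, fitness_mean=1.0 + 0.1 * counts, name="stair3")


@pytest.fixture
def epistatic_map_5s():
    """Noiseless L=5 map with a mostly-additive epistasis spectrum and a
    power-law measurement scale, mimicking an adaptive experimental map."""
    spec = MapSpec(
        n_sites=5,
        beta_spec={1: 0.94, 2: 0.038, 3: 0.012, 4: 0.009, 5: 0.001},
        scale=(2.5, 1.0, 0.0),
        noise_sd=0.0,
        n_replicates=1,
        seed=11,
    )
    gmap, truth, truth_scale = generate_map(spec)
    return gmap, truth, truth_scale


@pytest.fixture
def noisy_map_4s():
    """L=4 map with additive + pairwise epistasis, scale, and replicate noise."""
    spec = MapSpec(
        n_sites=4,
        beta_spec={1: 0.9, 2: 0.1},
        scale=(2.0, 1.0, 0.0),
        noise_sd=0.02,
        n_replicates=3,
        seed=21,
    )
    gmap, _, _ = generate_map(spec)
    return gmap
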