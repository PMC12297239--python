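import numpy as np
import pytest

from mchem import fixtures as fx
from mchem import reactions as rx


@pytest.fixture(scope="session")
def registry():
    return rx.default_registry()


@pytest.fixture(scope="session")
def registry_by_id(registry):
    return {r.id: r for r in registry}


@pytest.fixture(scope="session")
def noise_free_config():
    return fx.FixtureConfig(seed=42, rt_jitter_sd=0.0, mass_error_sd=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    # mass noise clipped below half the 0.002 Da tolerance floor
    return fx.FixtureConfig(seed=42, rt_jitter_sd=0.01, mass_error_sd=0.0003)


@pytest.fixture(scope="session")
def structure_pool():
    return fx.default_structure_pool()


@pytest.fixture(scope="session")
def benchmark():
    """Seeded 50-query analog benchmark shared across tests."""
    config = fx.FixtureConfig(seed=20, n_queries=50)
    return fx.make_analog_benchmark(config)


def random_feature_table(rng: np.random.Generator, registry, n: int):
    """A random feature table with some pairs planted at reaction deltas."""
    from mchem.linking import Feature

    features = []
    mzs = rng.uniform(100.0, 900.0, size=n)
    rts = rng.uniform(0.5, 14.0, size=n)
    for i in range(n):
        features.append(
            Feature(id=f"R{i:04d}", mz=float(mzs[i]), rt=float(rts[i]), areas={}, conditions={})
        )
    # plant some true-offset partners so edges actually occur
    for j in range(n // 5):
        base = features[int(rng.integers(0, n))]
        reaction = registry[int(rng.integers(0, len(registry)))]
        err = float(rng.uniform(-0.003, 0.003))
        rt_off = float(rng.uniform(-0.1, 0.1))
        features.append(
            Feature(
                id=f"P{j:04d}",
                mz=base.mz + reaction.delta_mass + err,
                rt=max(base.rt + rt_off, 0.0),
                areas={},
                conditions={},
            )
        )
    return features
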