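import numpy as np
import pytest

import paddyphenom as pp


@pytest.fixture(scope="session")
def scene():
    return pp.SceneSpec()


@pytest.fixture(scope="session")
def erect_spec():
    return pp.GenotypeSpec(
        genotype_id="T001",
        archetype="erect",
        base_leaf_count=8,
        emergence_rate_control=5,
        drought_emergence_factor=0.5,
        erectness=0.8,
        rolling_factor=0.3,
        leaf_len_px=180.0,
        leaf_width_px=7.0,
        seed=12345,
    )


@pytest.fixture(scope="session")
def sparse_plant(erect_spec, scene):
    """An 8-leaf erect plant: the sparse regime with guaranteed tip separation."""
    return pp.render_plant(erect_spec, "control", 1, scene, seed=42)


def sparse_suite_specs(n):
    """Deterministic sparse-regime specs (8-15 leaves, erect/semi-erect)."""
    rng = np.random.default_rng(20_240_001)
    return [
        pp.GenotypeSpec(
            genotype_id=f"S{i:03d}",
            archetype=["erect", "semi_erect"][i % 2],
            base_leaf_count=int(rng.integers(8, 16)),
            emergence_rate_control=5,
            drought_emergence_factor=0.6,
            erectness=[0.8, 0.55][i % 2],
            rolling_factor=0.3,
            leaf_len_px=float(rng.uniform(140, 210)),
            leaf_width_px=float(rng.uniform(5, 9)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i in range(n)
    ]


def dense_suite_specs(n):
    """Deterministic dense-regime specs (60-100 leaves, spread/open)."""
    rng = np.random.default_rng(20_240_002)
    return [
        pp.GenotypeSpec(
            genotype_id=f"D{i:03d}",
            archetype=["spread", "open"][i % 2],
            base_leaf_count=int(rng.integers(60, 101)),
            emergence_rate_control=5,
            drought_emergence_factor=0.6,
            erectness=[0.3, 0.1][i % 2],
            rolling_factor=0.3,
            leaf_len_px=float(rng.uniform(140, 210)),
            leaf_width_px=float(rng.uniform(5, 9)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i in range(n)
    ]
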