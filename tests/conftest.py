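import numpy as np
import pytest

from svgt.simulate import SimConfig, simulate_dataset


def small_config(**overrides) -> SimConfig:
    """A fast, fully featured simulation configuration for tests."""
    base = dict(
        region_length=80_000,
        class_counts=(4, 4, 4, 4, 4),
        sv_length_range=(300, 800),
        cnv_length_range=(500, 1200),
        copy_number=3,
        coverage=10.0,
        min_gap=200,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_sim_sam(small_sim, tmp_path_factory):
    """The same dataset written to SAM (without sequences, faster)."""
    from svgt.simulate import write_sam

    path = tmp_path_factory.mktemp("sam") / "small.sam"
    write_sam(path, small_sim.collection, small_sim.config)
    return path


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
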