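import pytest

from rnpchip.simulate import RepliconSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Two small replicons: fast enough for unit tests, keeps all structure."""
    return SyntheticConfig(
        replicon_specs=(
            RepliconSpec("chrA", 60_000, ori=5_000, ter=35_000),
            RepliconSpec("plasB", 30_000, ori=2_000, ter=17_000),
        ),
        n_true_peaks=20,
        n_decoy_peaks=8,
        n_is_copies=4,
        ori_decay_scale=8_000,
        depth_input=8.0,
        depth_ip=40.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)
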