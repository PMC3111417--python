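import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small expression TSV and return its path."""

    def _write(text: str, name: str = "expr.tsv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write


@pytest.fixture
def tiny_sim():
    """A small planted-edge compendium used by several integration tests."""
    from mirhost import SimulationConfig, simulate_compendium

    cfg = SimulationConfig(
        rng_seed=7,
        n_datasets=6,
        n_samples=12,
        n_hosts=4,
        n_targets=4,
        n_background=80,
        regulators_per_target=1,
        n_decoys=1,
        w_range=(1.0, 1.0),
    )
    return simulate_compendium(cfg)
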