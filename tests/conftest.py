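import pytest

from transchrom.pipeline import PipelineConfig, run_all
from transchrom.simulate import SimConfig, simulate_dataset


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Reduced-scale study conditions for fast unit tests: a 500 kb
    chromosome with proportionally fewer repeats and regions."""
    defaults = dict(
        chrom_length=500_000,
        n_repeats=200,
        n_shared_regions=15,
        n_specific_regions=8,
        n_background_probes=40,
        n_background_genes=10,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-scale synthetic dataset at the reference conditions."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_dataset(small_sim_config(seed=0))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A complete pipeline run on the reference conditions (seed 0)."""
    base = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(
        input_dir=str(base / "data"), outdir=str(base / "out"), seed=0, simulate_first=True
    )
    results = run_all(cfg)
    return cfg, results
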