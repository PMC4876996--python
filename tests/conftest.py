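import pytest

from soymir.pipeline import run_pipeline
from soymir.simulate import SimConfig, make_genome


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated dataset (genome + truth only) for unit tests."""
    return make_genome(SimConfig(seed=5, per_library_depth=6000))


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """Full pipeline run at modest depth with corruption enabled."""
    cfg = SimConfig(seed=5, per_library_depth=20000, corruption_fraction=0.03)
    outdir = tmp_path_factory.mktemp("small_run")
    return run_pipeline(cfg, str(outdir), write_outputs=True, quiet=True)


@pytest.fixture(scope="session")
def fourplex():
    """Corruption-free fourplex at full simulated depth (1e5 reads/library).

    This is the closed-loop dataset on which quantification must recover the
    planted truth exactly.
    """
    cfg = SimConfig(seed=11, per_library_depth=100_000, corruption_fraction=0.0)
    return run_pipeline(cfg, "unused", write_outputs=False, quiet=True)
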