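import numpy as np
import pytest

from madsfam import pipeline
from madsfam.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default synthetic allotetraploid pushed through the whole pipeline."""
    out = tmp_path_factory.mktemp("full_run")
    cfg = pipeline.RunConfig(out_dir=str(out), seed=1)
    ctx = pipeline.run_pipeline(cfg)
    return cfg, ctx


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small genome system for fast structural checks."""
    out = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(seed=7, n_chrom_A=2, n_chrom_C=2, genes_per_chrom=10,
                    family_size=6, n_tandem=1, n_segmental=1, n_HE=1,
                    expr_tissues=12)
    return simulate_dataset(cfg, str(out))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
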