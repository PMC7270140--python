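import numpy as np
import pytest

from menimm import synthetic
from menimm.types import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """Single-study cohort with planted modules and default couplings."""
    cfg = synthetic.SimulationConfig(
        n_genes=800, samples_per_study=(60,), skull_base_fraction=(0.5,),
        n_studies=1, module_sizes=(120, 80), gene_drop_rate=0.0,
        batch_shift_range=(0.0, 0.0), batch_scale_range=(1.0, 1.0),
        gene_shift_sd=0.0, seed=42)
    return synthetic.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"],
        np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), scale="linear")
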