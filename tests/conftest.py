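import numpy as np
import pytest

from clonerx import model as M
from clonerx.refdb import build_training_table
from clonerx.sim import SimConfig, simulate_patient, simulate_reference


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small corpus: fast to simulate and fit, still >= 100 training rows."""
    return SimConfig(
        n_drugs=12,
        n_cell_lines=5,
        n_landmark_genes=40,
        n_fp_bits=32,
        doses_per_drug=5,
        n_module_templates=4,
        module_size=6,
        n_cells=400,
        n_genes=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_reference(tiny_cfg):
    return simulate_reference(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_table(tiny_reference):
    pert, curves, fp, _ = tiny_reference
    return build_training_table(pert, curves, fp)


@pytest.fixture(scope="session")
def tiny_model(tiny_table):
    return M.fit(tiny_table, cv_repeats=1, cv_folds=5, n_search=2, seed=0)


@pytest.fixture(scope="session")
def tiny_patient(tiny_cfg, tiny_reference):
    _, _, _, truth = tiny_reference
    return simulate_patient(tiny_cfg, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
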