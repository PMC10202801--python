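import logging

import numpy as np
import pytest

from npfactor.synthetic import SimConfig, generate_cohort

# the pipeline logs every degenerate fold; keep test output readable
logging.getLogger("npfactor").setLevel(logging.ERROR)
for name in ("npfactor.cpm", "npfactor.fc", "npfactor.crossdisorder"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """150 subjects, 15 nodes (105 edges), two conditions, planted effects."""
    cfg = SimConfig(
        n_subjects=150,
        n_nodes=15,
        conditions=("cond_a", "cond_b"),
        n_pp=6,
        n_nn=3,
        n_pn=4,
        n_np=2,
        seed=11,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Same shape as small_cohort but with no planted effect (beta = 0)."""
    cfg = SimConfig(
        n_subjects=150,
        n_nodes=15,
        conditions=("cond_a", "cond_b"),
        n_pp=6,
        n_nn=3,
        n_pn=4,
        n_np=2,
        beta=0.0,
        seed=17,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
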