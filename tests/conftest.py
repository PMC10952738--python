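import numpy as np
import pytest

from bolatype import fixtures as fx
from bolatype.simulate import SimulationConfig, make_cohort, make_reference


@pytest.fixture(scope="session")
def mhc2_rows():
    return fx.load_mhc2_table()


@pytest.fixture(scope="session")
def mhc1_rows():
    return fx.load_mhc1_table()


@pytest.fixture(scope="session")
def small_reference():
    """A compact simulated reference: 4 groups x 2 members per MHCII locus."""
    cfg = SimulationConfig(seed=11, groups_per_locus={"DQA": 6, "DQB": 6, "DRB3": 4},
                           members_per_group=2, pool_size=5, cohort_size=10)
    db, groups = make_reference(cfg)
    return cfg, db, groups


@pytest.fixture(scope="session")
def planted_cohort_200():
    """A 200-animal diploid MHCII cohort drawn from 15 planted haplotypes."""
    cfg = SimulationConfig(seed=29, cohort_size=200, pool_size=15)
    db, groups = make_reference(cfg)
    cohort = make_cohort(cfg, db)
    return cfg, db, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
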