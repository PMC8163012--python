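import numpy as np
import pytest

import hammettfit as hf


@pytest.fixture(scope="session")
def sn2_world():
    """Noiseless four-position activation-energy world: 12 reactions x 625
    substituent sets, power-law distance decay."""
    table, truth = hf.make_sn2_like(seed=11)
    return table, truth


@pytest.fixture(scope="session")
def sn2_table(sn2_world):
    return sn2_world[0]


@pytest.fixture(scope="session")
def sn2_truth(sn2_world):
    return sn2_world[1]


@pytest.fixture(scope="session")
def sn2_params(sn2_table):
    """Global sigma-Hammett fit of the noiseless world (reused: ~3 s)."""
    return hf.fit_sigma_hammett(sn2_table)


@pytest.fixture(scope="session")
def sn2_geom():
    return hf.sn2_geometry()


@pytest.fixture(scope="session")
def single_world():
    """Noiseless single-substituent log10-rate world, 6 reactions."""
    return hf.make_single_substituent_like(6, seed=3)


def truth_scale(params, truth):
    """Gauge factor: fitted rho are truth/rho(anchor), fitted sigma are
    truth*rho(anchor)."""
    return truth.rho[params.anchor_reaction]


@pytest.fixture(scope="session")
def gauge_scale(sn2_params, sn2_truth):
    return truth_scale(sn2_params, sn2_truth)
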