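import pytest

from patchpk import SimulationGrid, load_preset, standard_cycle


@pytest.fixture(scope="session")
def table1():
    """Published parameter pair (NGMN in ng/mL, EE in pg/mL)."""
    return load_preset("table1-verbatim")


@pytest.fixture(scope="session")
def ngmn(table1):
    return table1["NGMN"]


@pytest.fixture(scope="session")
def ee(table1):
    return table1["EE"]


@pytest.fixture(scope="session")
def std_regimen():
    return standard_cycle()


@pytest.fixture(scope="session")
def std_grid(std_regimen):
    return SimulationGrid(dt=0.1, horizon=std_regimen.horizon)
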