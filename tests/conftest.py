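import numpy as np
import pytest

from woundscore import AnalysisConfig, Condition, PlateDataset, WellTimeSeries
from woundscore.simulate import SimParams, simulate_screen

GRID_72H = np.arange(0.0, 73.0, 2.0)  # 37 samples, the instrument's 2-h cadence


def make_condition(drug="DMSO", conc=0.0, cell_line="CL1", density=30_000, mmc=True, rep=1):
    return Condition(cell_line, drug, conc, density, mmc, rep)


def make_well(rwd, times=None, caspase=None, **cond_kwargs):
    rwd = np.asarray(rwd, dtype=float)
    if times is None:
        times = np.arange(len(rwd), dtype=float) * 2.0
    if caspase is None:
        caspase = np.full(len(rwd), 100.0)
    return WellTimeSeries(make_condition(**cond_kwargs), times, rwd, caspase)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def mixed_screen():
    """Default-conditions mixed screen across three seeding densities."""
    return simulate_screen(SimParams(), "mixed")


@pytest.fixture(scope="session")
def migrastatic_screen():
    return simulate_screen(SimParams(), "pure_migrastatic", densities=[30_000])


@pytest.fixture(scope="session")
def cytotoxic_screen():
    return simulate_screen(SimParams(), "pure_cytotoxic", densities=[30_000])


@pytest.fixture
def simple_stratum():
    """Control closing linearly plus one treated drug series (3 doses)."""
    ctrl_rwd = np.clip(GRID_72H / 36.0, 0.0, 1.0)
    wells = [make_well(ctrl_rwd, times=GRID_72H, caspase=np.full(37, 50.0))]
    for i, conc in enumerate([1.0, 2.0, 4.0], start=1):
        rwd = np.clip(GRID_72H / (36.0 + 12.0 * i), 0.0, 1.0)
        casp = np.full(37, 50.0 + 30.0 * i)
        wells.append(
            make_well(rwd, times=GRID_72H, caspase=casp, drug="DRUG-X", conc=conc)
        )
    return wells


@pytest.fixture
def simple_dataset(simple_stratum):
    return PlateDataset(wells=simple_stratum).validate()
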