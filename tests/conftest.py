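import warnings

import numpy as np
import pytest

from flankscr.encounter_data import TrapArray, ObservedEncounterData
from flankscr.state_space import HabitatGrid
from flankscr.detection import DetectionParams, ModelSpec
from flankscr.likelihood import PriorSpec

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def small_traps():
    """3 traps x 2 occasions with one dark trap-occasion."""
    op = np.array([[1, 1], [1, 0], [1, 1]], dtype=np.int8)
    return TrapArray(ids=["A", "B", "C"], xy=[[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]],
                     elevation=[500.0, 600.0, 700.0], operation=op)


@pytest.fixture(scope="session")
def micro_instance():
    """Tiny exactly-enumerable problem: 2 traps, 2 occasions, 4 cells,
    one single left-flank and one single right-flank record."""
    traps = TrapArray(ids=["A", "B"], xy=[[0.0, 0.0], [1000.0, 0.0]],
                      elevation=[500.0, 600.0],
                      operation=np.ones((2, 2), dtype=np.int8))
    cent = np.array([[-250.0, -250.0], [750.0, -250.0],
                     [-250.0, 750.0], [750.0, 750.0]])
    grid = HabitatGrid(centroids=cent, cell_size=1000.0,
                       h=np.ones(4, dtype=np.int8), nrow=2, ncol=2,
                       xll=-750.0, yll=-750.0)
    data = ObservedEncounterData(
        left=[np.array([[1, 0], [0, 0]], dtype=np.int8)],
        right=[np.array([[0, 0], [2, 0]], dtype=np.int8)])
    params = DetectionParams(beta=np.array([-0.5]), sigma=800.0)
    return {"traps": traps, "grid": grid, "data": data, "params": params,
            "model": ModelSpec("M0"), "priors": PriorSpec(),
            "delta1": 0.3, "delta2": 0.3, "alpha": 0.4}
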