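import numpy as np
import pandas as pd
import pytest

from roaddust import ConcentrationMatrix, ReferenceSet


@pytest.fixture
def background() -> dict:
    return {"Cd": 0.5, "Cr": 70.0, "Cu": 30.0, "Ni": 40.0, "Pb": 20.0,
            "Co": 12.0, "Ba": 60.0, "Fe": 15000.0, "Mn": 200.0, "Zn": 70.0}


@pytest.fixture
def ref(background) -> ReferenceSet:
    return ReferenceSet(background=background)


@pytest.fixture
def small_conc(background) -> ConcentrationMatrix:
    """Two zones x 6 sites x 4 metals, deterministic, all positive."""
    rng = np.random.default_rng(42)
    metals = ["Cd", "Ni", "Mn", "Zn"]
    sites = [f"A{i}" for i in range(1, 7)] + [f"B{i}" for i in range(1, 7)]
    base = np.array([background[m] for m in metals])
    data = pd.DataFrame(
        base * rng.lognormal(0.0, 0.4, size=(12, 4)), index=sites, columns=metals
    )
    return ConcentrationMatrix(data)
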