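import numpy as np
import pandas as pd
import pytest

from bubalus import pedigree as ped_mod
from bubalus import reml, simdata


@pytest.fixture
def fullsib_pedigree():
    """Founders A, B; full sibs S1, S2; X = offspring of the sib mating."""
    return ped_mod.pedigree_from_records(
        [("A", None, None), ("B", None, None), ("S1", "A", "B"),
         ("S2", "A", "B"), ("X", "S1", "S2")]
    )


@pytest.fixture
def six_record_model():
    """6 records on a 10-animal two-generation pedigree with repeated dams."""
    ped = ped_mod.pedigree_from_records([
        ("S1", None, None), ("S2", None, None), ("D1", None, None),
        ("D2", None, None), ("C1", "S1", "D1"), ("C2", "S1", "D1"),
        ("C3", "S2", "D2"), ("C4", "S2", "D1"), ("C5", "S1", "D2"),
        ("C6", "S2", "D2"),
    ])
    rng = np.random.default_rng(42)
    data = pd.DataFrame({
        "animal": ["C1", "C2", "C3", "C4", "C5", "C6"],
        "sex": ["m", "f", "m", "f", "m", "f"],
        "y": rng.normal(100.0, 4.0, 6),
    })
    spec = reml.AnimalModelSpec("y", ped, ("sex",), include_maternal=True)
    return ped, data, spec


def small_herd(seed=0, **kw):
    """A compact simulated herd for fast end-to-end tests."""
    defaults = dict(
        n_sires=6, n_dams=40, n_calves=80, n_farms=6, calves_per_dam=2,
        traits=("WH",), seed=seed,
    )
    defaults.update(kw)
    return simdata.simulate_herd(simdata.SimConfig(**defaults))
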