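import numpy as np
import pandas as pd
import pytest

from tbiscreen import synthetic as syn
from tbiscreen.seizures import AnimalRecord, SeizureEvent


@pytest.fixture
def toy_de_table() -> pd.DataFrame:
    """10 rows of which exactly 4 pass |FC| >= 1.5 and FDR < 0.05."""
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(10)],
            "fc": [2.0, 1.4, -1.6, 1.5, -3.0, 1.1, 1.8, -1.45, 4.0, -2.2],
            "fdr": [0.01, 0.001, 0.02, 0.20, 0.001, 0.01, 0.049, 0.001, 0.30, 0.06],
        }
    )
    # qualifying rows: g0 (2.0, .01), g2 (-1.6, .02), g4 (-3.0, .001), g6 (1.8, .049)


@pytest.fixture
def toy_records() -> list[AnimalRecord]:
    return [
        AnimalRecord("a1", "VEH", [SeizureEvent(9.0, 60.0, 2), SeizureEvent(30.2, 40.0, 0)]),
        AnimalRecord("a2", "VEH", []),
        AnimalRecord("a3", "VEH", [SeizureEvent(50.0, 40.0, None)]),
    ]


@pytest.fixture
def null_cohort_groups():
    """The study group structure with every group at vehicle parameters."""
    sizes = [("VEH", 16), ("TSA", 7), ("LEVlow", 10), ("LEVhigh", 10), ("LEVhigh+TSA", 10)]
    def make(seed: int):
        spec = syn.CohortSpec(
            groups=[syn.GroupSpec(lbl, n, 0.81) for lbl, n in sizes], seed=seed
        )
        return syn.gen_cohort(spec).by_group
    return make
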