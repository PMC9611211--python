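import numpy as np
import pandas as pd
import pytest

from cwevalkit.tables import CountTable

#: published six-indicator rotated loading matrix (two varimax factors)
#: used as the golden input for the weighting chain
ROTATED_LOADINGS = np.array(
    [
        [0.880, 0.350],   # COD removal rate
        [0.309, 0.795],   # TP removal rate
        [0.591, 0.744],   # TN removal rate
        [0.948, 0.126],   # NO3-N removal rate
        [0.017, 0.949],   # NH4-N removal rate
        [0.919, 0.125],   # CED removal rate
    ]
)

PUBLISHED_INDICATOR_WEIGHTS = {
    "COD": 0.1856,
    "TP": 0.1588,
    "TN": 0.1955,
    "NO3-N": 0.1649,
    "NH4-N": 0.1349,
    "CED": 0.1603,
}


@pytest.fixture
def rotated_loadings():
    return ROTATED_LOADINGS.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_count_table(counts: dict, groups: dict, lineage: dict | None = None):
    """Small CountTable from {sample: [counts]} plus {sample: group}."""
    frame = pd.DataFrame(counts)
    n = len(frame)
    ids = [f"otu{i}" for i in range(n)]
    frame.index = pd.Index(ids, name="taxon_id")
    lin = pd.Series(lineage) if lineage else pd.Series(
        {t: f"Bacteria;Phylum{i % 3};c;o;f;Genus{i}" for i, t in enumerate(ids)}
    )
    lin.index = frame.index if lineage is None else lin.index
    return CountTable(counts=frame, lineage=lin, groups=groups)


@pytest.fixture
def simple_removal_table():
    rows = []
    rng = np.random.default_rng(7)
    for system in ("S", "A"):
        for pollutant in ("COD", "TP", "TN"):
            for day in (1, 2, 3):
                for rep in (1, 2):
                    rows.append(
                        (system, pollutant, day, rep,
                         float(rng.uniform(0.1, 0.9)))
                    )
    return pd.DataFrame(
        rows, columns=["system", "pollutant", "day", "replicate", "removal"]
    )
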