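from pathlib import Path

import numpy as np
import pytest

from paleonet.synth import (
    planted_hub_spec,
    synth_abundance,
    two_block_spec,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def two_block_table():
    """30-sample count table with two planted 8-taxon blocks (basis rho 0.7)."""
    table, truth = synth_abundance(two_block_spec(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def hub_table():
    """30-sample count table with one hub taxon correlated with 10 partners."""
    table, truth = synth_abundance(planted_hub_spec(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def fractions_5taxa(data_dir):
    rows = (data_dir / "fractions_5taxa.tsv").read_text().strip().splitlines()
    taxa = rows[0].split("\t")
    values = np.array([[float(c) for c in r.split("\t")] for r in rows[1:]])
    return taxa, values
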