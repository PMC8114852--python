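import numpy as np
import pandas as pd
import pytest

from tarsomorph import MeasurementTable, SimConfig, generate_measurements


@pytest.fixture(scope="session")
def small_config():
    """Reduced synthetic layout: quick to generate, still 6 groups + fossils."""
    return SimConfig(
        n_extant_per_group=(6, 6, 6, 6, 6, 6),
        n_palaeocene=10,
        n_cretaceous=4,
        n_variables=12,
        n_latent=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    table, truth = generate_measurements(small_config)
    return table, truth


@pytest.fixture(scope="session")
def default_table():
    """Full study-size synthetic table (85 extant + 45 fossils, 29 vars)."""
    table, truth = generate_measurements(SimConfig(seed=7))
    return table, truth


@pytest.fixture()
def toy_table():
    meas = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 8.0], "c": [5.0, 1.0, 2.0]},
        index=pd.Index(["t1", "t2", "t3"], name="taxon"),
    )
    return MeasurementTable(
        meas,
        pd.Series(["extant", "extant", "Palaeocene"], index=meas.index),
        pd.Series(["arboreal", "cursorial", np.nan], index=meas.index),
    )
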