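import numpy as np
import pandas as pd
import pytest

from mra.measurement_data import MeasurementTable
from mra.synthetic import (demo_scenario, planted_contrast_config,
                           simulate_measurements)


def make_table(values: np.ndarray, columns, groups=None, ids=None) -> MeasurementTable:
    """Build a MeasurementTable from a raw array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    idx = pd.Index(ids, name="specimen_id")
    vals = pd.DataFrame(values, index=idx, columns=list(columns))
    group = pd.Series(groups if groups is not None else ["g"] * n,
                      index=idx, name="group")
    strain = pd.Series("", index=idx, name="strain")
    missing = vals.isna()
    imputed = pd.DataFrame(False, index=idx, columns=vals.columns)
    return MeasurementTable(vals, group, strain, missing, imputed)


@pytest.fixture(scope="session")
def planted_table():
    """Two groups of 60 separated by one planted log-ratio, analytic D = 5."""
    cfg = planted_contrast_config(seed=11)
    table, truth = simulate_measurements(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def demo_table():
    """Six-group demo scenario with gst.b artifact and 2% missingness."""
    cfg = demo_scenario(seed=7)
    table, truth = simulate_measurements(cfg)
    return cfg, table, truth
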