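import numpy as np
import pandas as pd
import pytest

from pairedmetab.io import Condition, ConcentrationTable, SampleKey
from pairedmetab.simulate import make_paper_shaped_cohort


def build_table(before: np.ndarray, after: np.ndarray, metabolites=None):
    """Assemble a ConcentrationTable from (animals x metabolites) arrays."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    assert before.shape == after.shape
    n, j = before.shape
    metabolites = metabolites or [f"M{k + 1:02d}" for k in range(j)]
    rows, keys = [], []
    for i in range(n):
        rows.append(before[i])
        keys.append(SampleKey(f"A{i + 1:02d}", Condition.BEFORE))
        rows.append(after[i])
        keys.append(SampleKey(f"A{i + 1:02d}", Condition.AFTER))
    return ConcentrationTable(pd.DataFrame(rows, columns=metabolites), keys)


@pytest.fixture(scope="session")
def preset_cohort():
    """One paper-shaped synthetic cohort shared across tests."""
    return make_paper_shaped_cohort(seed=11)


@pytest.fixture
def small_table():
    """3 animals x 3 metabolites with hand-chosen values."""
    before = np.array([[1.0, 2.0, 0.30], [1.2, 1.8, 0.25], [0.8, 2.2, 0.35]])
    after = np.array([[1.5, 1.6, 0.30], [1.9, 1.5, 0.20], [1.1, 1.9, 0.40]])
    return build_table(before, after, ["valine", "glucose", "acetate"])
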