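import numpy as np
import pandas as pd
import pytest

from epiclock import synthetic as syn
from epiclock.io import CpGCountMatrix


@pytest.fixture(scope="session")
def default_design():
    return syn.StudyDesign(seed=11)


@pytest.fixture(scope="session")
def default_arch():
    return syn.ClockArchitecture()


@pytest.fixture(scope="session")
def default_dataset(default_design, default_arch):
    """One default synthetic study (matrix, sheet, truth), shared read-only."""
    return syn.generate_methylation_dataset(default_design, default_arch)


@pytest.fixture()
def tiny_matrix():
    """3 sites x 2 libraries with easy hand-checkable counts."""
    meth = np.array([[5, 0], [2, 8], [0, 3]])
    total = np.array([[10, 4], [2, 10], [6, 3]])
    return CpGCountMatrix.from_arrays(
        ["chr1", "chr1", "chr2"], [10, 25, 7], meth, total, ["libA", "libB"])


@pytest.fixture()
def two_group_sheet():
    rows = []
    for treat in ("control", "diapause"):
        for day in (6, 12, 18, 24, 30):
            for rep in (1, 2, 3, 4):
                rows.append((f"{treat}_d{day:02d}_r{rep}", treat, float(day), rep, 10))
    return pd.DataFrame(rows, columns=["library_id", "treatment", "age_days",
                                       "replicate", "pool_size"])
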