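import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mwaskit import qc, simulate
from mwaskit.datatypes import AbundanceMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across read-only tests."""
    return simulate.simulate_cohort(simulate.CohortSimConfig(seed=11))


@pytest.fixture(scope="session")
def qc_cohort(default_cohort):
    matrix, phen, ann, truth = default_cohort
    processed, report = qc.run_qc_pipeline(matrix, qc.QcConfig(seed=11))
    return processed, report, phen, ann, truth


@pytest.fixture(scope="session")
def default_sumstats():
    return simulate.simulate_sumstats(simulate.MrSimConfig(seed=11))


def toy_matrix(values, batch=None, plate=None, run_day=None, wave=None, is_ref=None,
               scale="raw", subject=None):
    """Small AbundanceMatrix from a 2-D array for hand-computed fixtures."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    idx = [f"s{i}" for i in range(n)]
    cols = [f"m{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "batch": batch if batch is not None else ["b0"] * n,
            "plate": plate if plate is not None else ["p0"] * n,
            "run_day": run_day if run_day is not None else ["d0"] * n,
            "wave": wave if wave is not None else ["baseline"] * n,
            "is_reference": is_ref if is_ref is not None else [False] * n,
        },
        index=idx,
    )
    if subject is not None:
        meta["subject_id"] = subject
    return AbundanceMatrix(pd.DataFrame(values, index=idx, columns=cols), meta, scale=scale)
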