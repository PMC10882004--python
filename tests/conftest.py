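import numpy as np
import pandas as pd
import pytest

import stratrand as sr


@pytest.fixture(scope="session")
def default_cohort() -> sr.Cohort:
    """The 506-participant reference cohort (mean 0.978, SD 1.899, rho 0.601)."""
    return sr.generate_cohort(sr.CohortParams())


@pytest.fixture(scope="session")
def indexed_cohort() -> sr.Cohort:
    """Reference cohort augmented with auxiliary indices of graded correlation."""
    specs = tuple(
        sr.IndexSpec(name=f"idx_{int(c * 10):02d}", correlation=c, mean=0.978, sd=1.899)
        for c in (0.0, 0.3, 0.6, 0.9)
    )
    return sr.generate_cohort(sr.CohortParams(index_specs=specs, seed=17))


@pytest.fixture()
def tiny_cohort() -> sr.Cohort:
    """Hand-built 10-participant cohort for brute-force checks."""
    gt = np.array([0.0, 0.5, 1.0, -0.5, 2.0, 3.5, 0.0, 1.5, -1.0, 4.0])
    table = pd.DataFrame({
        "id": np.arange(10),
        "gt_change": gt,
        "pred_change": gt * 0.5 + 0.3,
    })
    return sr.Cohort(table=table)


def constant_cohort(n: int = 60, value: float = 1.0) -> sr.Cohort:
    table = pd.DataFrame({
        "id": np.arange(n),
        "gt_change": np.full(n, value),
        "pred_change": np.linspace(-1, 1, n),
    })
    return sr.Cohort(table=table)
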