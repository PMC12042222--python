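import numpy as np
import pandas as pd
import pytest

from dbt_triage.fixture import build_fixture_cohort
from dbt_triage.records import CohortTable


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_fixture_cohort()


def random_cohort(seed: int, n: int | None = None) -> CohortTable:
    """Small random cohort respecting the single/double-reading nesting.

    Used as an unstructured input for engine property tests; not drawn
    from the calibrated generator on purpose, so the engine's invariants
    are exercised on arbitrary recall structure.
    """
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(1, 1000))
    scores = rng.uniform(0.0, 10.0, size=n)
    cancer = rng.random(n) < 0.05
    sm_dr = rng.random(n) < 0.15
    dbt_dr = rng.random(n) < 0.2
    sm_sr = sm_dr & (rng.random(n) < 0.7)
    dbt_sr = dbt_dr & (rng.random(n) < 0.8)
    df = pd.DataFrame(
        {
            "exam_id": [f"r{seed}_{i}" for i in range(n)],
            "ai_score": scores,
            "cancer": cancer,
            "recall_sm_sr": sm_sr,
            "recall_sm_dr": sm_dr,
            "recall_dbt_sr": dbt_sr,
            "recall_dbt_dr": dbt_dr,
        }
    )
    return CohortTable(df, provenance=f"random seed={seed}")
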