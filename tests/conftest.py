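import warnings

import numpy as np
import pytest

from hypomel.pipeline import PipelineConfig, run_pipeline
from hypomel.synth import SimConfig, simulate_nanostring_cohort


@pytest.fixture(scope="session")
def planted_pipeline_runs():
    """100 seeded end-to-end runs on cohorts with a planted differential pair.

    Each record carries whether the planted pair (T01/T02) survived the
    correlation gate, whether it was the top-leverage feature, and the
    permutation p of the sample ordering. Shared between the NMF
    recovery test and the end-to-end acceptance check so the experiment
    runs once.
    """
    records = []
    for seed in range(100):
        cm = simulate_nanostring_cohort(SimConfig(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(PipelineConfig(seed=seed, permutations=1000), cm)
        records.append(
            {
                "found": "T01/T02" in res.pairs.labels(),
                "top": res.top_pair == "T01/T02",
                "p": res.perm.p,
                "n_pairs": len(res.pairs),
            }
        )
    return records


@pytest.fixture()
def small_cohort():
    """One modest cohort plus its normalized expression, reused across tests."""
    from hypomel.nanostring import normalize_counts

    cm = simulate_nanostring_cohort(SimConfig(seed=42))
    return cm, normalize_counts(cm)
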