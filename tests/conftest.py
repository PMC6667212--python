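import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import trajdeg as T

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cm():
    """300-gene, 4-stage x 4-replicate synthetic matrix."""
    cm, truth = T.simulate_counts(300, seed=1)
    return cm, truth


@pytest.fixture
def cfg():
    return T.PipelineConfig()


def make_cm(counts, stages, tissue="leaf"):
    """Build a CountMatrix from a genes x samples array and per-sample stages."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    reps = {}
    sample_ids, rep_col = [], []
    for s in stages:
        reps[s] = reps.get(s, 0) + 1
        sample_ids.append(f"{tissue}_{s}_r{reps[s]}")
        rep_col.append(reps[s])
    samples = pd.DataFrame(
        {"tissue": [tissue] * n_samples, "stage": list(stages), "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    df = pd.DataFrame(
        counts, index=[f"g{i + 1}" for i in range(n_genes)], columns=sample_ids
    )
    order = []
    for s in stages:
        if s not in order:
            order.append(s)
    return T.CountMatrix(df, samples, stage_order=tuple(order))
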