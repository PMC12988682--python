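import dataclasses

import numpy as np
import pandas as pd
import pytest

from octnorm import (
    CohortConfig,
    MetricModel,
    default_c_rdb_config,
    default_rw_rdb_config,
    generate_healthy_cohort,
)
from octnorm.registry import METRICS


@pytest.fixture(scope="session")
def gcl_spec():
    return METRICS["g_GCLplus"]


@pytest.fixture(scope="session")
def cp_spec():
    return METRICS["g_cpRNFL"]


def make_cohort(n, seed, metrics=("g_cpRNFL", "g_GCLplus"), hetero_slope=0.0, **age_kw):
    """Reference-population cohort restricted to a few metrics (fast path)."""
    base = default_rw_rdb_config(n, seed=seed, hetero_slope=hetero_slope)
    models = {m: base.metric_models[m] for m in metrics}
    cfg = dataclasses.replace(base, metric_models=models, **age_kw)
    return cfg, generate_healthy_cohort(cfg)


@pytest.fixture(scope="session")
def rw_like():
    """Medium reference cohort with the two global metrics."""
    return make_cohort(1500, seed=11)


@pytest.fixture(scope="session")
def small_rdb():
    """Commercial-sized (398-eye) cohort from the same population."""
    base = default_c_rdb_config(398, seed=23)
    models = {m: base.metric_models[m] for m in ("g_cpRNFL", "g_GCLplus")}
    cfg = dataclasses.replace(base, metric_models=models)
    return cfg, generate_healthy_cohort(cfg)


def toy_frame(ages, values, metric="g_GCLplus", disc=None):
    df = pd.DataFrame(
        {
            "eye_id": [f"t{i}" for i in range(len(ages))],
            "age": np.asarray(ages, dtype=float),
            "disc_area": np.full(len(ages), 2.0) if disc is None else np.asarray(disc, float),
            "cohort": "reference",
            metric: np.asarray(values, dtype=float),
        }
    )
    return df
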