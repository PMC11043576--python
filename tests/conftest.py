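import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirdiscover.cohort import CASE, CONTROL, CohortTable, SampleRecord
from mirdiscover.replication import FeatureTable


def make_cohort(n_cases, n_controls, hormone_pattern=None, phase="replication",
                ages=None, confirmed=None):
    """Small deterministic cohort for unit tests."""
    records = []
    for i in range(n_cases):
        records.append(SampleRecord(
            sample_id=f"case-{i + 1:03d}", group=CASE,
            hormone_use=bool(hormone_pattern[i]) if hormone_pattern else (i % 2 == 0),
            age=float(ages[i]) if ages else 18.0,
            pathology_confirmed=bool(confirmed[i]) if confirmed is not None else True,
        ))
    for i in range(n_controls):
        records.append(SampleRecord(
            sample_id=f"ctrl-{i + 1:03d}", group=CONTROL,
            hormone_use=(i % 2 == 0) if hormone_pattern is None
            else bool(hormone_pattern[i % n_cases]),
            age=18.0,
        ))
    return CohortTable(tuple(records), phase=phase)


def make_feature_table(X, y, hormone=None, probe_names=None, split=None):
    """Assemble a FeatureTable from a raw matrix (samples x probes)."""
    X = np.asarray(X, float)
    n, p = X.shape
    probe_names = list(probe_names) if probe_names else [f"p{i:03d}" for i in range(p)]
    frame = pd.DataFrame(X, columns=probe_names,
                         index=[f"s{i:03d}" for i in range(n)])
    frame["hormone_use"] = hormone if hormone is not None else 0
    frame["group"] = np.where(np.asarray(y) == 1, CASE, CONTROL)
    frame["split"] = split if split is not None else "train"
    return FeatureTable(frame, probe_ids=tuple(probe_names))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
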