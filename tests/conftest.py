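import numpy as np
import pandas as pd
import pytest

from hypoforecast.model import ModelSpec
from hypoforecast.pipeline import PipelineConfig, run_pipeline
from hypoforecast.preprocess import CHANNELS, VitalSeries
from hypoforecast.synthetic import SimConfig

#: Normal-range fill values used when a test only cares about some channels.
NORMAL = {"hr": 80.0, "rr": 16.0, "spo2": 97.0, "sbp": 120.0, "dbp": 70.0, "map": 87.0}


def make_series(n_minutes=60, stay_id="stayA", subject_id="subjA", **channels) -> VitalSeries:
    """Build a VitalSeries from per-channel arrays/scalars; unspecified
    channels are filled with normal-range constants."""
    data = {}
    for ch in CHANNELS:
        if ch in channels:
            v = np.asarray(channels[ch], dtype=float)
            if v.ndim == 0:
                v = np.full(n_minutes, float(v))
            data[ch] = v
        else:
            data[ch] = np.full(n_minutes, NORMAL[ch])
    df = pd.DataFrame(data, index=pd.RangeIndex(n_minutes, name="minute"))
    return VitalSeries(subject_id=subject_id, stay_id=stay_id, data=df)


@pytest.fixture(scope="session")
def small_run():
    """A quick end-to-end pipeline run shared by integration-style tests."""
    sim = SimConfig(
        n_subjects=40, record_len_min=720, onset_earliest_min=300, onset_latest_min=600
    )
    cfg = PipelineConfig(
        sim=sim,
        model=ModelSpec(params={"n_estimators": 100}),
        stacked_model=ModelSpec(params={"n_estimators": 100}),
        cv_folds=5,
    )
    return run_pipeline(cfg, seed=11)


@pytest.fixture(scope="session")
def default_run():
    """The default-condition cohort: 200 subjects, half hypotensive, 24-hour
    records, tenfold CV — the synthetic surrogate for the study cohort."""
    return run_pipeline(PipelineConfig(), seed=20)
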