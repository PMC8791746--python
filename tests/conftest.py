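import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import silenttalk as st

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
    deadline=None)
settings.load_profile("default")

#: One seed for everything a test derives data from.
MASTER_SEED = 11


@pytest.fixture(scope="session")
def acq_cfg():
    return st.AcquisitionConfig()


@pytest.fixture(scope="session")
def subject_data(acq_cfg):
    """One subject's full synthetic campaign, pushed through the whole
    preprocessing + feature chain.

    Returns a dict with the raw-design counts and the feature store;
    the bulky raw records are dropped after featurizing.
    """
    records = st.generate_subject_dataset(acq_cfg, seed=MASTER_SEED)
    n_records = len(records)
    word_counts: dict[int, int] = {}
    for rec in records:
        for code, _ in rec.sync_events:
            word_counts[code] = word_counts.get(code, 0) + 1
    segments = []
    for rec in records:
        segments.extend(st.preprocess_record(rec))
    kept, rejected = st.reject_artifacts(segments)
    store = st.featurize_segments(kept)
    return {
        "n_records": n_records,
        "word_counts": word_counts,
        "n_segments": len(segments),
        "n_kept": len(kept),
        "n_rejected": len(rejected),
        "store": store,
    }


@pytest.fixture()
def small_record(acq_cfg):
    """One small 3-class test recording (5 trials)."""
    sched = st.generate_schedule((1, 5, st.SILENCE_CODE), 5,
                                 ti_s=acq_cfg.instance_time_s,
                                 fs_hz=acq_cfg.fs_hz, seed=MASTER_SEED)
    return st.synthesize_record(sched, st.default_signatures(), acq_cfg,
                                record_id=2, seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
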