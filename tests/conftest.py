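import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import deltameld as dm

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


def make_records(rows, rid="A"):
    """Registry frame from (day, uncapped MELD[, terminal_code]) tuples."""
    recs = []
    for r in rows:
        day, meld = r[0], r[1]
        code = r[2] if len(r) > 2 else "none"
        recs.append(dict(registrant_id=rid, record_date=day,
                         meld_uncapped=meld, meld_capped=min(meld, 40),
                         serum_sodium=137.0, status="active",
                         terminal_code=code, age_years=50.0,
                         ethnicity="White", diagnosis="other",
                         exception_case=0, status_1=0))
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def default_registry():
    return dm.simulate_registry(dm.SimConfig(n_registrants=2000, seed=11))


@pytest.fixture(scope="session")
def default_cohort_rows(default_registry):
    kept, _ = dm.filter_cohort(default_registry)
    feats = dm.compute_delta_meld(kept)
    return feats, dm.cohort_counting_process(feats)


@pytest.fixture(scope="session")
def recovery_pipeline():
    """One clean-recovery simulation taken through the whole pipeline."""
    cfg = dm.recovery_scenario(n=4000, seed=42)
    reg = dm.simulate_registry(cfg)
    kept, _ = dm.filter_cohort(reg)
    feats = dm.compute_delta_meld(kept)
    rows = dm.cohort_counting_process(feats)
    return cfg, feats, rows


def random_registrants(n_registrants, seed, max_rows=8):
    """Random irregular MELD trajectories for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_registrants):
        k = int(rng.integers(1, max_rows + 1))
        days = np.sort(rng.choice(np.arange(0, 400), size=k, replace=False))
        melds = np.maximum(6, 18 + np.cumsum(rng.integers(-6, 15, size=k)))
        frames.append(pd.DataFrame({
            "registrant_id": f"r{i}", "record_date": days,
            "meld_uncapped": melds,
        }))
    return pd.concat(frames, ignore_index=True)
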