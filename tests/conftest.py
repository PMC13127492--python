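import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def tiny_panel():
    """Three subjects, handmade: one initiates at step 2, one never, one at
    step 0.  Single predictor ``p``."""
    rows = []
    # subject A: event at step 2 of steps 0..4
    for step, (y, m) in enumerate([(0, 1), (0, 1), (1, 1), (0, 0), (0, 0)]):
        rows.append({"subject_id": "A", "step": step, "y_use": y, "m_use": m,
                     "p": float(10 + step)})
    # subject B: never initiates over steps 0..3
    for step in range(4):
        rows.append({"subject_id": "B", "step": step, "y_use": 0, "m_use": 1,
                     "p": float(20 + step)})
    # subject C: initiates immediately
    rows.append({"subject_id": "C", "step": 0, "y_use": 1, "m_use": 1, "p": 30.0})
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
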