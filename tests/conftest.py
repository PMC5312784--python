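import numpy as np
import pandas as pd
import pytest

from revlearn import task_engine as te


def make_log(rows, subject_id=None):
    """Build a minimal trial-log frame from compact per-trial tuples:
    (block, trial, applied, correct, feedback, phase)."""
    records = []
    for block, trial, applied, correct, feedback, phase in rows:
        records.append({
            "block_index": block, "trial_index": trial,
            "stimulus_id": f"b{block}_s1", "correct_mapping": correct,
            "applied_mapping": applied,
            "rule_correct": applied == correct, "feedback": feedback,
            "feedback_valid": (feedback == te.POSITIVE) == (applied == correct),
            "instruction": te.VOLATILITY, "phase": phase,
            "reliability": 0.75, "has_reversal": True,
        })
    log = pd.DataFrame(records, columns=te.TRIAL_LOG_COLUMNS)
    if subject_id is not None:
        log.insert(0, "subject_id", subject_id)
    return log


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
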