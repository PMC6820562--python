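import numpy as np
import pandas as pd
import pytest

from delaycode.io_core import SAMPLE_PHASE_S, TRIAL_COLUMNS, validate_trials
from delaycode.synthetic import NeuronSpec, SimConfig, generate_session


def make_trials(rows):
    """Trial table from (condition, sample, choice, delay, iti) tuples."""
    records = []
    for i, (condition, sample, choice, delay, iti) in enumerate(rows):
        records.append(
            {
                "session_id": "s0",
                "trial_id": i,
                "condition": condition,
                "sample": sample,
                "choice": choice,
                "correct": sample == choice,
                "delay_duration": delay,
                "t_cue_on": 0.0,
                "t_delay_on": SAMPLE_PHASE_S,
                "t_delay_off": SAMPLE_PHASE_S + delay,
                "iti_before": iti,
            }
        )
    return validate_trials(pd.DataFrame(records, columns=TRIAL_COLUMNS))


@pytest.fixture(scope="session")
def small_session():
    """One simulated day, sized so decoding trial criteria are satisfiable."""
    cfg = SimConfig(
        n_sequential=8,
        n_persistent=3,
        n_untuned=3,
        n_interneurons=2,
        n_trials_per_condition=60,
        p_correct=0.85,
        seed=11,
    )
    units, trials, specs = generate_session(cfg)
    return cfg, units, trials, specs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
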