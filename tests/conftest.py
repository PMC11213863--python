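import numpy as np
import pandas as pd
import pytest

from msddm import (DesignSpec, AgeGenerativeModel, simulate_dataset,
                   preprocess)


@pytest.fixture(scope="session")
def design_spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def gen_model():
    return AgeGenerativeModel()


@pytest.fixture(scope="session")
def small_dataset(design_spec, gen_model):
    """Six simulated participants with ground truth; shared across tests."""
    trials, truth = simulate_dataset(design_spec, gen_model, 6, seed=11)
    return trials, truth


@pytest.fixture(scope="session")
def clean_trials(small_dataset):
    trials, _ = small_dataset
    clean, _ = preprocess(trials)
    return clean


def make_trials(rows):
    """Hand-build a trial table from (pid, age, cond, coh, rt_ms, correct)
    tuples; rt None means timeout."""
    recs = []
    for i, (pid, age, cond, coh, rt, correct) in enumerate(rows):
        recs.append({
            "participant_id": pid, "age": age, "block": 1, "trial": i + 1,
            "condition": cond, "coherence": coh, "category": "face",
            "rt": np.nan if rt is None else float(rt),
            "response": None if rt is None else ("face" if correct else "car"),
            "correct": None if rt is None else bool(correct),
            "timeout": rt is None,
        })
    return pd.DataFrame(recs)
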