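import numpy as np
import pandas as pd
import pytest

from popdim.io_core import SessionData
from popdim.synthetic import GeneratorConfig, make_fixture, simulate_session


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny-2block")


@pytest.fixture(scope="session")
def null_session():
    return make_fixture("null")


@pytest.fixture(scope="session")
def paper_shape():
    return make_fixture("paper-shape")


@pytest.fixture(scope="session")
def default_session():
    """One default-condition session with ground truth, shared by tests."""
    return simulate_session(GeneratorConfig(), seed=42)


@pytest.fixture()
def manual_session():
    """A hand-built two-neuron session with known counts for arithmetic checks.

    One What block of 12 trials reversing at trial 7; choices alternate so
    both classes appear in both phases.
    """
    n_trials = 12
    rev = 7
    rows = []
    for t in range(1, n_trials + 1):
        phase = "reversal" if t >= rev else "acquisition"
        choice = 1 + (t % 2)
        rows.append((1, "What", phase, t, t if t < rev else t - rev + 1,
                     choice, 1 + ((t // 2) % 2), t % 2, rev))
    trials = pd.DataFrame(rows, columns=[
        "block_id", "condition", "phase", "trial_in_block", "trial_in_phase",
        "chosen_image", "chosen_direction", "reward", "reversal_trial"])
    counts = np.zeros((2, n_trials, 2), dtype=np.int64)
    # neuron 0 fires 2 spikes for choice 1, 4 for choice 2 (bin 0)
    choice = trials["chosen_image"].to_numpy()
    counts[0, :, 0] = np.where(choice == 1, 2, 4)
    counts[1, :, 0] = np.where(choice == 1, 1, 3)
    counts[:, :, 1] = 1
    edges = np.array([[1.0, 251.0], [251.0, 501.0]])
    return SessionData(counts, trials, edges, "manual")
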