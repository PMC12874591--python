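import numpy as np
import pytest

import odorgng as og


def go_correct(session):
    return [
        t
        for t in session.trials
        if t.trial_type is og.TrialType.GO and t.outcome is og.Outcome.CORRECT
    ]


def nogo_correct(session):
    return [
        t
        for t in session.trials
        if t.trial_type is og.TrialType.NOGO and t.outcome is og.Outcome.CORRECT
    ]


@pytest.fixture(scope="session")
def mixed_session():
    """Small session with three neurons of each archetype."""
    task = og.TaskConfig(n_trials=120)
    return og.simulate_session(
        task,
        [
            (og.DEFAULT_ARCHETYPES["go_cue_late"], 3),
            (og.DEFAULT_ARCHETYPES["waiting_phasic"], 3),
            (og.DEFAULT_ARCHETYPES["drinking_ramp"], 3),
            (og.DEFAULT_ARCHETYPES["untuned"], 3),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def decoding_session():
    """Session large enough for 40 correct trials of each type."""
    task = og.TaskConfig(n_trials=150)
    return og.simulate_session(
        task,
        [
            (og.DEFAULT_ARCHETYPES["go_cue_late"], 15),
            (og.DEFAULT_ARCHETYPES["untuned"], 15),
        ],
        seed=23,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(101)
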