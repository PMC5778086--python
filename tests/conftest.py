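import numpy as np
import pytest

from ruleflux import behavior, synthetic_data
from ruleflux.session_io import (NeuronMeta, Session, TrialRecord,
                                 blocks_from_trials)


@pytest.fixture(scope="session")
def default_session():
    """One default-condition synthetic session, reused read-only."""
    cfg = synthetic_data.GeneratorConfig(seed=7)
    return synthetic_data.generate_session(cfg, seed=7)


@pytest.fixture(scope="session")
def default_phases(default_session):
    session, _ = default_session
    return behavior.session_phases(session)


def make_toy_session(spike_times=(), n_trials=5):
    """Tiny hand-checkable session: 10 s trials, run 3 s, reward 2 s."""
    trials = []
    for i in range(n_trials):
        t0 = 10.0 * i
        start = "N" if i % 2 == 0 else "S"  # alternating, never >4 in a row
        trials.append(TrialRecord(
            index=i, rule_id=0, rule_name="go_east", start_arm=start,
            chosen_arm="E", correct=1, t_trial_start=t0, t_run_start=t0,
            t_reward_cross=t0 + 3.0, t_trial_end=t0 + 10.0, mean_speed=0.4))
    spikes = {"n0": np.asarray(sorted(spike_times), dtype=float)}
    total = trials[-1].t_trial_end - trials[0].t_trial_start
    neurons = [NeuronMeta("n0", len(spike_times) / total)]
    return Session(session_id="toy", trials=trials, neurons=neurons,
                   rule_schedule=blocks_from_trials(trials), spikes=spikes,
                   trajectories={})


@pytest.fixture
def toy_session():
    # spikes: 2 in trial 0 run, 10 in trial 0 reward, 1 in trial 1
    # inter-trial, 1 between-session gap (outside nothing: trials tile),
    # 1 after the last trial end (outside all trials)
    times = [0.5, 2.9, 3.1, *np.linspace(3.2, 4.9, 9), 16.0, 51.0]
    return make_toy_session(times)
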