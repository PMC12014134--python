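import numpy as np
import pandas as pd
import pytest

from avcortex.io_model import CUE_SIDE, SessionConfig
from avcortex.synthdata import (
    BehaviorSpec,
    NeuronSpec,
    PopulationSpec,
    generate_session,
    generate_spikes,
)


@pytest.fixture(scope="session")
def config():
    return SessionConfig()


@pytest.fixture(scope="session")
def fast_config():
    """Reduced resampling counts for quick unit tests."""
    return SessionConfig(n_permutations=200, n_bootstrap=500,
                         decode_resamples=3, decode_shuffles=20)


@pytest.fixture(scope="session")
def small_session():
    """A 12-neuron trained-condition session shared across tests."""
    pop = PopulationSpec(
        n_neurons=12, trials_per_cue=40, seed=11,
        weights={"auditory-only": 0.2, "visual-only": 0.1,
                 "audiovisual": 0.6, "audiovisual-only": 0.0,
                 "unresponsive": 0.1},
        interaction_mean={"A10kVvt": 1.5, "A3kVhz": 1.0,
                          "A10kVhz": 1.0, "A3kVvt": 1.0})
    spikes, trials, specs = generate_session(pop, BehaviorSpec())
    return spikes, trials, specs


def make_trials(cues, n_per_cue, p_correct=1.0, rng=None, start_id=1):
    """Hand-rolled trial table: ``n_per_cue`` trials per listed cue."""
    rng = np.random.default_rng(rng)
    rows = []
    tid = start_id
    for cue in cues:
        side = CUE_SIDE.get(cue)
        for _ in range(n_per_cue):
            if side is None:
                correct = "either"
                choice = "left" if rng.random() < 0.5 else "right"
            else:
                ok = rng.random() < p_correct
                correct = bool(ok)
                choice = side if ok else ("left" if side == "right" else "right")
            rows.append((tid, cue, choice, correct, 300.0))
            tid += 1
    return pd.DataFrame(rows, columns=[
        "trial_id", "cue", "choice", "correct", "reaction_time_ms"])


def make_spike_frame(times_by_trial, neuron_id="n0"):
    """Spike table from {trial_id: [times_ms, ...]}."""
    rows = [(neuron_id, tid, t)
            for tid, times in times_by_trial.items() for t in times]
    return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "spike_time_ms"])


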